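"""Raw-data examination: cluster-period event modification and tipping point.

With sparse events and few clusters, model-based effect estimates can hinge
on a handful of events in one or two cluster periods (site x month cells).
Two probes quantify that sensitivity:

* :func:`set_cluster_period_events` rewrites a single cell's event count
  (by seeded relabelling within the cell) and the analysis is refitted — for
  example reducing an outlying cell to the median count.

* :func:`tipping_point` removes events one at a time from a chosen
  (condition, phase) stratum — largest cluster periods first, ties broken by
  site order, then a seeded draw within the cell — refitting after each
  removal, until the odds ratio crosses 1 (or the stratum is exhausted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analyses import MODEL_CATALOGUE, run_analysis
from .design import CONTROL, INTERVENTION, TrialDesign, derive, tabulate_cluster_periods

logger = logging.getLogger("steppedwedge")


@dataclass
class TippingResult:
    """Outcome of the tipping-point search."""

    k_star: int | None              # minimal events removed; None if not reached
    modified_or: float | None
    modified_ci: tuple | None
    trajectory: list = field(default_factory=list)   # (k, OR, ci_low, ci_high)

    def trajectory_frame(self):
        return pd.DataFrame(
            self.trajectory, columns=["k_removed", "or", "ci_low", "ci_high"]
        )


def set_cluster_period_events(
    df: pd.DataFrame,
    design: TrialDesign,
    site,
    month_index: int,
    k: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Return a copy with the (site, month) cell's event count set to ``k``.

    Seeded relabelling of ``safety_event`` within the cell; denominators and
    every other cell are untouched.
    """
    # identical semantics to spike injection; exposed here under the
    # raw-data-examination vocabulary
    from .cohort import inject_spike

    return inject_spike(df, design, site, month_index, k, seed=seed)


def median_cluster_period_events(df, design, phase: str | None = "randomisation"):
    """Median events per cluster period (cells with >= 1 presentation),
    optionally restricted to one phase."""
    work = derive(df, design)
    if phase is not None:
        work = work[work["phase"] == phase]
    tab = tabulate_cluster_periods(work, design)
    return float(tab["events"].median()) if len(tab) else float("nan")


def crude_or(events_a, n_a, events_b, n_b):
    """Crude odds ratio from the implied 2x2 table; +0.5 continuity
    correction added to every cell when any cell is zero."""
    a, b = float(events_a), float(events_b)
    c, d = float(n_a) - a, float(n_b) - b
    if min(a, b, c, d) < 0:
        raise ValueError("events cannot exceed denominators")
    if (a + c) == 0 or (b + d) == 0:
        raise ValueError("odds ratio undefined: an entire margin is zero")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _removal_order(work, design, rng):
    """Event row indices ordered: largest-count cluster period first, ties by
    site order in the design, then seeded within the cell."""
    tab = tabulate_cluster_periods(work, design)
    tab = tab[tab["events"] > 0]
    site_rank = {s: i for i, s in enumerate(design.site_ids)}
    tab = tab.sort_values(
        by=["events", "site", "month_index"],
        key=lambda col: col.map(site_rank) if col.name == "site" else col,
        ascending=[False, True, True],
    )
    order = []
    months = work["month_index"].to_numpy()
    for _, row in tab.iterrows():
        cell = work.index[
            (work["site"] == row["site"]) & (months == row["month_index"])
            & (work["safety_event"] == 1)
        ].to_numpy()
        order.extend(rng.permutation(cell).tolist())
    return order


def tipping_point(
    df: pd.DataFrame,
    design: TrialDesign,
    code: str = "A",
    condition: str = INTERVENTION,
    phase: str = "randomisation",
    *,
    adjustment="none",
    method: str | None = None,
    seed: int = 0,
    max_removed: int | None = None,
) -> TippingResult:
    """How many events removed from a stratum reverse the odds ratio?

    For k = 0, 1, 2, ... events are removed cumulatively from the
    (condition, phase) stratum in the documented order and the ``code``
    model is refitted on the full analysis population each time.  The search
    stops at the first k with OR < 1 (k_star), at stratum exhaustion, or at
    ``max_removed``.  Non-convergence at some k is recorded and the search
    continues.
    """
    if condition not in (INTERVENTION, CONTROL):
        raise ValueError(f"condition must be '{INTERVENTION}' or '{CONTROL}'")
    rng = np.random.default_rng(seed)
    work = derive(df.copy(), design)
    stratum = work[(work["condition"] == condition) & (work["phase"] == phase)]
    n_events = int(stratum["safety_event"].sum())
    if n_events == 0:
        raise ValueError(f"no events in the {condition}/{phase} stratum")
    order = _removal_order(stratum[stratum["safety_event"] == 1], design, rng)
    limit = n_events if max_removed is None else min(max_removed, n_events)

    current = df.copy()
    trajectory = []
    k_star = None
    modified = (None, None)
    for k in range(0, limit + 1):
        if k > 0:
            current.loc[order[k - 1], "safety_event"] = 0
        try:
            fit = run_analysis(current, design, code, adjustment, outcome="safety",
                               method=method)
            or_k = fit.effect["estimate"]
            ci = (fit.effect["ci_low"], fit.effect["ci_high"])
        except Exception as err:   # keep probing past a failed refit
            logger.warning("tipping-point refit failed at k=%d: %s", k, err)
            trajectory.append((k, np.nan, np.nan, np.nan))
            continue
        trajectory.append((k, or_k, ci[0], ci[1]))
        if or_k < 1.0:
            k_star, modified = k, (or_k, ci)
            break
    return TippingResult(
        k_star=k_star,
        modified_or=modified[0],
        modified_ci=modified[1],
        trajectory=trajectory,
    )


__all__ = [
    "TippingResult", "set_cluster_period_events", "median_cluster_period_events",
    "crude_or", "tipping_point",
]
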