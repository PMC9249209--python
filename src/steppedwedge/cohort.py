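"""Synthetic cohort generation for stepped-wedge trial analyses.

Two generation modes:

* :func:`generate_parametric` draws a cohort from an explicit statistical
  model (uniform continuous recruitment, covariate marginals with optional
  secular drift, log-normal length of stay with multiplicative intervention /
  season / secular effects, and a rare binary safety event from a logistic
  model with site random intercepts).  This is the workhorse for simulation
  studies: every generating parameter is a knob of :class:`CohortParams`.

* :func:`generate_replica` reproduces a fixed set of phase-level count
  identities exactly — phase denominators, phase event totals, and the
  condition-specific split of events within the randomisation phase — while
  filling covariates parametrically.  Optionally one nominated cluster period
  (site x month) carries a fixed spike of events.  Counts are forced, not
  sampled, so the printed arithmetic of the emulated trial holds verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import (
    CONTROL,
    INTERVENTION,
    DATASET_COLUMNS,
    HISTORY_COLUMNS,
    TrialDesign,
    derive,
    season_of,
    tabulate_cluster_periods,
)

_SEASON_ORDER = ("Winter", "Spring", "Summer", "Autumn")


@dataclass
class CohortParams:
    """Generating parameters for the parametric cohort model.

    Defaults emulate a large unselected emergency-department population:
    mean age 59 (SD 17), 45% women, equal deprivation quintiles, plausible
    cardiovascular history prevalences, a geometric-mean length of stay of
    about 10 hours reduced multiplicatively under the intervention, and a
    rare safety event (~0.4%) with effectively zero between-site
    heterogeneity and, by default, no intervention effect (the null).
    """

    age_mean: float = 59.0
    age_sd: float = 17.0
    prop_female: float = 0.45
    simd_probs: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    history_prevalences: tuple = (
        0.15,  # prior ischaemic heart disease
        0.08,  # myocardial infarction
        0.05,  # cerebrovascular disease
        0.10,  # diabetes
        0.05,  # PCI
        0.03,  # CABG
        0.20,  # aspirin
        0.25,  # lipid-lowering drugs
        0.15,  # beta blockers
        0.15,  # ACE inhibitors
    )
    los_log_mean: float = float(np.log(10.1))   # log-hours
    los_log_sd: float = 0.9
    los_intervention_multiplier: float = 0.78
    los_season_multipliers: tuple = (1.0, 0.97, 0.95, 0.97)  # Winter, Spring, Summer, Autumn
    los_secular_slope: float = 0.0              # per-day change in log-hours
    los_missing_fraction: float = 0.0
    safety_baseline_logit: float = float(logit(0.004))
    safety_site_sd: float = 0.0
    safety_intervention_log_or: float = 0.0
    safety_secular_slope: float = 0.0           # per-day change on the logit scale
    site_weights: tuple | None = None           # relative site sizes; equal if None
    confounding_drift: dict | None = None       # covariate -> per-day slope
    seed: int = 0

    def validate(self):
        probs = [self.prop_female, *self.simd_probs, *self.history_prevalences]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.simd_probs) - 1.0) > 1e-8:
            raise ValueError("simd_probs must sum to 1")
        if self.los_log_sd <= 0:
            raise ValueError("los_log_sd must be positive")
        if self.safety_site_sd < 0:
            raise ValueError("safety_site_sd must be non-negative")
        if len(self.history_prevalences) != len(HISTORY_COLUMNS):
            raise ValueError("history_prevalences must have length 10")
        return self


@dataclass
class ReplicaCounts:
    """Phase-level count identities to reproduce exactly.

    Defaults are the emulated trial's printed arithmetic: 31,492 patients
    over three phases (10,724 / 9,336 / 11,432) with 113 safety events
    (49 / 37 / 27); within the randomisation phase, 29 events among 5,248
    intervention-condition presentations and 8 among 4,088 controls; and an
    optional single cluster-period spike of 7 events.
    """

    phase_denominators: tuple = (10724, 9336, 11432)
    phase_events: tuple = (49, 37, 27)
    randomisation_intervention: tuple = (29, 5248)   # (events, denominator)
    randomisation_control: tuple = (8, 4088)
    spike: tuple | None = None   # (site, month_index, events)

    def validate(self):
        ri_e, ri_n = self.randomisation_intervention
        rc_e, rc_n = self.randomisation_control
        if ri_e + rc_e != self.phase_events[1]:
            raise ValueError(
                "randomisation-phase condition events must sum to the phase total: "
                f"{ri_e} + {rc_e} != {self.phase_events[1]}"
            )
        if ri_n + rc_n != self.phase_denominators[1]:
            raise ValueError(
                "randomisation-phase condition denominators must sum to the phase total: "
                f"{ri_n} + {rc_n} != {self.phase_denominators[1]}"
            )
        for e, n in zip(self.phase_events, self.phase_denominators):
            if e > n:
                raise ValueError(f"phase events {e} exceed denominator {n}")
        if self.spike is not None and self.spike[2] > self.randomisation_intervention[0]:
            raise ValueError("spike events cannot exceed the randomisation-phase intervention events")
        return self

    @property
    def total_records(self):
        return int(sum(self.phase_denominators))

    @property
    def total_events(self):
        return int(sum(self.phase_events))


# ----------------------------------------------------------------------
# Covariate and outcome filling
# ----------------------------------------------------------------------

def _drift_slope(params: CohortParams, name: str) -> float:
    if not params.confounding_drift:
        return 0.0
    return float(params.confounding_drift.get(name, 0.0))


def _fill_covariates(df: pd.DataFrame, params: CohortParams, rng: np.random.Generator):
    """Draw age / sex / SIMD / history flags, with optional secular drift.

    Drift slopes are per-day: additive on years for age, additive on the
    logit scale for binary covariates.
    """
    n = len(df)
    day = df["day"].to_numpy(dtype=float)
    df["age"] = np.round(
        rng.normal(params.age_mean + _drift_slope(params, "age") * day, params.age_sd), 1
    ).clip(18.0, 110.0)
    p_female = expit(logit(params.prop_female) + _drift_slope(params, "sex") * day)
    df["sex"] = (rng.random(n) < p_female).astype(int)  # 1 = female
    df["simd"] = rng.choice(np.arange(1, 6), size=n, p=np.asarray(params.simd_probs))
    for col, prev in zip(HISTORY_COLUMNS, params.history_prevalences):
        if prev in (0.0, 1.0):
            p = np.full(n, prev)
        else:
            p = expit(logit(prev) + _drift_slope(params, col) * day)
        df[col] = (rng.random(n) < p).astype(int)
    return df


def _season_multiplier(params: CohortParams, seasons: np.ndarray) -> np.ndarray:
    lut = dict(zip(_SEASON_ORDER, params.los_season_multipliers))
    return np.array([lut[s] for s in seasons])


def _fill_los(df: pd.DataFrame, params: CohortParams, rng: np.random.Generator):
    n = len(df)
    day = df["day"].to_numpy(dtype=float)
    months = pd.DatetimeIndex(df["_date"]).month if "_date" in df else None
    seasons = df["season"].to_numpy()
    mu = (
        params.los_log_mean
        + np.log(params.los_intervention_multiplier) * (df["condition"].to_numpy() == INTERVENTION)
        + np.log(_season_multiplier(params, seasons))
        + params.los_secular_slope * day
    )
    los = np.exp(rng.normal(mu, params.los_log_sd))
    if params.los_missing_fraction > 0:
        mask = rng.random(n) < params.los_missing_fraction
        los = np.where(mask, np.nan, los)
    df["los_hours"] = np.round(los, 2)
    return df


def _safety_linpred(df: pd.DataFrame, params: CohortParams, site_effects: dict):
    day = df["day"].to_numpy(dtype=float)
    u = df["site"].map(site_effects).to_numpy(dtype=float)
    return (
        params.safety_baseline_logit
        + u
        + params.safety_intervention_log_or * (df["condition"].to_numpy() == INTERVENTION)
        + params.safety_secular_slope * day
    )


# ----------------------------------------------------------------------
# Parametric mode
# ----------------------------------------------------------------------

def generate_parametric(
    design: TrialDesign,
    params: CohortParams | None = None,
    n: int = 31492,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw ``n`` presentations from the parametric cohort model.

    Presentation days are uniform over the study window (continuous
    recruitment) with sites drawn from ``site_weights``; condition follows
    each site's actual crossover day.  Reproducible for a fixed seed.
    """
    params = (params or CohortParams()).validate()
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    weights = params.site_weights
    if weights is None:
        weights = np.full(len(design.site_ids), 1.0 / len(design.site_ids))
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    sites = rng.choice(np.asarray(design.site_ids, dtype=object), size=n, p=weights)
    days = rng.integers(design.study_start_day, design.study_end_day, size=n)

    df = pd.DataFrame({"site": sites, "day": days})
    df = derive(df, design)
    df = _fill_covariates(df, params, rng)
    df = _fill_los(df, params, rng)
    site_effects = dict(
        zip(design.site_ids, rng.normal(0.0, params.safety_site_sd, len(design.site_ids)))
    )
    eta = _safety_linpred(df, params, site_effects)
    df["safety_event"] = (rng.random(n) < expit(eta)).astype(int)
    df["synthetic"] = 0
    return df[DATASET_COLUMNS].reset_index(drop=True)


# ----------------------------------------------------------------------
# Replica mode
# ----------------------------------------------------------------------

def _uniform_days(rng, lo, hi, size):
    """Uniform integer days over [lo, hi); hi > lo required."""
    return rng.integers(lo, hi, size=size)


def generate_replica(
    design: TrialDesign,
    counts: ReplicaCounts | None = None,
    params: CohortParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a dataset reproducing the phase-level count identities exactly.

    Phase denominators, phase event totals and the randomisation-phase
    condition split are forced; events are spread over cluster periods by a
    seeded draw proportional to denominators (the true cluster-period table
    is not reconstructable); covariates and length of stay are filled from
    the parametric model.
    """
    counts = (counts or ReplicaCounts()).validate()
    params = (params or CohortParams()).validate()
    rng = np.random.default_rng(seed)

    n_sites = len(design.site_ids)
    site_arr = np.asarray(design.site_ids, dtype=object)
    cross = design.crossover_days("actual")
    frames = []

    # Validation phase: all control.
    n_val = counts.phase_denominators[0]
    frames.append(pd.DataFrame({
        "site": rng.choice(site_arr, size=n_val),
        "day": _uniform_days(rng, design.study_start_day, design.validation_end_day, n_val),
    }))

    # Randomisation phase: force the condition split.  Control records are
    # placed in [phase start, site crossover), intervention records in
    # [crossover, phase end); sites are drawn proportional to the length of
    # the relevant window so every record is feasible.
    _, n_int = counts.randomisation_intervention
    _, n_ctl = counts.randomisation_control
    ctl_span = np.array([cross[s] - design.validation_end_day for s in design.site_ids], dtype=float)
    int_span = np.array([design.randomisation_end_day - cross[s] for s in design.site_ids], dtype=float)
    ctl_sites = rng.choice(site_arr, size=n_ctl, p=ctl_span / ctl_span.sum())
    int_sites = rng.choice(site_arr, size=n_int, p=int_span / int_span.sum())
    ctl_lo = np.full(n_ctl, design.validation_end_day)
    ctl_hi = np.array([cross[s] for s in ctl_sites])
    int_lo = np.array([cross[s] for s in int_sites])
    int_hi = np.full(n_int, design.randomisation_end_day)
    frames.append(pd.DataFrame({
        "site": ctl_sites,
        "day": rng.integers(ctl_lo, ctl_hi),
    }))
    frames.append(pd.DataFrame({
        "site": int_sites,
        "day": rng.integers(int_lo, int_hi),
    }))

    # Implementation phase: all intervention.
    n_imp = counts.phase_denominators[2]
    frames.append(pd.DataFrame({
        "site": rng.choice(site_arr, size=n_imp),
        "day": _uniform_days(rng, design.randomisation_end_day, design.study_end_day, n_imp),
    }))

    df = pd.concat(frames, ignore_index=True)
    df = derive(df, design)
    df["safety_event"] = 0

    # Allocate events: exact totals per stratum via seeded sampling without
    # replacement (equivalent to a multinomial over cluster periods
    # proportional to denominators).  If a spike is configured, its events
    # are carved out of the randomisation-phase intervention total first so
    # the grand totals still hold exactly.
    rand_int_mask = (
        (df["phase"] == "randomisation") & (df["condition"] == INTERVENTION)
    ).to_numpy()
    event_idx = []
    n_rand_int = counts.randomisation_intervention[0]
    if counts.spike is not None:
        site, month, k_spike = counts.spike
        in_cell = (
            (df["site"].to_numpy() == site) & (df["month_index"].to_numpy() == month)
        )
        cell_pool = np.flatnonzero(in_cell & rand_int_mask)
        if cell_pool.size < k_spike:
            raise ValueError(
                f"spike cell ({site}, month {month}) has only {cell_pool.size} "
                f"intervention-condition presentations in the randomisation phase; "
                f"cannot hold {k_spike} events"
            )
        event_idx.append(rng.choice(cell_pool, size=k_spike, replace=False))
        rand_int_mask = rand_int_mask & ~in_cell
        n_rand_int -= k_spike
    else:
        in_cell = np.zeros(len(df), dtype=bool)
    strata = [
        ((df["phase"] == "validation").to_numpy(), counts.phase_events[0]),
        (rand_int_mask, n_rand_int),
        (
            (
                (df["phase"] == "randomisation") & (df["condition"] == CONTROL)
            ).to_numpy()
            & ~in_cell,
            counts.randomisation_control[0],
        ),
        ((df["phase"] == "implementation").to_numpy(), counts.phase_events[2]),
    ]
    for mask, n_events in strata:
        pool = np.flatnonzero(mask)
        event_idx.append(rng.choice(pool, size=n_events, replace=False))
    df.loc[np.concatenate(event_idx), "safety_event"] = 1

    df = _fill_covariates(df, params, rng)
    df = _fill_los(df, params, rng)
    df["synthetic"] = 0
    return df[DATASET_COLUMNS].reset_index(drop=True)


def default_spike(design: TrialDesign) -> tuple:
    """A sensible default spike cell: the first site's first full
    intervention month inside the randomisation phase, 7 events."""
    site = design.site_ids[0]
    month = design.month_index(design.actual_crossover_day[site])
    return (site, month, 7)


def inject_spike(
    df: pd.DataFrame,
    design: TrialDesign,
    site,
    month_index: int,
    target_events: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Set one cluster period's event count to ``target_events`` exactly.

    Relabels ``safety_event`` within the (site, calendar month) cell by a
    seeded draw; all other cells are untouched, so the dataset's total event
    count changes by the difference in that one cell.
    """
    rng = np.random.default_rng(seed)
    out = df.copy()
    months = design.month_index(out["day"].to_numpy())
    cell = np.flatnonzero((out["site"].to_numpy() == site) & (months == month_index))
    if cell.size == 0:
        raise ValueError(f"cluster period ({site}, month {month_index}) has no presentations")
    if target_events < 0 or target_events > cell.size:
        raise ValueError(
            f"target of {target_events} events infeasible for a cluster period "
            f"with {cell.size} presentations"
        )
    current = int(out.loc[cell, "safety_event"].sum())
    if current == target_events:
        return out
    if target_events > current:
        pool = cell[out.loc[cell, "safety_event"].to_numpy() == 0]
        flip = rng.choice(pool, size=target_events - current, replace=False)
        out.loc[flip, "safety_event"] = 1
    else:
        pool = cell[out.loc[cell, "safety_event"].to_numpy() == 1]
        flip = rng.choice(pool, size=current - target_events, replace=False)
        out.loc[flip, "safety_event"] = 0
    return out


__all__ = [
    "CohortParams", "ReplicaCounts", "generate_parametric", "generate_replica",
    "inject_spike", "default_spike",
]
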