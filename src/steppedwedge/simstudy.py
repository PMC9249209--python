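"""Simulation assessment of the primary safety model under the trial design.

Repeatedly generates cohorts from the parametric model, fits the primary
(code A) safety analysis to each, and aggregates type-I error (null runs),
bias of the log odds ratio and 95% CI coverage, each with a Monte-Carlo
standard error.  Scenario knobs (event rate, between-site SD, cohort size,
secular slope, cluster-period spikes via the replica generator) make this a
stress-testing harness for few-cluster, sparse-event stepped-wedge designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .analyses import run_analysis
from .cohort import CohortParams, generate_parametric
from .design import TrialDesign

_Z95 = float(norm.ppf(0.975))


@dataclass
class SimStudyResult:
    """Aggregated operating characteristics of a simulation study."""

    reps: int                      # converged replicates included
    truth: float                   # true log OR
    type1_error: float | None      # fraction with two-sided Wald p < 0.05
    bias: float                    # mean(log OR estimate) - truth
    coverage: float                # fraction of 95% CIs covering the truth
    mc_se: dict = field(default_factory=dict)
    mean_ci_width: float = float("nan")   # mean log-scale CI width
    n_nonconverged: int = 0
    estimates: np.ndarray | None = None

    def to_frame(self):
        rows = [
            ("reps", self.reps, np.nan),
            ("truth_log_or", self.truth, np.nan),
            ("type1_error", self.type1_error, self.mc_se.get("type1_error")),
            ("bias", self.bias, self.mc_se.get("bias")),
            ("coverage", self.coverage, self.mc_se.get("coverage")),
            ("mean_ci_width", self.mean_ci_width, np.nan),
            ("n_nonconverged", self.n_nonconverged, np.nan),
        ]
        return pd.DataFrame(rows, columns=["metric", "value", "mc_se"])


def _prop_mc_se(f, n):
    return float(np.sqrt(max(f * (1 - f), 0.0) / n)) if n else float("nan")


def recovery_study(
    design: TrialDesign,
    params: CohortParams | None = None,
    true_log_or: float = 0.0,
    reps: int = 500,
    seed: int = 0,
    *,
    n: int = 31492,
    code: str = "A",
    method: str = "laplace",
    keep_estimates: bool = False,
) -> SimStudyResult:
    """Bias / coverage / rejection-rate study at a given true log OR.

    Each replicate generates a fresh cohort with the intervention log OR set
    to ``true_log_or`` and fits the ``code`` safety model.  Replicates whose
    fit does not converge are excluded and counted; more than 10%
    non-convergence aborts with diagnostics.
    """
    params = params or CohortParams()
    seeds = np.random.SeedSequence(seed).generate_state(reps) % (2 ** 31)
    est, se = [], []
    n_bad = 0
    for r in range(reps):
        rep_params = CohortParams(**{**params.__dict__,
                                     "safety_intervention_log_or": float(true_log_or)})
        df = generate_parametric(design, rep_params, n=n, seed=int(seeds[r]))
        try:
            fit = run_analysis(df, design, code, "none", outcome="safety", method=method)
        except Exception:
            n_bad += 1
            continue
        if not fit.converged or not np.isfinite(fit.effect["log_se"]):
            n_bad += 1
            continue
        est.append(fit.effect["log_estimate"])
        se.append(fit.effect["log_se"])
    if n_bad > 0.10 * reps:
        raise RuntimeError(
            f"{n_bad}/{reps} replicates failed to converge; the scenario is "
            "too extreme for the fitted model (check the event rate and n)"
        )
    est, se = np.asarray(est), np.asarray(se)
    m = len(est)
    reject_null = np.abs(est) / se > _Z95       # two-sided Wald test of log OR = 0
    cover = np.abs(est - true_log_or) / se <= _Z95
    bias = float(est.mean() - true_log_or)
    result = SimStudyResult(
        reps=m,
        truth=float(true_log_or),
        type1_error=float(reject_null.mean()) if true_log_or == 0 else None,
        bias=bias,
        coverage=float(cover.mean()),
        mean_ci_width=float((2 * _Z95 * se).mean()),
        n_nonconverged=n_bad,
        mc_se={
            "type1_error": _prop_mc_se(float(reject_null.mean()), m),
            "coverage": _prop_mc_se(float(cover.mean()), m),
            "bias": float(est.std(ddof=1) / np.sqrt(m)) if m > 1 else float("nan"),
        },
        estimates=est if keep_estimates else None,
    )
    return result


def simulate_null_study(
    design: TrialDesign,
    params: CohortParams | None = None,
    reps: int = 500,
    seed: int = 0,
    **kwargs,
) -> SimStudyResult:
    """Null (no intervention effect) study: type-I error and bias of the
    primary safety model."""
    params = params or CohortParams()
    if params.safety_intervention_log_or != 0.0:
        raise ValueError("the null study requires safety_intervention_log_or = 0")
    return recovery_study(design, params, true_log_or=0.0, reps=reps, seed=seed, **kwargs)


__all__ = ["SimStudyResult", "simulate_null_study", "recovery_study"]
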