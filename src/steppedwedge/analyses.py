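"""Declarative catalogue of the trial analyses and adjustment methods.

Eleven analysis models, A through K, share one backbone — a mixed model of
the outcome on an intervention indicator with a site random intercept — and
differ in analysis population, crossover timing source, secular-trend term,
season terms, exposure-time term and random-effect structure:

======  ====================  =======  ============  ======  ========  ====================
code    population            timing   time trend    season  exposure  random effects
======  ====================  =======  ============  ======  ========  ====================
A       full                  actual   linear        on      none      intercept
B       calendar matched      actual   none          off     none      intercept
C       full                  actual   linear        on      none      intercept+intervention
D       randomisation phase   actual   linear        on      none      intercept
E       full                  planned  linear        on      none      intercept
F       full                  actual   linear        on      none      intercept+time
G       full                  actual   linear        on      linear    intercept
H       full                  actual   cubic spline  on      none      intercept
I       full                  actual   cubic spline  on      spline    intercept
J       full                  actual   categorical   off     none      intercept
K       full                  actual   categorical   off     spline    intercept
======  ====================  =======  ============  ======  ========  ====================

Four covariate-adjustment methods can be layered on any of them: direct
adjustment for demographics (AFD: age, sex, SIMD), direct adjustment for the
full 13-variable history + demographics list (AMC), regression adjustment
for the logit of a propensity score (APS), and inverse probability of
treatment weighting (IPTW) with weight ``w = Z/p + (1 - Z)/(1 - p)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .design import (
    CONTROL, INTERVENTION, DEMOGRAPHIC_COVARIATES, FULL_COVARIATES,
    POPULATION_FILTERS, SEASONS, SEASON_REFERENCE, TrialDesign, derive,
    enrolment_midpoint,
)
from .glmm import (
    DesignMatrices, FitResult, fit_lmm, fit_logistic_glmm,
    natural_cubic_spline_basis, wald_ci,
)

#: Internal time scale: days are divided by this before entering design
#: matrices so that time coefficients are O(1) for the optimiser.
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one analysis model (one row of the catalogue)."""

    code: str
    outcome: str = "safety"                    # 'los' or 'safety'
    population: str = "full"                   # full | calendar_matched | randomisation_phase
    timing: str = "actual"                     # actual | planned
    time_trend: str = "linear"                 # linear | spline | categorical_3mo | none
    season: bool = True
    exposure: str = "none"                     # none | linear | spline
    random: str = "intercept"                  # intercept | intercept+intervention | intercept+time

    def for_outcome(self, outcome):
        return replace(self, outcome=outcome)


def _catalogue():
    A = ModelSpec("A")
    return {
        "A": A,
        "B": replace(A, code="B", population="calendar_matched", time_trend="none", season=False),
        "C": replace(A, code="C", random="intercept+intervention"),
        "D": replace(A, code="D", population="randomisation_phase"),
        "E": replace(A, code="E", timing="planned"),
        "F": replace(A, code="F", random="intercept+time"),
        "G": replace(A, code="G", exposure="linear"),
        "H": replace(A, code="H", time_trend="spline"),
        "I": replace(A, code="I", time_trend="spline", exposure="spline"),
        "J": replace(A, code="J", time_trend="categorical_3mo", season=False),
        "K": replace(A, code="K", time_trend="categorical_3mo", season=False, exposure="spline"),
    }


MODEL_CATALOGUE = _catalogue()
MODEL_CODES = tuple(MODEL_CATALOGUE)

ADJUSTMENT_METHODS = ("none", "AFD", "AMC", "APS", "IPTW")


@dataclass(frozen=True)
class AdjustmentSpec:
    """Covariate-adjustment method and its covariate list."""

    method: str = "none"
    covariates: tuple = ()

    @classmethod
    def of(cls, method):
        method = method if method == "none" else method.upper()
        if method not in ADJUSTMENT_METHODS:
            raise ValueError(f"unknown adjustment method {method!r}; "
                             f"choose from {ADJUSTMENT_METHODS}")
        if method == "none":
            return cls("none", ())
        if method == "AFD":
            return cls("AFD", tuple(DEMOGRAPHIC_COVARIATES))
        return cls(method, tuple(FULL_COVARIATES))


@dataclass
class PSResult:
    """Propensity scores, their logits and IPTW weights."""

    p: np.ndarray
    logit_p: np.ndarray
    w: np.ndarray
    Z: np.ndarray
    fit: FitResult | None = None


# ----------------------------------------------------------------------
# Design-matrix assembly
# ----------------------------------------------------------------------

def _season_dummies(season):
    """Dummy-code season over the levels present in the population.

    Winter is the reference when present; in restricted populations that
    lack it (e.g. the randomisation phase spans spring and summer only) the
    first present season is the reference, as factor coding would do."""
    season = np.asarray(season)
    present = [s for s in SEASONS if (season == s).any()]
    ref = SEASON_REFERENCE if SEASON_REFERENCE in present else present[0]
    cols, names = [], []
    for s in present:
        if s == ref:
            continue
        cols.append((season == s).astype(float))
        names.append(f"season_{s}")
    return cols, names


def _categorical_periods(df, design, months_per_period=3):
    """Dummies for calendar periods of ``months_per_period`` months from
    study start; the first period present in the population is the
    reference."""
    period = df["month_index"].to_numpy() // months_per_period
    present = np.unique(period)
    cols, names = [], []
    for k in present[1:]:
        cols.append((period == k).astype(float))
        names.append(f"period_{int(k)}")
    return cols, names


N_SPLINE_KNOTS = 3  # interior knots at quantiles; configurable per call


def build_design(
    df: pd.DataFrame,
    design: TrialDesign,
    spec: ModelSpec,
    adjustment: AdjustmentSpec | str = "none",
    *,
    logit_p: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    n_spline_knots: int = N_SPLINE_KNOTS,
    intercept: bool = True,
    extra_columns: dict | None = None,
) -> DesignMatrices:
    """Assemble the fixed- and random-effect design for one analysis.

    ``df`` must already carry the derived columns (see
    :func:`steppedwedge.design.derive`) for the correct timing source and be
    restricted to the analysis population.  APS adjustment requires
    ``logit_p``; IPTW requires ``weights``.
    """
    if isinstance(adjustment, str):
        adjustment = AdjustmentSpec.of(adjustment)
    n = len(df)
    cols, names = [], []
    if intercept:
        cols.append(np.ones(n)); names.append("intercept")
    if extra_columns:
        for nm, col in extra_columns.items():
            cols.append(np.asarray(col, dtype=float)); names.append(nm)
    cols.append((df["condition"].to_numpy() == INTERVENTION).astype(float))
    names.append("intervention")

    if spec.season:
        c, nm = _season_dummies(df["season"].to_numpy())
        cols += c; names += nm

    time_years = None
    if spec.time_trend == "linear":
        mid = enrolment_midpoint(df["day"].to_numpy())
        time_years = (df["day"].to_numpy() - mid) / DAYS_PER_YEAR
        cols.append(time_years); names.append("time")
    elif spec.time_trend == "spline":
        mid = enrolment_midpoint(df["day"].to_numpy())
        time_years = (df["day"].to_numpy() - mid) / DAYS_PER_YEAR
        basis = natural_cubic_spline_basis(time_years, n_spline_knots)
        for k in range(basis.shape[1]):
            cols.append(basis[:, k]); names.append(f"time_ns{k + 1}")
    elif spec.time_trend == "categorical_3mo":
        c, nm = _categorical_periods(df, design)
        cols += c; names += nm
    elif spec.time_trend != "none":
        raise ValueError(f"unknown time trend {spec.time_trend!r}")

    if spec.exposure == "linear":
        cols.append(df["exposure_days"].to_numpy() / DAYS_PER_YEAR)
        names.append("exposure")
    elif spec.exposure == "spline":
        expo = df["exposure_days"].to_numpy() / DAYS_PER_YEAR
        pos = expo[expo > 0]
        knots = np.quantile(pos, np.linspace(0, 1, n_spline_knots + 2)[1:-1]) if pos.size else None
        basis = natural_cubic_spline_basis(expo, n_spline_knots, knots=knots)
        for k in range(basis.shape[1]):
            cols.append(basis[:, k]); names.append(f"exposure_ns{k + 1}")
    elif spec.exposure != "none":
        raise ValueError(f"unknown exposure term {spec.exposure!r}")

    if adjustment.method in ("AFD", "AMC"):
        for cname in adjustment.covariates:
            if cname not in df.columns:
                raise ValueError(f"adjustment covariate {cname!r} not in the dataset")
            cols.append(df[cname].to_numpy(dtype=float)); names.append(cname)
    elif adjustment.method == "APS":
        if logit_p is None:
            raise ValueError("APS adjustment requires propensity-score logits")
        cols.append(np.asarray(logit_p, dtype=float)); names.append("logit_ps")
    elif adjustment.method == "IPTW":
        if weights is None:
            raise ValueError("IPTW adjustment requires weights")

    if spec.outcome == "los":
        keep = df["los_hours"].notna().to_numpy()
        y = np.log(df.loc[keep, "los_hours"].to_numpy(dtype=float))
    elif spec.outcome == "safety":
        keep = np.ones(n, dtype=bool)
        y = df["safety_event"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown outcome {spec.outcome!r}")

    X = np.column_stack(cols)[keep]
    site_codes, site_labels = pd.factorize(df["site"], sort=True)

    z_spec = "intercept"
    if spec.random == "intercept+intervention":
        z_spec = "intercept+intervention"
    elif spec.random == "intercept+time":
        if "time" not in names:
            raise ValueError("a random time slope requires a linear time term")
        z_spec = "intercept+time"
    elif spec.random != "intercept":
        raise ValueError(f"unknown random-effect structure {spec.random!r}")

    w = None if weights is None else np.asarray(weights, dtype=float)[keep]
    return DesignMatrices(
        X=X, columns=names, y=y, cluster_index=site_codes[keep],
        cluster_labels=list(site_labels), Z_spec=z_spec, weights=w,
    )


# ----------------------------------------------------------------------
# Propensity scores
# ----------------------------------------------------------------------

PS_TRIM = 1e-6


def estimate_propensity(
    df: pd.DataFrame,
    covariates=None,
    *,
    trim: float = PS_TRIM,
    truncate_weights: float | None = None,
) -> PSResult:
    """Random-intercept (site) logistic model of condition on covariates.

    Fitted probabilities are trimmed to ``[trim, 1 - trim]``; IPTW weights
    are ``Z/p + (1 - Z)/(1 - p)``.  Must be re-estimated whenever the
    analysis population is restricted.
    """
    covariates = list(covariates) if covariates is not None else list(FULL_COVARIATES)
    Z = (df["condition"].to_numpy() == INTERVENTION).astype(float)
    if len(np.unique(Z)) < 2:
        raise ValueError("propensity estimation needs both conditions present")
    cols = [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates]
    site_codes, site_labels = pd.factorize(df["site"], sort=True)
    dm = DesignMatrices(
        X=np.column_stack(cols), columns=["intercept"] + covariates, y=Z,
        cluster_index=site_codes, cluster_labels=list(site_labels),
    )
    fit = fit_logistic_glmm(dm, method="laplace")
    eta = dm.X @ fit.beta.to_numpy()
    p = np.clip(expit(eta), trim, 1 - trim)
    w = Z / p + (1 - Z) / (1 - p)
    if truncate_weights is not None:
        w = np.minimum(w, np.quantile(w, truncate_weights))
    return PSResult(p=p, logit_p=logit(p), w=w, Z=Z, fit=fit)


# ----------------------------------------------------------------------
# End-to-end runner
# ----------------------------------------------------------------------

def _default_method(spec: ModelSpec) -> str:
    # Adaptive quadrature for the pre-specified scalar-random-effect safety
    # models; Laplace for the post-hoc models and wherever a random slope
    # makes the integral multi-dimensional.
    if spec.random != "intercept":
        return "laplace"
    return "agq" if spec.code in ("A", "B", "D", "E") else "laplace"


def prepare_population(df, design, spec: ModelSpec):
    """Filter to the analysis population and derive columns for the spec's
    timing source."""
    work = df.loc[df["synthetic"] == 0] if "synthetic" in df.columns else df
    work = POPULATION_FILTERS[spec.population](work, design)
    if work.empty:
        raise ValueError(f"analysis population {spec.population!r} is empty")
    return derive(work, design, timing=spec.timing)


def run_analysis(
    df: pd.DataFrame,
    design: TrialDesign,
    code: str,
    adjustment="none",
    *,
    outcome: str = "safety",
    method: str | None = None,
    n_nodes: int = 25,
    ps: PSResult | None = None,
) -> FitResult:
    """Run one (analysis code, adjustment) pair end to end.

    Applies the population filter and timing source, estimates the
    propensity score on the analysis population when needed, assembles the
    design, fits the mixed model and attaches the effect on the OR (safety)
    or GMR (log length-of-stay) scale.
    """
    spec = MODEL_CATALOGUE[code].for_outcome(outcome)
    adj = AdjustmentSpec.of(adjustment) if isinstance(adjustment, str) else adjustment
    work = prepare_population(df, design, spec)

    logit_p = weights = None
    if adj.method in ("APS", "IPTW"):
        if ps is None:
            ps = estimate_propensity(work, adj.covariates)
        if adj.method == "APS":
            logit_p = ps.logit_p
        else:
            weights = ps.w
    dm = build_design(work, design, spec, adj, logit_p=logit_p, weights=weights)

    label = f"{code}-{adj.method}" if adj.method != "none" else code
    try:
        if spec.outcome == "los":
            fit = fit_lmm(dm)
        else:
            fit = fit_logistic_glmm(dm, method or _default_method(spec), n_nodes)
    except Exception as err:
        raise RuntimeError(f"analysis {label} failed to fit: {err}") from err
    fit.label = label
    if not fit.converged:
        import logging
        logging.getLogger("steppedwedge").warning("analysis %s did not converge", label)
    return fit


def run_suite(
    df, design, codes=MODEL_CODES, adjustments=ADJUSTMENT_METHODS,
    outcome="safety", method=None,
):
    """Run the full (code x adjustment) grid; returns labelled FitResults.

    The propensity fit is shared across codes with the same analysis
    population (it only depends on the population, not the model)."""
    results = []
    ps_cache = {}
    for code in codes:
        spec = MODEL_CATALOGUE[code].for_outcome(outcome)
        for adjustment in adjustments:
            adj = AdjustmentSpec.of(adjustment)
            ps = None
            if adj.method in ("APS", "IPTW"):
                key = (spec.population, spec.timing)
                if key not in ps_cache:
                    work = prepare_population(df, design, spec)
                    ps_cache[key] = estimate_propensity(work, adj.covariates)
                ps = ps_cache[key]
            results.append(
                run_analysis(df, design, code, adj, outcome=outcome, method=method, ps=ps)
            )
    return results


# ----------------------------------------------------------------------
# Effect summaries
# ----------------------------------------------------------------------

def approximate_risk_difference(fit: FitResult, dm: DesignMatrices, level=0.95):
    """Average marginal effect of the intervention on the risk scale (%).

    Mean over patients of the model probability with the intervention
    indicator set to 1 minus that with it set to 0 (random effects at their
    population value of zero), with a delta-method CI.
    """
    if fit.effect.get("scale") != "OR":
        raise ValueError("risk differences are defined for safety-outcome fits")
    j = dm.columns.index("intervention")
    beta = fit.beta.to_numpy()
    X1, X0 = dm.X.copy(), dm.X.copy()
    X1[:, j], X0[:, j] = 1.0, 0.0
    p1, p0 = expit(X1 @ beta), expit(X0 @ beta)
    rd = float(np.mean(p1 - p0))
    grad = (X1 * (p1 * (1 - p1))[:, None] - X0 * (p0 * (1 - p0))[:, None]).mean(axis=0)
    var = float(grad @ fit.cov_beta.to_numpy() @ grad)
    se = np.sqrt(max(var, 0.0))
    z = abs(norm.ppf((1 - level) / 2))
    return 100 * rd, 100 * (rd - z * se), 100 * (rd + z * se)


def forest_table(results, reference_code: str = "A") -> pd.DataFrame:
    """Plot-ready effect table, ordered by code then adjustment.

    The ``divergent`` column flags results whose 95% CI does not overlap the
    reference (code-A, unadjusted) result on the same scale.
    """
    if not results:
        raise ValueError("no results to tabulate")
    rows = []
    for fit in results:
        eff = fit.effect
        rows.append({
            "label": fit.label or "fit",
            "scale": eff.get("scale", ""),
            "estimate": eff.get("estimate", np.nan),
            "ci_low": eff.get("ci_low", np.nan),
            "ci_high": eff.get("ci_high", np.nan),
            "n_used": fit.n_used,
            "converged": fit.converged,
        })
    tab = pd.DataFrame(rows)
    order = {c: i for i, c in enumerate(MODEL_CODES)}
    adj_order = {a: i for i, a in enumerate(ADJUSTMENT_METHODS)}

    def key(label):
        code, _, adj = label.partition("-")
        return (order.get(code, 99), adj_order.get(adj or "none", 99))

    tab = tab.sort_values("label", key=lambda s: s.map(key), kind="stable").reset_index(drop=True)
    tab["divergent"] = False
    for scale in tab["scale"].unique():
        ref = tab[(tab["label"] == reference_code) & (tab["scale"] == scale)]
        if ref.empty:
            continue
        lo, hi = float(ref["ci_low"].iloc[0]), float(ref["ci_high"].iloc[0])
        mask = tab["scale"] == scale
        tab.loc[mask, "divergent"] = (tab.loc[mask, "ci_low"] > hi) | (tab.loc[mask, "ci_high"] < lo)
    return tab


def plot_forest(tab: pd.DataFrame, path=None, title="Sensitivity analyses"):
    """Simple rendered forest plot of a :func:`forest_table` frame."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.35 * len(tab) + 1.5))
    ypos = np.arange(len(tab))[::-1]
    ax.errorbar(
        tab["estimate"], ypos,
        xerr=[tab["estimate"] - tab["ci_low"], tab["ci_high"] - tab["estimate"]],
        fmt="s", color="black", ecolor="grey", capsize=2, markersize=4,
    )
    ax.axvline(1.0, color="red", linestyle=":", linewidth=1)
    ax.set_yticks(ypos)
    ax.set_yticklabels(tab["label"])
    ax.set_xscale("log")
    ax.set_xlabel(f"effect ({'/'.join(tab['scale'].unique())}) with 95% CI")
    ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


__all__ = [
    "ModelSpec", "AdjustmentSpec", "PSResult", "MODEL_CATALOGUE", "MODEL_CODES",
    "ADJUSTMENT_METHODS", "build_design", "estimate_propensity", "run_analysis",
    "run_suite", "approximate_risk_difference", "forest_table", "plot_forest",
    "prepare_population",
]
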