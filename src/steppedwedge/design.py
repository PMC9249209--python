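"""Trial-design data model and deterministic derivations.

A stepped-wedge cluster randomised trial with continuous recruitment is
described by a :class:`TrialDesign`: a fixed set of sites (clusters), a study
window in integer days, three consecutive phases (validation / randomisation /
implementation) and, per site, the planned (randomised) and actual day on
which the site crossed over from the control pathway to the intervention
pathway.  Patient-level data live in a plain :class:`pandas.DataFrame` with
the column schema in :data:`DATASET_COLUMNS`; every derivation here
(condition assignment, season, centred time, exposure time, phase and
calendar-window filters, cluster-period tabulation) is a pure function of
that frame plus the design.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("steppedwedge")

CONTROL = "control"
INTERVENTION = "intervention"

SEASONS = ("Winter", "Spring", "Summer", "Autumn")
#: Winter is the reference level for dummy coding.
SEASON_REFERENCE = "Winter"
_MONTH_TO_SEASON = {
    12: "Winter", 1: "Winter", 2: "Winter",
    3: "Spring", 4: "Spring", 5: "Spring",
    6: "Summer", 7: "Summer", 8: "Summer",
    9: "Autumn", 10: "Autumn", 11: "Autumn",
}

PHASES = ("validation", "randomisation", "implementation")

HISTORY_COLUMNS = [
    "hx_ihd",        # prior ischaemic heart disease
    "hx_mi",         # prior myocardial infarction
    "hx_cvd",        # prior cerebrovascular disease
    "hx_diabetes",
    "hx_pci",        # percutaneous coronary intervention
    "hx_cabg",       # coronary artery bypass grafting
    "hx_aspirin",
    "hx_lipid",      # lipid-lowering drugs
    "hx_beta_blocker",
    "hx_ace_inhibitor",
]

#: Fixed column schema for patient-level datasets (CSV round-trippable).
DATASET_COLUMNS = (
    ["site", "day", "age", "sex", "simd"]
    + HISTORY_COLUMNS
    + ["los_hours", "safety_event", "synthetic"]
)

#: Covariates for the "adjusted for demographics" method.
DEMOGRAPHIC_COVARIATES = ["age", "sex", "simd"]
#: The 13-variable covariate list used for direct multiple-covariate
#: adjustment and for propensity-score estimation.
FULL_COVARIATES = HISTORY_COLUMNS + ["age", "sex", "simd"]


@dataclass(frozen=True)
class TrialDesign:
    """Sites, crossover days, phase boundaries and the calendar anchor.

    Days are integer offsets from ``calendar_origin`` (day 0).  Phases are
    half-open: validation ``[study_start_day, validation_end_day)``,
    randomisation ``[validation_end_day, randomisation_end_day)`` and
    implementation ``[randomisation_end_day, study_end_day)``.
    """

    site_ids: tuple
    actual_crossover_day: dict
    planned_crossover_day: dict
    validation_end_day: int
    randomisation_end_day: int
    study_start_day: int = 0
    study_end_day: int = 730
    calendar_origin: _dt.date = _dt.date(2018, 6, 1)

    def __post_init__(self):
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        if len(self.site_ids) != 7:
            raise ValueError(f"expected exactly 7 sites, got {len(self.site_ids)}")
        if len(set(self.site_ids)) != 7:
            raise ValueError("site_ids must be distinct")
        for mapping, name in [
            (self.actual_crossover_day, "actual_crossover_day"),
            (self.planned_crossover_day, "planned_crossover_day"),
        ]:
            missing = set(self.site_ids) - set(mapping)
            if missing:
                raise ValueError(f"{name} missing sites {sorted(missing)}")
        if not (
            self.study_start_day
            <= self.validation_end_day
            <= self.randomisation_end_day
            <= self.study_end_day
        ):
            raise ValueError("phase boundaries must be ordered within the study window")
        for s in self.site_ids:
            c = self.actual_crossover_day[s]
            if not (self.validation_end_day <= c <= self.randomisation_end_day):
                raise ValueError(
                    f"site {s}: actual crossover day {c} outside the randomisation "
                    f"phase [{self.validation_end_day}, {self.randomisation_end_day}]"
                )
        n_steps = len(set(self.planned_crossover_day.values()))
        if n_steps != 3:
            raise ValueError(
                f"planned crossover days must take exactly 3 distinct values "
                f"(the randomised steps); got {n_steps}"
            )

    # -- calendar ------------------------------------------------------
    def date_of(self, day):
        """Calendar date(s) for integer day offset(s) from the origin."""
        origin = pd.Timestamp(self.calendar_origin)
        if np.isscalar(day):
            return (origin + pd.Timedelta(days=int(day))).date()
        return origin + pd.to_timedelta(np.asarray(day, dtype=int), unit="D")

    def month_index(self, day):
        """Calendar-month index (months since the origin month) of day(s)."""
        dates = pd.DatetimeIndex(
            pd.Timestamp(self.calendar_origin)
            + pd.to_timedelta(np.atleast_1d(np.asarray(day, dtype=int)), unit="D")
        )
        origin = self.calendar_origin
        idx = (dates.year - origin.year) * 12 + (dates.month - origin.month)
        return idx.to_numpy() if not np.isscalar(day) else int(idx[0])

    def crossover_days(self, timing="actual"):
        if timing == "actual":
            return dict(self.actual_crossover_day)
        if timing == "planned":
            return dict(self.planned_crossover_day)
        raise ValueError(f"timing must be 'actual' or 'planned', got {timing!r}")

    def phase_of(self, day):
        """Phase label(s) for integer day(s); half-open boundaries."""
        day = np.asarray(day)
        out = np.where(
            day < self.validation_end_day,
            "validation",
            np.where(day < self.randomisation_end_day, "randomisation", "implementation"),
        )
        return out if out.ndim else str(out)

    def to_dict(self):
        return {
            "site_ids": list(self.site_ids),
            "actual_crossover_day": {str(k): int(v) for k, v in self.actual_crossover_day.items()},
            "planned_crossover_day": {str(k): int(v) for k, v in self.planned_crossover_day.items()},
            "validation_end_day": int(self.validation_end_day),
            "randomisation_end_day": int(self.randomisation_end_day),
            "study_start_day": int(self.study_start_day),
            "study_end_day": int(self.study_end_day),
            "calendar_origin": self.calendar_origin.isoformat(),
        }

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if isinstance(d.get("calendar_origin"), str):
            d["calendar_origin"] = _dt.date.fromisoformat(d["calendar_origin"])
        d["site_ids"] = tuple(d["site_ids"])
        return cls(**d)


def default_design() -> TrialDesign:
    """The 7-site, 24-month, three-phase design used throughout.

    Day 0 is 1 June of the first study year.  The validation phase runs for
    9 months, the randomisation phase for 6 (during which every site crosses
    over), and the implementation phase for the remaining 9.  Four sites
    actually crossed over at the first crossover point, one at the second and
    two at the third; planned (randomised) crossover days take three distinct
    step values and differ from the actual days by one to two months at most
    sites.
    """
    sites = tuple(f"site_{i}" for i in range(1, 8))
    actual = dict(zip(sites, [304, 304, 304, 304, 365, 426, 426]))
    planned = dict(zip(sites, [334, 334, 365, 365, 396, 396, 365]))
    return TrialDesign(
        site_ids=sites,
        actual_crossover_day=actual,
        planned_crossover_day=planned,
        validation_end_day=273,
        randomisation_end_day=457,
        study_end_day=730,
        calendar_origin=_dt.date(2018, 6, 1),
    )


# ----------------------------------------------------------------------
# Deterministic derivations
# ----------------------------------------------------------------------

def assign_condition(day, crossover_day, *, study_start=0, study_end=730):
    """Condition of a presentation: intervention iff ``day >= crossover_day``.

    The crossover day itself counts as intervention — the new pathway is live
    from the implementation date.
    """
    day_arr = np.asarray(day)
    if np.any(day_arr < study_start) or np.any(day_arr > study_end):
        raise ValueError(
            f"presentation day outside the study window [{study_start}, {study_end}]"
        )
    out = np.where(day_arr >= np.asarray(crossover_day), INTERVENTION, CONTROL)
    return out if out.ndim else str(out)


def season_of(calendar_month):
    """Season of a calendar month (1-12): Winter = Dec-Feb (reference),
    Spring = Mar-May, Summer = Jun-Aug, Autumn = Sep-Nov."""
    m = np.atleast_1d(np.asarray(calendar_month, dtype=int))
    if np.any((m < 1) | (m > 12)):
        raise ValueError("calendar month must be in 1..12")
    out = np.array([_MONTH_TO_SEASON[int(x)] for x in m])
    return out if not np.isscalar(calendar_month) else str(out[0])


def centred_time(day, enrolment_mid):
    """Presentation day centred on the enrolment midpoint (days)."""
    return np.asarray(day, dtype=float) - float(enrolment_mid)


def enrolment_midpoint(days):
    """Midpoint of the min/max presentation day in an analysis population."""
    days = np.asarray(days, dtype=float)
    if days.size == 0:
        raise ValueError("cannot compute the enrolment midpoint of an empty population")
    return float((days.min() + days.max()) / 2.0)


def exposure_time(day, crossover_day):
    """Days since the site crossed over; 0 for control-condition records."""
    e = np.asarray(day, dtype=float) - np.asarray(crossover_day, dtype=float)
    out = np.maximum(e, 0.0)
    return out if out.ndim else float(out)


def derive(df: pd.DataFrame, design: TrialDesign, *, timing="actual") -> pd.DataFrame:
    """Attach derived columns: condition, phase, month index, calendar month,
    season, exposure time.  Record count is conserved."""
    out = df.copy()
    cross = out["site"].map(design.crossover_days(timing)).to_numpy()
    out["crossover_day"] = cross
    out["condition"] = assign_condition(
        out["day"].to_numpy(), cross,
        study_start=design.study_start_day, study_end=design.study_end_day,
    )
    out["phase"] = design.phase_of(out["day"].to_numpy())
    dates = design.date_of(out["day"].to_numpy())
    out["calendar_month"] = dates.month
    out["month_index"] = design.month_index(out["day"].to_numpy())
    out["season"] = season_of(out["calendar_month"].to_numpy())
    out["exposure_days"] = exposure_time(out["day"].to_numpy(), cross)
    return out


# ----------------------------------------------------------------------
# Population filters
# ----------------------------------------------------------------------

def filter_calendar_matched(
    df: pd.DataFrame,
    design: TrialDesign,
    *,
    window_start=(3, 3),      # (day, month): 3 March
    window_end=(3, 9),        # 3 September
    inclusive=True,
) -> pd.DataFrame:
    """Calendar-matched before/after population.

    Keeps validation- and implementation-phase records whose calendar date
    falls between 3 March and 3 September of any study year (boundaries
    inclusive by default); randomisation-phase records are always excluded.
    Idempotent.
    """
    phase = design.phase_of(df["day"].to_numpy())
    dates = design.date_of(df["day"].to_numpy())
    md = dates.month * 100 + dates.day  # sortable month-day key
    lo = window_start[1] * 100 + window_start[0]
    hi = window_end[1] * 100 + window_end[0]
    if inclusive:
        in_window = (md >= lo) & (md <= hi)
    else:
        in_window = (md > lo) & (md < hi)
    keep = np.asarray(in_window) & np.isin(phase, ["validation", "implementation"])
    out = df.loc[keep].copy()
    if out.empty:
        logger.warning("calendar-matched filter returned an empty population")
    return out


def filter_randomisation_phase(df: pd.DataFrame, design: TrialDesign) -> pd.DataFrame:
    """Records with validation_end_day <= day < randomisation_end_day."""
    day = df["day"].to_numpy()
    keep = (day >= design.validation_end_day) & (day < design.randomisation_end_day)
    return df.loc[keep].copy()


POPULATION_FILTERS = {
    "full": lambda df, design: df.copy(),
    "calendar_matched": filter_calendar_matched,
    "randomisation_phase": filter_randomisation_phase,
}


# ----------------------------------------------------------------------
# Cluster-period tabulation
# ----------------------------------------------------------------------

def tabulate_cluster_periods(df: pd.DataFrame, design: TrialDesign) -> pd.DataFrame:
    """Site x calendar-month table of safety events and denominators.

    Returns a frame with columns (site, month_index, events, denominator),
    one row per cluster period with at least one presentation.  Totals are
    conserved exactly: events sum to the dataset's event count, denominators
    to the dataset size.
    """
    if df.empty:
        return pd.DataFrame(columns=["site", "month_index", "events", "denominator"])
    work = df[["site", "day", "safety_event"]].copy()
    work["month_index"] = design.month_index(work["day"].to_numpy())
    tab = (
        work.groupby(["site", "month_index"], as_index=False)
        .agg(events=("safety_event", "sum"), denominator=("safety_event", "size"))
    )
    tab["events"] = tab["events"].astype(int)
    tab["denominator"] = tab["denominator"].astype(int)
    return tab.sort_values(["site", "month_index"]).reset_index(drop=True)


# ----------------------------------------------------------------------
# Dataset I/O
# ----------------------------------------------------------------------

def validate_dataset(df: pd.DataFrame, design: TrialDesign | None = None) -> None:
    """Check the fixed column schema and basic invariants; raise on failure."""
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing required columns: {missing}")
    los = df["los_hours"]
    if (los.dropna() <= 0).any():
        raise ValueError("los_hours must be positive where present")
    if not df["safety_event"].isin([0, 1]).all():
        raise ValueError("safety_event must be 0/1")
    if not df["synthetic"].isin([0, 1]).all():
        raise ValueError("synthetic must be 0/1")
    if design is not None:
        unknown = set(df["site"].unique()) - set(design.site_ids)
        if unknown:
            raise ValueError(f"dataset contains sites not in the design: {sorted(unknown)}")
        day = df["day"].to_numpy()
        if day.size and (day.min() < design.study_start_day or day.max() > design.study_end_day):
            raise ValueError("presentation days fall outside the study window")


def read_dataset(path, design: TrialDesign | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_dataset(df, design)
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    df.loc[:, DATASET_COLUMNS].to_csv(path, index=False)


__all__ = [
    "CONTROL", "INTERVENTION", "SEASONS", "SEASON_REFERENCE", "PHASES",
    "HISTORY_COLUMNS", "DATASET_COLUMNS", "DEMOGRAPHIC_COVARIATES",
    "FULL_COVARIATES", "TrialDesign", "default_design", "assign_condition",
    "season_of", "centred_time", "enrolment_midpoint", "exposure_time",
    "derive", "filter_calendar_matched", "filter_randomisation_phase",
    "POPULATION_FILTERS", "tabulate_cluster_periods", "validate_dataset",
    "read_dataset", "write_dataset", "replace",
]
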