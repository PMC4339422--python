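"""Arm-level trial data structures, the CSV dialect, and derived quantities.

A mixed treatment comparison (MTC) consumes aggregate, arm-level summaries
from parallel-group RCTs: one row per study-arm, carrying the arm's size,
withdrawals, study duration, population covariates, and an endpoint payload —
a mean change from baseline with its standard error for continuous endpoints
(FEV1 in litres, SGRQ in score units), or an exacerbation event count and/or
annualised rate for the Poisson endpoint.

This module defines the validated in-memory containers (:class:`ArmRecord`,
:class:`TrialDataset`), the CSV reader/writer for the documented dialect,
covariate centring against the model's reference profile, and the
reconstruction rules for person-years of follow-up and event counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mtcni")

ENDPOINTS = ("fev1", "sgrq", "exacerbation")
CONTINUOUS_ENDPOINTS = ("fev1", "sgrq")

FEV1_CATEGORIES = ("lt50", "50to70", "gt70", "missing")
EXAC_HISTORY_CATEGORIES = ("at_least_1", "at_least_2", "not_reported")

#: Centring constants for the continuous covariates: the model works with
#: age - 60 years, proportion male - 0.75 and proportion current smokers - 0.5.
AGE_CENTER = 60.0
MALE_CENTER = 0.75
SMOKER_CENTER = 0.5

#: Duration band cuts in weeks: <c0, [c0, c1), [c1, c2] (reference), >c2.
DEFAULT_DURATION_CUTS = (20.0, 40.0, 60.0)

#: Column order of a full covariate vector. The reference profile
#: (50-70% predicted FEV1, >=1 exacerbation in the previous year,
#: 40-60 weeks duration) maps to all-zero indicators.
FULL_COVARIATE_COLUMNS = (
    "age_c",
    "male_c",
    "smoker_c",
    "fev1_lt50",
    "fev1_gt70",
    "exac_ge2",
    "exac_not_reported",
    "dur_lt20",
    "dur_20to40",
    "dur_gt60",
)
DURATION_COVARIATE_COLUMNS = ("dur_lt20", "dur_20to40", "dur_gt60")

REQUIRED_COLUMNS = (
    "study_id",
    "treatment_id",
    "n_randomised",
    "n_withdrawn",
    "duration_weeks",
)
OPTIONAL_COLUMNS = (
    "treatment_label",
    "is_placebo",
    "mean_age_years",
    "prop_male",
    "prop_smokers",
    "fev1_pct_pred_cat",
    "exac_history_cat",
    "mean_change",
    "std_error",
    "n_events",
    "annual_rate",
    "person_years",
    "explicit_history_required",
    "rates_follow_up_adjusted",
)


class DataFormatError(ValueError):
    """The input file does not match the documented CSV dialect."""


class DataValidationError(ValueError):
    """The input violates a dataset invariant."""


@dataclass(frozen=True)
class TreatmentRegimen:
    """A treatment regimen node of the network (drug(s), dose, frequency)."""

    id: str
    label: str = ""
    is_placebo: bool = False


@dataclass(frozen=True)
class ContinuousPayload:
    """Arm-level mean change from baseline with its standard error."""

    mean_change: float
    std_error: float

    def __post_init__(self) -> None:
        if not self.std_error > 0:
            raise DataValidationError(
                f"std_error must be > 0, got {self.std_error}"
            )


@dataclass(frozen=True)
class CountPayload:
    """Arm-level exacerbation payload: events and/or annualised rate.

    At least one of ``n_events`` and ``annual_rate`` must be present;
    ``person_years`` may be reported directly.
    """

    n_events: int | None = None
    annual_rate: float | None = None
    person_years: float | None = None

    def __post_init__(self) -> None:
        if self.n_events is None and self.annual_rate is None:
            raise DataValidationError(
                "count payload needs n_events or annual_rate (or both)"
            )
        if self.person_years is not None and not self.person_years > 0:
            raise DataValidationError(
                f"person_years must be > 0, got {self.person_years}"
            )


@dataclass(frozen=True)
class ArmRecord:
    """One study-arm's sizes, covariates and endpoint payload(s)."""

    study_id: str
    treatment_id: str
    n_randomised: int
    n_withdrawn: int
    duration_weeks: float
    mean_age_years: float | None = None
    prop_male: float | None = None
    prop_smokers: float | None = None
    fev1_pct_pred_cat: str = "missing"
    exac_history_cat: str = "not_reported"
    continuous_payload: ContinuousPayload | None = None
    count_payload: CountPayload | None = None

    def __post_init__(self) -> None:
        if self.n_randomised < 10:
            raise DataValidationError(
                f"{self.study_id}/{self.treatment_id}: n_randomised must be "
                f">= 10, got {self.n_randomised}"
            )
        if self.n_withdrawn < 0 or self.n_withdrawn > self.n_randomised:
            raise DataValidationError(
                f"{self.study_id}/{self.treatment_id}: n_withdrawn "
                f"{self.n_withdrawn} outside [0, n_randomised]"
            )
        if not self.duration_weeks > 0:
            raise DataValidationError(
                f"{self.study_id}/{self.treatment_id}: duration_weeks must "
                "be positive"
            )
        if self.continuous_payload is None and self.count_payload is None:
            raise DataValidationError(
                f"{self.study_id}/{self.treatment_id}: at least one endpoint "
                "payload required"
            )
        for prop, name in ((self.prop_male, "prop_male"),
                           (self.prop_smokers, "prop_smokers")):
            if prop is not None and not (0.0 <= prop <= 1.0):
                raise DataValidationError(
                    f"{self.study_id}/{self.treatment_id}: {name} must lie "
                    f"in [0, 1], got {prop}"
                )
        if self.fev1_pct_pred_cat not in FEV1_CATEGORIES:
            raise DataValidationError(
                f"unknown fev1_pct_pred_cat {self.fev1_pct_pred_cat!r}"
            )
        if self.exac_history_cat not in EXAC_HISTORY_CATEGORIES:
            raise DataValidationError(
                f"unknown exac_history_cat {self.exac_history_cat!r}"
            )


@dataclass(frozen=True)
class CovariateVector:
    """Centred covariates of one arm (the Z vector of the linear predictor).

    Continuous elements are centred against the modelling reference (age 60,
    75% male, 50% current smokers); categorical elements are 0/1 indicators
    against the reference bands, so the reference profile is the zero vector.
    """

    age_c: float = 0.0
    male_c: float = 0.0
    smoker_c: float = 0.0
    fev1_lt50: float = 0.0
    fev1_gt70: float = 0.0
    exac_ge2: float = 0.0
    exac_not_reported: float = 0.0
    dur_lt20: float = 0.0
    dur_20to40: float = 0.0
    dur_gt60: float = 0.0
    imputed: tuple[str, ...] = ()

    def as_array(self, columns: Sequence[str] = FULL_COVARIATE_COLUMNS) -> np.ndarray:
        return np.array([getattr(self, c) for c in columns], dtype=float)


@dataclass
class StudyFlags:
    """Per-study provenance notes used by sensitivity-analysis filters."""

    explicit_history_required: bool = False
    rates_follow_up_adjusted: bool = False


@dataclass
class TrialDataset:
    """A validated collection of study-arms for one endpoint."""

    endpoint: str
    treatments: list[TreatmentRegimen]
    arms: list[ArmRecord]
    study_flags: dict[str, StudyFlags] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- views ---------------------------------------------------------
    @property
    def study_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for arm in self.arms:
            seen.setdefault(arm.study_id, None)
        return list(seen)

    @property
    def treatment_ids(self) -> list[str]:
        return [t.id for t in self.treatments]

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)

    def arms_of_study(self, study_id: str) -> list[ArmRecord]:
        return [a for a in self.arms if a.study_id == study_id]

    def placebo(self) -> TreatmentRegimen | None:
        for t in self.treatments:
            if t.is_placebo:
                return t
        return None

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise DataValidationError(f"unknown endpoint {self.endpoint!r}")
        ids = [t.id for t in self.treatments]
        if len(ids) != len(set(ids)):
            raise DataValidationError("treatment ids must be unique")
        if sum(t.is_placebo for t in self.treatments) > 1:
            raise DataValidationError("at most one regimen may be placebo")
        known = set(ids)
        seen_pairs: set[tuple[str, str]] = set()
        per_study: dict[str, int] = {}
        for arm in self.arms:
            if arm.treatment_id not in known:
                raise DataValidationError(
                    f"arm {arm.study_id}/{arm.treatment_id} references an "
                    "undeclared treatment"
                )
            pair = (arm.study_id, arm.treatment_id)
            if pair in seen_pairs:
                raise DataValidationError(
                    f"duplicate (study, treatment) pair {pair}"
                )
            seen_pairs.add(pair)
            per_study[arm.study_id] = per_study.get(arm.study_id, 0) + 1
            if not _has_endpoint_payload(arm, self.endpoint):
                raise DataValidationError(
                    f"arm {arm.study_id}/{arm.treatment_id} lacks the "
                    f"{self.endpoint} payload"
                )
        for study, count in per_study.items():
            if count < 2:
                raise DataValidationError(
                    f"study {study} has fewer than 2 arms"
                )

    def subset(self, study_ids: Iterable[str]) -> "TrialDataset":
        """Restrict to the given studies, pruning unused treatments."""
        keep = set(study_ids)
        arms = [a for a in self.arms if a.study_id in keep]
        used = {a.treatment_id for a in arms}
        treatments = [t for t in self.treatments if t.id in used]
        flags = {s: f for s, f in self.study_flags.items() if s in keep}
        return TrialDataset(self.endpoint, treatments, arms, flags)


def _has_endpoint_payload(arm: ArmRecord, endpoint: str) -> bool:
    if endpoint in CONTINUOUS_ENDPOINTS:
        return arm.continuous_payload is not None
    return arm.count_payload is not None


# ----------------------------------------------------------------------
# Covariate normalisation
# ----------------------------------------------------------------------

def duration_category(
    duration_weeks: float,
    cuts: Sequence[float] = DEFAULT_DURATION_CUTS,
) -> str:
    """Band a study duration: <c0 | [c0,c1) | [c1,c2] (reference) | >c2."""
    c0, c1, c2 = cuts
    if duration_weeks < c0:
        return "lt20"
    if duration_weeks < c1:
        return "20to40"
    if duration_weeks <= c2:
        return "ref"
    return "gt60"


def fev1_category(pct_predicted: float) -> str:
    """Band a mean % predicted FEV1: <50 | [50, 70] (reference) | >70."""
    if pct_predicted < 50.0:
        return "lt50"
    if pct_predicted <= 70.0:
        return "50to70"
    return "gt70"


def normalize_covariates(
    arm: ArmRecord,
    duration_cuts: Sequence[float] = DEFAULT_DURATION_CUTS,
) -> CovariateVector:
    """Centre an arm's covariates against the model's reference profile.

    Continuous covariates are shifted (age - 60 years, proportion male -
    0.75, proportion current smokers - 0.5); categorical covariates become
    indicators against their reference bands. A missing covariate is imputed
    to the reference (centred value 0 / indicator 0) and flagged, so it
    contributes no covariate effect.
    """
    imputed: list[str] = []

    def centred(value: float | None, center: float, name: str) -> float:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            imputed.append(name)
            return 0.0
        return value - center

    age_c = centred(arm.mean_age_years, AGE_CENTER, "mean_age_years")
    male_c = centred(arm.prop_male, MALE_CENTER, "prop_male")
    smoker_c = centred(arm.prop_smokers, SMOKER_CENTER, "prop_smokers")

    fev1_lt50 = 1.0 if arm.fev1_pct_pred_cat == "lt50" else 0.0
    fev1_gt70 = 1.0 if arm.fev1_pct_pred_cat == "gt70" else 0.0
    if arm.fev1_pct_pred_cat == "missing":
        imputed.append("fev1_pct_pred_cat")

    exac_ge2 = 1.0 if arm.exac_history_cat == "at_least_2" else 0.0
    exac_nr = 1.0 if arm.exac_history_cat == "not_reported" else 0.0

    band = duration_category(arm.duration_weeks, duration_cuts)
    if imputed:
        logger.debug(
            "arm %s/%s: covariates imputed to reference: %s",
            arm.study_id, arm.treatment_id, ", ".join(imputed),
        )
    return CovariateVector(
        age_c=age_c,
        male_c=male_c,
        smoker_c=smoker_c,
        fev1_lt50=fev1_lt50,
        fev1_gt70=fev1_gt70,
        exac_ge2=exac_ge2,
        exac_not_reported=exac_nr,
        dur_lt20=1.0 if band == "lt20" else 0.0,
        dur_20to40=1.0 if band == "20to40" else 0.0,
        dur_gt60=1.0 if band == "gt60" else 0.0,
        imputed=tuple(imputed),
    )


def covariate_columns(covariate_set: str) -> tuple[str, ...]:
    """Column names of the design matrix for a covariate set."""
    if covariate_set == "full":
        return FULL_COVARIATE_COLUMNS
    if covariate_set == "duration_only":
        return DURATION_COVARIATE_COLUMNS
    if covariate_set == "none":
        return ()
    raise ValueError(f"unknown covariate_set {covariate_set!r}")


# ----------------------------------------------------------------------
# Person-years / event reconstruction
# ----------------------------------------------------------------------

def estimate_person_years(arm: ArmRecord) -> float:
    """Person-years of follow-up for one arm.

    Computed directly as events / rate when both are reported; otherwise a
    reported person-years value is passed through; otherwise reconstructed
    from the arm sizes assuming completers have full follow-up and
    withdrawals contribute half of their potential follow-up:

        person_years = (duration_weeks / 52) * (n_complete + 0.5 * n_withdrawn)
    """
    p = arm.count_payload
    if p is None:
        raise DataValidationError(
            f"{arm.study_id}/{arm.treatment_id}: no count payload"
        )
    if p.n_events is not None and p.annual_rate is not None:
        if p.annual_rate == 0:
            if p.n_events > 0:
                raise DataValidationError(
                    f"{arm.study_id}/{arm.treatment_id}: annual_rate 0 with "
                    f"{p.n_events} events is inconsistent"
                )
        else:
            return p.n_events / p.annual_rate
    if p.person_years is not None:
        return p.person_years
    n_complete = arm.n_randomised - arm.n_withdrawn
    years = arm.duration_weeks / 52.0
    return years * (n_complete + 0.5 * arm.n_withdrawn)


def reconstruct_events(arm: ArmRecord, person_years: float) -> int:
    """Event count for one arm: reported when available, otherwise
    round(annual_rate * person_years) to the nearest integer (halves away
    from zero, so the Poisson likelihood sees a count)."""
    p = arm.count_payload
    if p is None or (p.n_events is None and p.annual_rate is None):
        raise DataValidationError(
            f"{arm.study_id}/{arm.treatment_id}: cannot reconstruct events"
        )
    if p.n_events is not None:
        return int(p.n_events)
    x = p.annual_rate * person_years
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


# ----------------------------------------------------------------------
# CSV dialect
# ----------------------------------------------------------------------

def _opt_float(row: Mapping, col: str) -> float | None:
    if col not in row:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_int(row: Mapping, col: str) -> int | None:
    v = _opt_float(row, col)
    return None if v is None else int(round(v))


def _opt_str(row: Mapping, col: str, default: str) -> str:
    if col not in row:
        return default
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return default
    return str(v)


def _opt_bool(row: Mapping, col: str) -> bool:
    v = _opt_float(row, col)
    return bool(v) if v is not None else False


def read_dataset(path: str | Path, endpoint: str) -> TrialDataset:
    """Read a trial dataset from the documented arm-level CSV dialect.

    The file is UTF-8, comma-separated with a "." decimal and a header row;
    one row per (study, arm). Rows lacking the requested endpoint's payload
    are dropped with a logged count; malformed rows abort with an error
    naming the offence.
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"missing required column(s): {', '.join(missing)}"
        )
    return dataset_from_frame(df, endpoint, source=str(path))


def dataset_from_frame(
    df: pd.DataFrame, endpoint: str, source: str = "<frame>"
) -> TrialDataset:
    """Build a validated :class:`TrialDataset` from an arm-level DataFrame."""
    arms: list[ArmRecord] = []
    treatments: dict[str, TreatmentRegimen] = {}
    flags: dict[str, StudyFlags] = {}
    n_dropped = 0
    for _, row in df.iterrows():
        cont = None
        mean_change = _opt_float(row, "mean_change")
        std_error = _opt_float(row, "std_error")
        if mean_change is not None and std_error is not None:
            cont = ContinuousPayload(mean_change, std_error)
        count = None
        n_events = _opt_int(row, "n_events")
        annual_rate = _opt_float(row, "annual_rate")
        person_years = _opt_float(row, "person_years")
        if n_events is not None or annual_rate is not None:
            count = CountPayload(n_events, annual_rate, person_years)
        needed = cont if endpoint in CONTINUOUS_ENDPOINTS else count
        if needed is None:
            n_dropped += 1
            continue
        arm = ArmRecord(
            study_id=str(row["study_id"]),
            treatment_id=str(row["treatment_id"]),
            n_randomised=int(row["n_randomised"]),
            n_withdrawn=int(row["n_withdrawn"]),
            duration_weeks=float(row["duration_weeks"]),
            mean_age_years=_opt_float(row, "mean_age_years"),
            prop_male=_opt_float(row, "prop_male"),
            prop_smokers=_opt_float(row, "prop_smokers"),
            fev1_pct_pred_cat=_opt_str(row, "fev1_pct_pred_cat", "missing"),
            exac_history_cat=_opt_str(row, "exac_history_cat", "not_reported"),
            continuous_payload=cont,
            count_payload=count,
        )
        arms.append(arm)
        tid = arm.treatment_id
        if tid not in treatments:
            treatments[tid] = TreatmentRegimen(
                id=tid,
                label=_opt_str(row, "treatment_label", tid),
                is_placebo=_opt_bool(row, "is_placebo"),
            )
        sf = flags.setdefault(arm.study_id, StudyFlags())
        sf.explicit_history_required |= _opt_bool(
            row, "explicit_history_required")
        sf.rates_follow_up_adjusted |= _opt_bool(
            row, "rates_follow_up_adjusted")
    if n_dropped:
        logger.warning(
            "%s: dropped %d row(s) lacking the %s payload",
            source, n_dropped, endpoint,
        )
    return TrialDataset(endpoint, list(treatments.values()), arms, flags)


def dataset_to_frame(dataset: TrialDataset) -> pd.DataFrame:
    """Serialise a dataset back to the arm-level CSV dialect."""
    treatments = {t.id: t for t in dataset.treatments}
    rows = []
    for arm in dataset.arms:
        t = treatments[arm.treatment_id]
        sf = dataset.study_flags.get(arm.study_id, StudyFlags())
        row: dict = {
            "study_id": arm.study_id,
            "treatment_id": arm.treatment_id,
            "treatment_label": t.label,
            "is_placebo": int(t.is_placebo),
            "n_randomised": arm.n_randomised,
            "n_withdrawn": arm.n_withdrawn,
            "duration_weeks": arm.duration_weeks,
            "mean_age_years": arm.mean_age_years,
            "prop_male": arm.prop_male,
            "prop_smokers": arm.prop_smokers,
            "fev1_pct_pred_cat": arm.fev1_pct_pred_cat,
            "exac_history_cat": arm.exac_history_cat,
            "explicit_history_required": int(sf.explicit_history_required),
            "rates_follow_up_adjusted": int(sf.rates_follow_up_adjusted),
        }
        if arm.continuous_payload is not None:
            row["mean_change"] = arm.continuous_payload.mean_change
            row["std_error"] = arm.continuous_payload.std_error
        if arm.count_payload is not None:
            row["n_events"] = arm.count_payload.n_events
            row["annual_rate"] = arm.count_payload.annual_rate
            row["person_years"] = arm.count_payload.person_years
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(dataset: TrialDataset, path: str | Path) -> None:
    dataset_to_frame(dataset).to_csv(path, index=False)
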