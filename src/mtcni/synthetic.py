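"""Synthetic trial-network generator.

Generates arm-level aggregate datasets with exactly the statistical
structure the analysis model assumes: study effects drawn from a common
Normal distribution, fixed per-treatment effects, arm-level covariates
(population mean age, proportion male, proportion current smokers, disease
severity and exacerbation-history bands), Normal measurement error on
continuous outcomes with standard errors derived from arm sizes, Poisson
exacerbation counts with a person-years exposure built from a binomial
withdrawal process, and per-study provenance flags for sensitivity filters.

Every simulated dataset round-trips through the CSV dialect and validates,
and comes with a truth sidecar (all latent values) so parameter-recovery
and coverage studies can score the fitted posteriors.

:func:`make_copd_network` returns ready-made scenarios whose network
topology mirrors a realistic ICS/LABA evidence base in COPD: a 28-study
lung-function (FEV1) network, a 15-study exacerbation-rate network in which
a single short 12-week study links the once-daily FF/VI cluster to the rest
of the network (plus 6 optional studies without an explicit
exacerbation-history entry requirement, for sensitivity analyses), and a
20-study SGRQ health-status network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

from .data import (
    ArmRecord,
    ContinuousPayload,
    CountPayload,
    StudyFlags,
    TreatmentRegimen,
    TrialDataset,
    normalize_covariates,
)

#: Covariate generator defaults: population mean age 63.79 years, mean
#: proportion male 0.73, mean proportion current smokers 0.46.
DEFAULT_AGE_MEAN = 63.79
DEFAULT_AGE_SD = 5.0
DEFAULT_PROP_MALE = 0.73
DEFAULT_PROP_SMOKERS = 0.46
DEFAULT_PROP_CONCENTRATION = 40.0

#: Assumed subject-level outcome dispersion used to derive arm standard
#: errors (se = sd / sqrt(n)): 0.25 L for FEV1, 12 score units for SGRQ.
DEFAULT_SUBJECT_SD = {"fev1": 0.25, "sgrq": 12.0}

#: Severity-band mix (fraction of studies per % predicted FEV1 band).
DEFAULT_FEV1_CAT_PROBS = {"lt50": 0.39, "50to70": 0.49, "gt70": 0.12}


class ScenarioError(ValueError):
    """The scenario violates one of its invariants."""


@dataclass(frozen=True)
class StudyDesign:
    """One simulated study: which treatments it compares and its size."""

    study_id: str
    treatment_ids: tuple[str, ...]
    n_per_arm: int
    duration_weeks: float
    explicit_history: bool = False
    rates_adjusted: bool = False


@dataclass
class SyntheticScenario:
    """Full generative description of a synthetic trial network."""

    endpoint: str
    treatments: tuple[TreatmentRegimen, ...]
    theta_true: dict[str, float]
    studies: tuple[StudyDesign, ...]
    beta_true: dict[str, float] = field(default_factory=dict)
    mu_true: float = 0.0
    tau_true: float = 0.02
    subject_sd: float | None = None
    withdrawal_prob: float = 0.10
    age_mean: float = DEFAULT_AGE_MEAN
    age_sd: float = DEFAULT_AGE_SD
    prop_male: float = DEFAULT_PROP_MALE
    prop_smokers: float = DEFAULT_PROP_SMOKERS
    prop_concentration: float = DEFAULT_PROP_CONCENTRATION
    fev1_cat_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEV1_CAT_PROBS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subject_sd is None and self.endpoint in DEFAULT_SUBJECT_SD:
            self.subject_sd = DEFAULT_SUBJECT_SD[self.endpoint]
        if self.tau_true < 0:
            raise ScenarioError("tau_true must be >= 0")
        if self.subject_sd is not None and self.subject_sd < 0:
            raise ScenarioError("subject_sd must be >= 0")
        if not 0 <= self.withdrawal_prob < 1:
            raise ScenarioError("withdrawal_prob must lie in [0, 1)")
        ids = {t.id for t in self.treatments}
        for t in ids:
            if t not in self.theta_true:
                raise ScenarioError(f"no true effect for treatment {t!r}")
        for sd in self.studies:
            for t in sd.treatment_ids:
                if t not in ids:
                    raise ScenarioError(
                        f"study {sd.study_id} uses undeclared treatment {t!r}")
            if len(sd.treatment_ids) < 2:
                raise ScenarioError(
                    f"study {sd.study_id} needs >= 2 arms")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["treatments"] = [asdict(t) for t in self.treatments]
        d["studies"] = [asdict(s) for s in self.studies]
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticScenario":
        d = dict(d)
        d["treatments"] = tuple(
            TreatmentRegimen(**t) for t in d["treatments"])
        d["studies"] = tuple(
            StudyDesign(**{**s, "treatment_ids": tuple(s["treatment_ids"])})
            for s in d["studies"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticScenario":
        return cls.from_dict(yaml.safe_load(text))


def simulate_dataset(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[TrialDataset, dict]:
    """Draw one dataset (and its truth sidecar) from a scenario.

    Study effects are drawn alpha_s ~ N(mu_true, tau_true^2); each arm gets
    covariates from the scenario's generators, then either a Normal mean
    change (se = subject_sd / sqrt(n)) or a Poisson event count over the
    person-years implied by the binomial withdrawal process (withdrawals
    contribute half their potential follow-up). The sidecar holds every
    latent value, so (scenario, seed) jointly reproduce both outputs.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    continuous = scenario.endpoint in ("fev1", "sgrq")
    conc = scenario.prop_concentration

    alpha: dict[str, float] = {}
    arms: list[ArmRecord] = []
    flags: dict[str, StudyFlags] = {}
    fev1_cats = list(scenario.fev1_cat_probs)
    fev1_p = np.array([scenario.fev1_cat_probs[c] for c in fev1_cats])
    fev1_p = fev1_p / fev1_p.sum()

    for sd in scenario.studies:
        a_s = scenario.mu_true + scenario.tau_true * rng.standard_normal()
        alpha[sd.study_id] = float(a_s)
        flags[sd.study_id] = StudyFlags(
            explicit_history_required=sd.explicit_history,
            rates_follow_up_adjusted=sd.rates_adjusted,
        )
        # categorical covariates are study-level design features
        fev1_cat = str(rng.choice(fev1_cats, p=fev1_p))
        if sd.explicit_history:
            exac_cat = "at_least_2" if rng.random() < 0.2 else "at_least_1"
        else:
            exac_cat = "not_reported"
        for tid in sd.treatment_ids:
            n = sd.n_per_arm
            withdrawn = int(rng.binomial(n, scenario.withdrawal_prob))
            base = ArmRecord(
                study_id=sd.study_id,
                treatment_id=tid,
                n_randomised=n,
                n_withdrawn=withdrawn,
                duration_weeks=sd.duration_weeks,
                mean_age_years=float(rng.normal(
                    scenario.age_mean, scenario.age_sd)),
                prop_male=float(rng.beta(
                    scenario.prop_male * conc,
                    (1 - scenario.prop_male) * conc)),
                prop_smokers=float(rng.beta(
                    scenario.prop_smokers * conc,
                    (1 - scenario.prop_smokers) * conc)),
                fev1_pct_pred_cat=fev1_cat,
                exac_history_cat=exac_cat,
                continuous_payload=ContinuousPayload(0.0, 1.0),
            )
            z = normalize_covariates(base)
            pred = a_s + scenario.theta_true[tid]
            for name, coef in scenario.beta_true.items():
                pred += coef * getattr(z, name)
            if continuous:
                se = scenario.subject_sd / np.sqrt(n)
                y = pred + se * rng.standard_normal()
                arm = replace(base, continuous_payload=ContinuousPayload(
                    float(y), float(max(se, 1e-9))))
            else:
                py = (sd.duration_weeks / 52.0) * (
                    (n - withdrawn) + 0.5 * withdrawn)
                events = int(rng.poisson(py * np.exp(pred)))
                rate = events / py if sd.rates_adjusted else None
                arm = replace(
                    base,
                    continuous_payload=None,
                    count_payload=CountPayload(
                        n_events=events, annual_rate=rate),
                )
            arms.append(arm)

    dataset = TrialDataset(
        endpoint=scenario.endpoint,
        treatments=list(scenario.treatments),
        arms=arms,
        study_flags=flags,
    )
    truth = {
        "seed": int(scenario.seed if seed is None else seed),
        "endpoint": scenario.endpoint,
        "mu": scenario.mu_true,
        "tau": scenario.tau_true,
        "alpha": alpha,
        "theta": dict(scenario.theta_true),
        "beta": dict(scenario.beta_true),
    }
    return dataset, truth


def truth_to_json(truth: dict) -> str:
    return json.dumps(truth, indent=2, sort_keys=True)


# ----------------------------------------------------------------------
# Ready-made networks with realistic ICS/LABA evidence-base topology
# ----------------------------------------------------------------------

_TREATMENTS = (
    TreatmentRegimen("PBO", "Placebo", is_placebo=True),
    TreatmentRegimen("FFVI", "FF/VI 100/25 mcg QD"),
    TreatmentRegimen("FPSAL", "FP/SAL 500/50 mcg BID"),
    TreatmentRegimen("BUDFORM", "BUD/FORM 400/12 mcg BID"),
    TreatmentRegimen("SAL", "SAL 50 mcg BID"),
    TreatmentRegimen("FORM", "FORM 9 mcg BID"),
    TreatmentRegimen("VI", "VI 25 mcg QD"),
    TreatmentRegimen("TIO", "TIO 18 mcg QD"),
)

#: True treatment effects (change from baseline FEV1, litres). The FF/VI
#: vs FP/SAL contrast is +0.023 L and FF/VI vs BUD/FORM +0.027 L.
_FEV1_THETA = {
    "PBO": -0.123, "FFVI": 0.028, "FPSAL": 0.005, "BUDFORM": 0.001,
    "SAL": -0.040, "FORM": -0.045, "VI": -0.020, "TIO": -0.030,
}

#: True log annual exacerbation rates relative to a placebo rate of 1/year.
_EXAC_THETA = {
    "PBO": 0.0,
    "FFVI": float(np.log(0.62)), "FPSAL": float(np.log(0.66)),
    "BUDFORM": float(np.log(0.71)), "SAL": float(np.log(0.85)),
    "FORM": float(np.log(0.87)), "VI": float(np.log(0.90)),
    "TIO": float(np.log(0.80)),
}

#: True SGRQ changes from baseline (units; lower is better). Differences
#: vs placebo: FF/VI -4.599, FP/SAL -3.278, BUD/FORM -3.635.
_SGRQ_THETA = {
    "PBO": -1.0, "FFVI": -5.599, "FPSAL": -4.278, "BUDFORM": -4.635,
    "SAL": -4.0, "FORM": -4.1, "VI": -4.3, "TIO": -4.5,
}


def _studies(rows: Sequence[tuple], prefix: str) -> tuple[StudyDesign, ...]:
    out = []
    for i, (treats, n, dur, *rest) in enumerate(rows, start=1):
        hist = rest[0] if rest else False
        adj = rest[1] if len(rest) > 1 else False
        out.append(StudyDesign(
            study_id=f"{prefix}{i:02d}", treatment_ids=tuple(treats),
            n_per_arm=n, duration_weeks=dur,
            explicit_history=hist, rates_adjusted=adj))
    return tuple(out)


_FEV1_STUDIES = _studies([
    # FF/VI development programme (7 FF/VI arms)
    (("FFVI", "FPSAL"), 400, 12),
    (("FFVI", "FPSAL"), 400, 12),
    (("FFVI", "VI", "PBO"), 300, 24),
    (("FFVI", "VI", "PBO"), 300, 24),
    (("FFVI", "TIO"), 300, 12),
    (("FFVI", "VI"), 400, 52),
    (("FFVI", "VI"), 400, 52),
    # FP/SAL evidence base
    (("FPSAL", "SAL", "PBO"), 350, 52),
    (("FPSAL", "SAL", "PBO"), 350, 52),
    (("FPSAL", "SAL", "PBO"), 350, 52),
    (("FPSAL", "PBO"), 250, 24),
    (("FPSAL", "PBO"), 250, 24),
    (("FPSAL", "PBO"), 250, 24),
    (("FPSAL", "SAL"), 300, 12),
    (("FPSAL", "SAL"), 300, 12),
    # BUD/FORM evidence base
    (("BUDFORM", "FORM", "PBO"), 330, 52),
    (("BUDFORM", "FORM", "PBO"), 330, 52),
    (("BUDFORM", "FORM", "PBO"), 330, 52),
    (("BUDFORM", "PBO"), 280, 26),
    (("BUDFORM", "PBO"), 280, 26),
    (("BUDFORM", "FORM"), 300, 12),
    (("BUDFORM", "FORM"), 300, 12),
    # monotherapy and cross links
    (("SAL", "PBO"), 250, 24),
    (("SAL", "PBO"), 250, 24),
    (("FORM", "PBO"), 250, 24),
    (("FORM", "PBO"), 250, 24),
    (("TIO", "PBO"), 300, 48),
    (("FPSAL", "BUDFORM"), 300, 26),
], "F")

# One 12-week FF/VI study is the single link between the FF/VI cluster and
# the rest of the network, and the only study under 20 weeks.
_EXAC_STUDIES = _studies([
    (("FFVI", "VI"), 400, 24, True, False),
    (("FFVI", "VI"), 400, 26, True, False),
    (("FFVI", "FPSAL"), 400, 12, True, False),
    (("FPSAL", "SAL", "PBO"), 380, 52, True, True),
    (("FPSAL", "SAL", "PBO"), 380, 52, True, True),
    (("FPSAL", "SAL", "PBO"), 380, 52, True, True),
    (("FPSAL", "PBO"), 350, 48, True, False),
    (("FPSAL", "PBO"), 350, 48, True, False),
    (("BUDFORM", "FORM", "PBO"), 360, 48, True, True),
    (("BUDFORM", "FORM", "PBO"), 360, 48, True, True),
    (("BUDFORM", "FORM", "PBO"), 360, 48, True, True),
    (("BUDFORM", "PBO"), 340, 52, True, False),
    (("BUDFORM", "PBO"), 340, 52, True, False),
    (("SAL", "PBO"), 300, 52, True, True),
    (("FORM", "PBO"), 300, 52, True, False),
], "X")

_EXAC_SENSITIVITY_STUDIES = _studies([
    (("TIO", "PBO"), 320, 48, False, True),
    (("SAL", "PBO"), 300, 24, False, False),
    (("FORM", "PBO"), 300, 24, False, False),
    (("FPSAL", "SAL"), 320, 52, False, True),
    (("BUDFORM", "FORM"), 320, 52, False, False),
    (("FPSAL", "PBO"), 300, 26, False, False),
], "XS")

_SGRQ_STUDIES = _studies([
    (("FFVI", "FPSAL"), 400, 12),
    (("FFVI", "FPSAL"), 400, 12),
    (("FFVI", "VI", "PBO"), 300, 24),
    (("FFVI", "VI", "PBO"), 300, 24),
    (("FFVI", "VI"), 400, 52),
    (("FPSAL", "SAL", "PBO"), 350, 52),
    (("FPSAL", "SAL", "PBO"), 350, 52),
    (("FPSAL", "SAL", "PBO"), 350, 52),
    (("FPSAL", "PBO"), 250, 24),
    (("FPSAL", "PBO"), 250, 24),
    (("BUDFORM", "FORM", "PBO"), 330, 52),
    (("BUDFORM", "FORM", "PBO"), 330, 52),
    (("BUDFORM", "FORM", "PBO"), 330, 52),
    (("BUDFORM", "PBO"), 280, 26),
    (("BUDFORM", "PBO"), 280, 26),
    (("SAL", "PBO"), 250, 24),
    (("FORM", "PBO"), 250, 24),
    (("TIO", "PBO"), 300, 48),
    (("FPSAL", "BUDFORM"), 300, 26),
    (("BUDFORM", "FORM"), 300, 12),
], "Q")


def make_copd_network(
    endpoint: str,
    include_sensitivity_studies: bool = False,
    seed: int = 0,
) -> SyntheticScenario:
    """A ready-made scenario per endpoint: 28 studies for FEV1, 15 for
    exacerbation rates (21 with the 6 no-explicit-history sensitivity
    studies included) and 20 for SGRQ."""
    if endpoint == "fev1":
        return SyntheticScenario(
            endpoint="fev1",
            treatments=_TREATMENTS,
            theta_true=dict(_FEV1_THETA),
            beta_true={"age_c": -0.004},
            mu_true=0.0,
            tau_true=0.02,
            studies=_FEV1_STUDIES,
            seed=seed,
        )
    if endpoint == "exacerbation":
        studies = _EXAC_STUDIES
        treatments = tuple(t for t in _TREATMENTS
                           if t.id != "TIO") if not include_sensitivity_studies \
            else _TREATMENTS
        if include_sensitivity_studies:
            studies = studies + _EXAC_SENSITIVITY_STUDIES
        return SyntheticScenario(
            endpoint="exacerbation",
            treatments=treatments,
            theta_true={t.id: _EXAC_THETA[t.id] for t in treatments},
            beta_true={"age_c": -0.01, "dur_lt20": -0.3},
            mu_true=0.0,
            tau_true=0.10,
            studies=studies,
            seed=seed,
        )
    if endpoint == "sgrq":
        return SyntheticScenario(
            endpoint="sgrq",
            treatments=_TREATMENTS,
            theta_true=dict(_SGRQ_THETA),
            beta_true={},
            mu_true=0.0,
            tau_true=0.5,
            studies=_SGRQ_STUDIES,
            seed=seed,
        )
    raise ValueError(f"unknown endpoint {endpoint!r}")
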