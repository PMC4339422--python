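"""Shared fixtures: small hand-written trial datasets and chain stubs."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from mtcni.data import (
    ArmRecord,
    ContinuousPayload,
    CountPayload,
    TreatmentRegimen,
    TrialDataset,
)
from mtcni.model import ModelSpec
from mtcni.sampler import PosteriorChains, SamplerSettings

logging.getLogger("mtcni").setLevel(logging.ERROR)

#: 3 studies, 7 arms, FEV1 payloads — the small hand-written fixture used
#: by the I/O and network tests.
FIXTURE_CSV = """\
study_id,treatment_id,treatment_label,is_placebo,n_randomised,n_withdrawn,duration_weeks,mean_age_years,prop_male,prop_smokers,fev1_pct_pred_cat,exac_history_cat,mean_change,std_error
S1,PBO,Placebo,1,120,12,24,64.1,0.70,0.45,50to70,at_least_1,-0.110,0.020
S1,ACT1,Active one,0,118,10,24,63.5,0.72,0.44,50to70,at_least_1,0.030,0.021
S2,PBO,Placebo,1,200,30,52,62.0,0.75,0.50,lt50,not_reported,-0.130,0.015
S2,ACT1,Active one,0,205,25,52,61.8,0.74,0.49,lt50,not_reported,0.020,0.015
S2,ACT2,Active two,0,198,28,52,62.2,0.76,0.51,lt50,not_reported,0.010,0.016
S3,ACT1,Active one,0,90,5,12,65.0,0.71,0.40,gt70,at_least_2,0.040,0.025
S3,ACT2,Active two,0,92,4,12,64.8,0.69,0.41,gt70,at_least_2,0.025,0.024
"""


@pytest.fixture
def fixture_csv(tmp_path):
    path = tmp_path / "arms.csv"
    path.write_text(FIXTURE_CSV)
    return path


def continuous_arm(study, treatment, y, se, *, n=100, withdrawn=0,
                   duration=24.0, **kw) -> ArmRecord:
    return ArmRecord(study, treatment, n, withdrawn, duration,
                     continuous_payload=ContinuousPayload(y, se), **kw)


def count_arm(study, treatment, *, events=None, rate=None, py=None,
              n=100, withdrawn=0, duration=52.0, **kw) -> ArmRecord:
    return ArmRecord(study, treatment, n, withdrawn, duration,
                     count_payload=CountPayload(events, rate, py), **kw)


def two_treatment_dataset(endpoint="fev1", arms=None) -> TrialDataset:
    treatments = [TreatmentRegimen("A", "A"), TreatmentRegimen("B", "B")]
    return TrialDataset(endpoint, treatments, arms)


@pytest.fixture
def conjugate_toy() -> TrialDataset:
    """One study, two treatments with known observation sd 0.1: with the
    study effect pinned at 0, each theta has a closed-form Normal posterior."""
    return two_treatment_dataset("fev1", [
        continuous_arm("S1", "A", 0.5, 0.1),
        continuous_arm("S1", "B", 0.0, 0.1),
    ])


@pytest.fixture
def poisson_toy() -> TrialDataset:
    """One study, two treatments: 50 vs 40 events on 100 person-years."""
    return two_treatment_dataset("exacerbation", [
        count_arm("S1", "A", events=50, py=100.0),
        count_arm("S1", "B", events=40, py=100.0),
    ])


def chains_from_theta(theta: np.ndarray, treatment_ids=("A", "B"),
                      family="normal") -> PosteriorChains:
    """Wrap raw theta draws (n_chains, n_draws, T) as PosteriorChains,
    for testing the inference layer in isolation."""
    theta = np.asarray(theta, dtype=float)
    c, d, t = theta.shape
    assert t == len(treatment_ids)
    return PosteriorChains(
        study_ids=("S1",),
        treatment_ids=tuple(treatment_ids),
        covariate_names=(),
        alpha=np.zeros((c, d, 1)),
        theta=theta,
        beta=np.zeros((c, d, 0)),
        mu=np.zeros((c, d)),
        tau2=np.ones((c, d)),
        sigma2=None,
        acceptance={},
        step_sizes={},
        step_trajectory={},
        settings=SamplerSettings(n_chains=c, n_burnin=0, n_draws=d),
        spec=ModelSpec(family=family, covariate_set="none"),
    )
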