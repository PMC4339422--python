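"""Joint model: linear predictor, likelihoods, priors, invariances."""

import numpy as np
import pytest
from scipy.stats import invgamma, norm, poisson

from mtcni.data import TreatmentRegimen, TrialDataset, normalize_covariates
from mtcni.model import (
    ModelDesign,
    ModelSpec,
    linear_predictor,
    log_likelihood,
    log_posterior,
    log_prior,
)
from conftest import continuous_arm, count_arm, two_treatment_dataset


@pytest.fixture
def normal_design():
    ds = two_treatment_dataset("fev1", [
        continuous_arm("S1", "A", 0.1, 0.05),
        continuous_arm("S1", "B", 0.0, 0.04),
        continuous_arm("S2", "A", 0.2, 0.03),
        continuous_arm("S2", "B", 0.05, 0.03),
    ])
    return ModelDesign(ds, ModelSpec(family="normal", covariate_set="none"))


@pytest.fixture
def poisson_design():
    ds = two_treatment_dataset("exacerbation", [
        count_arm("S1", "A", events=10, py=20.0),
        count_arm("S1", "B", events=8, py=20.0),
    ])
    return ModelDesign(ds, ModelSpec(family="poisson", covariate_set="none"))


class TestLinearPredictor:
    def test_zero_state_gives_zero(self, normal_design):
        state = normal_design.new_state()
        arm = continuous_arm("S1", "A", 0.1, 0.05)
        z = normalize_covariates(arm)
        assert linear_predictor(state, arm, z) == 0.0

    def test_age_effect_arithmetic(self):
        ds = two_treatment_dataset("fev1", [
            continuous_arm("S1", "A", 0.1, 0.05, mean_age_years=63.79),
            continuous_arm("S1", "B", 0.0, 0.05, mean_age_years=63.79),
        ])
        design = ModelDesign(ds, ModelSpec(family="normal"))
        state = design.new_state(alpha=[0.1])
        state.theta[design.treatment_ids.index("A")] = 0.02
        state.beta[design.covariate_names.index("age_c")] = -0.005
        arm = ds.arms[0]
        value = linear_predictor(state, arm, normalize_covariates(arm))
        assert value == pytest.approx(0.1 + 0.02 - 0.005 * 3.79, abs=1e-12)

    def test_poisson_expected_count(self, poisson_design):
        # predictor log(0.5) over 20 person-years -> mean count 10
        state = poisson_design.new_state(alpha=[np.log(0.5)])
        eta = poisson_design.linear_predictor(state)
        mean_counts = poisson_design.person_years * np.exp(eta)
        assert mean_counts[0] == pytest.approx(10.0)

    def test_unknown_ids_raise(self, normal_design):
        state = normal_design.new_state()
        arm = continuous_arm("S9", "A", 0.1, 0.05)
        with pytest.raises(KeyError, match="S9"):
            linear_predictor(state, arm, normalize_covariates(arm))


class TestLogLikelihood:
    def test_normal_single_arm_value(self):
        # y = 0.1 at predictor 0 with sd 0.05
        ds = two_treatment_dataset("fev1", [
            continuous_arm("S1", "A", 0.1, 0.05),
            continuous_arm("S1", "B", 0.1, 0.05),
        ])
        design = ModelDesign(ds, ModelSpec(family="normal",
                                           covariate_set="none"))
        state = design.new_state()
        # direct evaluation: -0.5 log(2 pi 0.05^2) - 0.1^2/(2 0.05^2)
        per_arm = norm.logpdf(0.1, 0.0, 0.05)
        assert per_arm == pytest.approx(0.0767937, abs=5e-7)
        assert design.log_likelihood(state) == pytest.approx(2 * per_arm)

    def test_poisson_single_arm_value(self, poisson_design):
        state = poisson_design.new_state(alpha=[np.log(0.5)])
        expected = (poisson.logpmf(10, 10.0) + poisson.logpmf(8, 10.0))
        assert poisson_design.log_likelihood(state) == pytest.approx(expected)
        assert poisson.logpmf(10, 10.0) == pytest.approx(-2.078562, abs=5e-7)

    def test_matches_scipy_on_random_states(self, normal_design,
                                            poisson_design):
        rng = np.random.default_rng(0)
        for design in (normal_design, poisson_design):
            state = design.new_state(
                alpha=rng.normal(size=len(design.study_ids), scale=0.3),
                theta=rng.normal(size=len(design.treatment_ids), scale=0.3))
            eta = design.linear_predictor(state)
            if design.spec.family == "normal":
                expected = norm.logpdf(design.y, eta,
                                       np.sqrt(design.se2)).sum()
            else:
                expected = poisson.logpmf(
                    design.events.astype(int),
                    design.person_years * np.exp(eta)).sum()
            assert design.log_likelihood(state) == pytest.approx(expected)

    def test_empty_dataset_contributes_zero(self):
        ds = TrialDataset("fev1", [TreatmentRegimen("A")], [])
        design = ModelDesign(ds, ModelSpec(family="normal",
                                           covariate_set="none"))
        assert design.log_likelihood(design.new_state()) == 0.0

    def test_factorises_over_studies(self, normal_design):
        state = normal_design.new_state(alpha=[0.1, -0.2],
                                        theta=[0.05, 0.0])
        total = normal_design.log_likelihood(state)
        parts = 0.0
        for sid in ("S1", "S2"):
            arms = [a for a in [
                continuous_arm("S1", "A", 0.1, 0.05),
                continuous_arm("S1", "B", 0.0, 0.04),
                continuous_arm("S2", "A", 0.2, 0.03),
                continuous_arm("S2", "B", 0.05, 0.03),
            ] if a.study_id == sid]
            sub = two_treatment_dataset("fev1", arms)
            d = ModelDesign(sub, normal_design.spec)
            s = d.new_state(
                alpha=[state.alpha[normal_design.study_ids.index(sid)]],
                theta=state.theta)
            parts += d.log_likelihood(s)
        assert total == pytest.approx(parts)

    def test_translation_leaves_likelihood_unchanged(self, normal_design,
                                                     poisson_design):
        for design in (normal_design, poisson_design):
            state = design.new_state(
                alpha=np.linspace(-0.2, 0.1, len(design.study_ids)),
                theta=np.linspace(0.0, 0.3, len(design.treatment_ids)))
            base = design.log_likelihood(state)
            c = 0.37
            shifted = state.copy()
            shifted.theta = state.theta + c
            shifted.alpha = state.alpha - c
            assert design.log_likelihood(shifted) == pytest.approx(base)

    def test_exposure_rate_rescaling_preserves_mean(self):
        ds1 = two_treatment_dataset("exacerbation", [
            count_arm("S1", "A", events=10, py=20.0),
            count_arm("S1", "B", events=8, py=20.0)])
        ds2 = two_treatment_dataset("exacerbation", [
            count_arm("S1", "A", events=10, py=40.0),
            count_arm("S1", "B", events=8, py=40.0)])
        spec = ModelSpec(family="poisson", covariate_set="none")
        d1, d2 = ModelDesign(ds1, spec), ModelDesign(ds2, spec)
        s1 = d1.new_state(alpha=[np.log(0.5)])
        s2 = d2.new_state(alpha=[np.log(0.25)])  # rate halved, exposure x2
        assert d1.log_likelihood(s1) == pytest.approx(d2.log_likelihood(s2))


class TestLogPrior:
    def test_theta_at_mode_contribution(self, normal_design):
        # each theta at its prior mode contributes -log(sqrt(2 pi) * 100)
        per_theta = -0.5 * np.log(2 * np.pi * 100.0 ** 2)
        assert norm.logpdf(0.0, 0.0, 100.0) == pytest.approx(per_theta)
        spec = normal_design.spec
        base = log_prior(normal_design.new_state(), spec)
        moved = normal_design.new_state()
        moved.theta[0] = 100.0  # one prior sd away costs exactly 1/2
        assert log_prior(moved, spec) == pytest.approx(base - 0.5)

    def test_theta_quadratic_form(self, normal_design):
        spec = normal_design.spec
        s1 = normal_design.new_state()
        s2 = normal_design.new_state()
        s1.theta[0] = 100.0
        s2.theta[0] = 200.0
        assert (log_prior(s2, spec) - log_prior(s1, spec)
                ) == pytest.approx(-1.5)

    def test_inverse_gamma_value_at_one(self, normal_design):
        spec = normal_design.spec
        s1 = normal_design.new_state(tau2=1.0)
        s2 = normal_design.new_state(tau2=2.0)
        diff = log_prior(s1, spec) - log_prior(s2, spec)
        # both the IG hyperprior and the two alpha ~ N(mu, tau2) terms move
        expected = (invgamma.logpdf(1.0, 0.001, scale=0.001)
                    - invgamma.logpdf(2.0, 0.001, scale=0.001)
                    + 2 * (norm.logpdf(0.0, 0.0, 1.0)
                           - norm.logpdf(0.0, 0.0, np.sqrt(2.0))))
        assert diff == pytest.approx(expected)

    def test_nonpositive_tau2_is_minus_infinity(self, normal_design):
        state = normal_design.new_state(tau2=-1.0)
        assert log_prior(state, normal_design.spec) == -np.inf

    def test_posterior_is_sum_of_parts(self, normal_design):
        ds = two_treatment_dataset("fev1", [
            continuous_arm("S1", "A", 0.1, 0.05),
            continuous_arm("S1", "B", 0.0, 0.04),
            continuous_arm("S2", "A", 0.2, 0.03),
            continuous_arm("S2", "B", 0.05, 0.03)])
        spec = normal_design.spec
        state = normal_design.new_state(alpha=[0.1, 0.0], theta=[0.02, 0.0])
        assert log_posterior(state, ds, spec) == pytest.approx(
            log_prior(state, spec) + log_likelihood(state, ds, spec))


class TestModelSpec:
    def test_yaml_round_trip(self):
        spec = ModelSpec(family="poisson", covariate_set="duration_only",
                         treatment_prior_sd=50.0)
        again = ModelSpec.from_dict(
            __import__("yaml").safe_load(spec.to_yaml()))
        assert again == spec

    @pytest.mark.parametrize("kwargs", [
        {"family": "gamma"}, {"covariate_set": "some"},
        {"variance_mode": "other"}, {"treatment_prior_sd": 0.0},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelSpec(**kwargs)

    def test_endpoint_family_mapping(self):
        assert ModelSpec.for_endpoint("fev1").family == "normal"
        assert ModelSpec.for_endpoint("sgrq").family == "normal"
        assert ModelSpec.for_endpoint("exacerbation").family == "poisson"
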