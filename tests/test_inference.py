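"""Inference layer: non-inferiority probabilities, contrasts, residuals,
and the end-to-end analysis driver."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mtcni.data import TreatmentRegimen, TrialDataset
from mtcni.inference import (
    normal_noninferiority_probability,
    placebo_referenced_effects,
    run_analysis,
    standardized_residuals,
    summarize_contrast,
)
from mtcni.model import ModelSpec
from mtcni.network import StudyFilter
from mtcni.sampler import SamplerSettings
from mtcni.synthetic import (
    StudyDesign,
    SyntheticScenario,
    simulate_dataset,
)
from conftest import chains_from_theta, continuous_arm

FAST = SamplerSettings(n_chains=2, n_burnin=600, n_draws=2000, seed=1)


def _delta_chains(delta: np.ndarray, family="normal"):
    """Chains whose A-vs-B contrast equals the given draws exactly."""
    delta = np.asarray(delta, float).reshape(1, -1)
    theta = np.stack([delta, np.zeros_like(delta)], axis=-1)
    return chains_from_theta(theta, ("A", "B"), family=family)


class TestNonInferiorityProbability:
    def test_matches_normal_cdf_on_analytic_draws(self):
        rng = np.random.default_rng(0)
        n = 200_000
        delta = rng.normal(-0.025, 0.02, size=n)
        chains = _delta_chains(delta)
        c = summarize_contrast(chains, "A", "B", margins=[0.05],
                               direction="higher_better")
        expected = norm.cdf((0.05 - 0.025) / 0.02)  # = Phi(1.25)
        mc_err = 3 * np.sqrt(expected * (1 - expected) / n)
        assert expected == pytest.approx(0.8944, abs=1e-4)
        assert abs(c.noninferiority[0.05] - expected) < 3 * mc_err

    def test_degenerate_draws_give_certainty(self):
        chains = _delta_chains(np.zeros(1000))
        c = summarize_contrast(chains, "A", "B", margins=[0.001, 1.0],
                               direction="higher_better")
        assert c.noninferiority[0.001] == 1.0
        assert c.noninferiority[1.0] == 1.0
        assert (c.ci_low, c.ci_high) == (0.0, 0.0)

    def test_margin_monotonicity_rate_ratio(self):
        rng = np.random.default_rng(1)
        chains = _delta_chains(rng.normal(-0.05, 0.4, 50_000),
                               family="poisson")
        c = summarize_contrast(chains, "A", "B", margins=[0.10, 0.20])
        assert c.noninferiority[0.20] >= c.noninferiority[0.10]

    def test_lower_better_direction(self):
        rng = np.random.default_rng(2)
        delta = rng.normal(-1.3, 1.4, 100_000)  # SGRQ-like units
        chains = _delta_chains(delta)
        c = summarize_contrast(chains, "A", "B", margins=[2.0, 3.0],
                               direction="lower_better")
        expected = norm.cdf((2.0 + 1.3) / 1.4)
        assert c.noninferiority[2.0] == pytest.approx(expected, abs=0.01)
        assert c.noninferiority[3.0] >= c.noninferiority[2.0]

    def test_closed_form_equals_quadrature(self):
        for direction in ("higher_better", "lower_better"):
            for mean, sd, m in [(-0.025, 0.02, 0.05), (0.1, 0.3, 0.2)]:
                a = normal_noninferiority_probability(
                    mean, sd, m, direction, method="closed_form")
                b = normal_noninferiority_probability(
                    mean, sd, m, direction, method="quadrature")
                assert abs(a - b) < 1e-6

    def test_invalid_margin_rejected(self):
        chains = _delta_chains(np.zeros(10))
        with pytest.raises(ValueError, match="margin"):
            summarize_contrast(chains, "A", "B", margins=[-0.1])

    def test_probability_label_granularity(self):
        chains = _delta_chains(np.zeros(1000))
        c = summarize_contrast(chains, "A", "B", margins=[0.05],
                               direction="higher_better")
        assert c.probability_label(0.05) == ">99%"

    def test_translation_invariance_of_contrasts(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(size=(2, 5000, 2))
        c1 = summarize_contrast(chains_from_theta(theta), "A", "B",
                                margins=[0.05], direction="higher_better")
        c2 = summarize_contrast(chains_from_theta(theta + 17.0), "A", "B",
                                margins=[0.05], direction="higher_better")
        assert c1.mean == pytest.approx(c2.mean)
        assert c1.noninferiority == c2.noninferiority


class TestPlaceboReferencedEffects:
    def _chains_with_placebo(self, family="normal"):
        rng = np.random.default_rng(4)
        theta = rng.normal(size=(2, 3000, 2)) * 0.05
        chains = chains_from_theta(theta, ("PBO", "ACT"), family=family)
        arms = [continuous_arm("S1", "PBO", -0.1, 0.02),
                continuous_arm("S1", "ACT", 0.05, 0.02)]
        ds = TrialDataset("fev1", [
            TreatmentRegimen("PBO", is_placebo=True),
            TreatmentRegimen("ACT")], arms)
        return chains, ds

    def test_placebo_vs_itself_is_null(self):
        chains, ds = self._chains_with_placebo()
        table = placebo_referenced_effects(chains, ds)
        row = table[table.treatment == "PBO"].iloc[0]
        assert row["mean"] == 0.0
        rr = placebo_referenced_effects(
            self._chains_with_placebo("poisson")[0], ds)
        assert rr[rr.treatment == "PBO"].iloc[0]["mean"] == 1.0

    def test_antisymmetry_draw_by_draw(self):
        chains, _ = self._chains_with_placebo()
        ab = chains.contrast_draws("ACT", "PBO")
        ba = chains.contrast_draws("PBO", "ACT")
        assert np.array_equal(ab, -ba)

    def test_missing_placebo_points_to_contrasts(self):
        chains, _ = self._chains_with_placebo()
        arms = [continuous_arm("S1", "PBO", -0.1, 0.02),
                continuous_arm("S1", "ACT", 0.05, 0.02)]
        ds = TrialDataset("fev1", [TreatmentRegimen("PBO"),
                                   TreatmentRegimen("ACT")], arms)
        with pytest.raises(ValueError, match="summarize_contrast"):
            placebo_referenced_effects(chains, ds)


class TestStandardizedResiduals:
    def test_definition_arithmetic(self):
        # constant draws -> fitted value 0.8 against observed 1.0, sd 0.1
        theta = np.full((1, 100, 2), 0.8)
        theta[:, :, 1] = 1.0
        chains = chains_from_theta(theta, ("A", "B"))
        arms = [continuous_arm("S1", "A", 1.0, 0.1),
                continuous_arm("S1", "B", 1.0, 0.1)]
        ds = TrialDataset("fev1", [TreatmentRegimen("A"),
                                   TreatmentRegimen("B")], arms)
        report = standardized_residuals(chains, ds)
        assert report.residuals[0] == pytest.approx(-2.0)
        assert report.residuals[1] == pytest.approx(0.0)
        assert report.worst_arm == ("S1", "A")


class TestRunAnalysis:
    @pytest.fixture
    def small_scenario(self):
        treatments = (TreatmentRegimen("PBO", "Placebo", is_placebo=True),
                      TreatmentRegimen("ACT1"), TreatmentRegimen("ACT2"))
        studies = tuple(
            StudyDesign(f"S{i}", pair, 150, 24, explicit_history=(i % 2 == 0))
            for i, pair in enumerate([
                ("PBO", "ACT1"), ("PBO", "ACT2"), ("ACT1", "ACT2"),
                ("PBO", "ACT1", "ACT2"), ("PBO", "ACT1"), ("PBO", "ACT2"),
            ]))
        return SyntheticScenario(
            endpoint="fev1", treatments=treatments,
            theta_true={"PBO": -0.1, "ACT1": 0.03, "ACT2": 0.01},
            studies=studies, beta_true={}, tau_true=0.01, seed=12)

    def test_bundle_written_and_deterministic(self, small_scenario, tmp_path):
        ds, _ = simulate_dataset(small_scenario)
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        for out in (out1, out2):
            run_analysis(ds, settings=FAST, output_dir=out,
                         margins=[0.05], label="golden")
        for name in ("contrasts.csv", "placebo_ref.csv", "residuals.csv",
                     "network_edges.csv", "manifest.json"):
            assert (out1 / name).exists()
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
        manifest = json.loads((out1 / "manifest.json").read_text())
        assert manifest["endpoint"] == "fev1"
        assert manifest["seed"] == FAST.seed
        assert manifest["n_studies"] == 6

    def test_sensitivity_rerun_with_filter(self, small_scenario, tmp_path):
        ds, _ = simulate_dataset(small_scenario)
        result = run_analysis(
            ds, settings=FAST, output_dir=tmp_path / "sens",
            study_filter=StudyFilter(require_history=True),
            margins=[0.05], label="sensitivity")
        assert result.manifest["label"] == "sensitivity"
        assert result.manifest["n_studies"] == 3
        assert (tmp_path / "sens" / "manifest.json").exists()

    def test_disconnected_requires_override(self):
        arms = [continuous_arm("S1", "A", 0.1, 0.02),
                continuous_arm("S1", "B", 0.0, 0.02),
                continuous_arm("S2", "C", 0.1, 0.02),
                continuous_arm("S2", "D", 0.0, 0.02)]
        ds = TrialDataset("fev1", [TreatmentRegimen(t)
                                   for t in "ABCD"], arms)
        with pytest.raises(RuntimeError, match="disconnected"):
            run_analysis(ds, settings=FAST)
        result = run_analysis(ds, settings=FAST, allow_disconnected=True)
        assert len(result.network.components) == 2

    def test_endpoint_required_for_paths(self, tmp_path):
        with pytest.raises(ValueError, match="endpoint"):
            run_analysis(tmp_path / "x.csv")
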