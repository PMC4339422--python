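"""Posterior summaries: contrasts, non-inferiority probabilities, residuals.

The clinically reported quantities are pairwise treatment contrasts. For
continuous endpoints the contrast is the per-draw mean difference
delta = theta_new - theta_ref (litres for FEV1, score units for SGRQ); for
the exacerbation endpoint it is the per-draw rate ratio exp(delta). The
posterior probability of non-inferiority at margin m follows the endpoint's
direction convention:

* higher is better (FEV1):      P(delta > -m)
* lower is better (SGRQ):       P(delta < +m)
* rate ratio (exacerbations):   P(RR < 1 + m)

Credible intervals are equal-tailed 95% percentile intervals of the draws.
Model fit is assessed through standardized residuals, (posterior-mean fitted
value - observed value) / estimated sd, where the sd is the observation sd
the likelihood used (the reported standard error, the posterior mean of
sqrt(sigma^2) in shared-variance mode, or sqrt(fitted count) on the count
scale for the Poisson family).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm

from .data import TrialDataset, read_dataset
from .model import ModelDesign, ModelSpec
from .network import StudyFilter, TreatmentNetwork, build_network, filter_studies
from .sampler import (
    DiagnosticReport,
    PosteriorChains,
    SamplerSettings,
    diagnostics,
    run_mcmc,
)

logger = logging.getLogger("mtcni")

#: Direction conventions: whether a larger endpoint value favours the
#: patient. Exacerbation contrasts are rate ratios, where smaller is better.
ENDPOINT_DIRECTIONS = {
    "fev1": "higher_better",
    "sgrq": "lower_better",
    "exacerbation": "lower_better",
}

#: Default non-inferiority margins per endpoint: 50 mL for FEV1, 2 and 3
#: score units for SGRQ, 10% and 20% rate-ratio margins for exacerbations.
DEFAULT_MARGINS = {
    "fev1": (0.05,),
    "sgrq": (2.0, 3.0),
    "exacerbation": (0.10, 0.20),
}


@dataclass(frozen=True)
class ContrastSummary:
    """Posterior summary of one treatment pair."""

    t_new: str
    t_ref: str
    scale: str  # "mean_difference" | "rate_ratio"
    direction: str
    mean: float
    median: float
    ci_low: float
    ci_high: float
    noninferiority: dict[float, float]  # margin -> posterior probability

    def probability_label(self, margin: float) -> str:
        """Report-granularity probability: '>99%' beyond 0.99."""
        p = self.noninferiority[margin]
        return ">99%" if p > 0.99 else f"{round(100 * p):.0f}%"

    def to_row(self) -> dict:
        row = {
            "treatment": self.t_new,
            "comparator": self.t_ref,
            "scale": self.scale,
            "mean": self.mean,
            "median": self.median,
            "ci_2.5": self.ci_low,
            "ci_97.5": self.ci_high,
        }
        for m, p in self.noninferiority.items():
            row[f"p_noninferiority_{m:g}"] = p
        return row


def summarize_contrast(
    chains: PosteriorChains,
    t_new: str,
    t_ref: str,
    margins: Sequence[float] | None = None,
    direction: str | None = None,
) -> ContrastSummary:
    """Summarise the posterior contrast of ``t_new`` against ``t_ref``.

    For the normal family the summarised scale is the mean difference; for
    the Poisson family the rate ratio exp(theta_new - theta_ref), with
    non-inferiority read as RR < 1 + margin.
    """
    family = chains.spec.family
    if direction is None:
        direction = "lower_better" if family == "poisson" else "higher_better"
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown direction {direction!r}")
    delta = chains.contrast_draws(t_new, t_ref)
    if margins is None:
        margins = (0.05,) if family == "normal" else (0.10, 0.20)
    ni: dict[float, float] = {}
    for m in margins:
        if not m > 0:
            raise ValueError(f"non-inferiority margin must be > 0, got {m}")
        if family == "poisson":
            ni[float(m)] = float(np.mean(np.exp(delta) < 1.0 + m))
        elif direction == "higher_better":
            ni[float(m)] = float(np.mean(delta > -m))
        else:
            ni[float(m)] = float(np.mean(delta < m))
    summarised = np.exp(delta) if family == "poisson" else delta
    lo, med, hi = np.percentile(summarised, [2.5, 50.0, 97.5])
    return ContrastSummary(
        t_new=t_new,
        t_ref=t_ref,
        scale="rate_ratio" if family == "poisson" else "mean_difference",
        direction=direction,
        mean=float(np.mean(summarised)),
        median=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        noninferiority=ni,
    )


def normal_noninferiority_probability(
    delta_mean: float,
    delta_sd: float,
    margin: float,
    direction: str = "higher_better",
    method: str = "closed_form",
) -> float:
    """Non-inferiority probability for an exactly Normal contrast posterior.

    ``closed_form`` evaluates the Normal CDF; ``quadrature`` integrates the
    Normal density over the non-inferior region. Used to validate the
    draw-based estimate in :func:`summarize_contrast`.
    """
    if not delta_sd > 0:
        raise ValueError("delta_sd must be > 0")
    if direction == "higher_better":
        lo, hi = -margin, np.inf
    elif direction == "lower_better":
        lo, hi = -np.inf, margin
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if method == "closed_form":
        return float(norm.cdf(hi, delta_mean, delta_sd)
                     - norm.cdf(lo, delta_mean, delta_sd))
    if method == "quadrature":
        val, _ = integrate.quad(
            lambda x: norm.pdf(x, delta_mean, delta_sd), lo, hi)
        return float(val)
    raise ValueError(f"unknown method {method!r}")


def placebo_referenced_effects(
    chains: PosteriorChains, dataset: TrialDataset
) -> pd.DataFrame:
    """Per-treatment effects referenced to placebo.

    Continuous endpoints: posterior mean and 95% CrI of theta_t -
    theta_placebo. Poisson endpoint: the rate ratio exp(theta_t -
    theta_placebo), so the placebo row is identically 1.0.
    """
    placebo = dataset.placebo()
    if placebo is None or placebo.id not in chains.treatment_ids:
        raise ValueError(
            "no placebo regimen in the fitted network; use pairwise "
            "contrasts (summarize_contrast) instead")
    rows = []
    poisson = chains.spec.family == "poisson"
    for t in chains.treatment_ids:
        delta = chains.contrast_draws(t, placebo.id)
        vals = np.exp(delta) if poisson else delta
        lo, hi = np.percentile(vals, [2.5, 97.5])
        rows.append({
            "treatment": t,
            "scale": "rate_ratio_vs_placebo" if poisson
                     else "difference_vs_placebo",
            "mean": float(np.mean(vals)),
            "ci_2.5": float(lo),
            "ci_97.5": float(hi),
        })
    return pd.DataFrame(rows)


@dataclass
class ResidualReport:
    """Per-arm standardized residuals and model-fit flags."""

    arm_ids: list[tuple[str, str]]  # (study, treatment)
    residuals: np.ndarray
    threshold: float = 2.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.residuals)):
            raise ValueError("standardized residuals must be finite")

    @property
    def n_extreme(self) -> int:
        return int(np.sum(np.abs(self.residuals) > self.threshold))

    @property
    def worst_arm(self) -> tuple[str, str]:
        return self.arm_ids[int(np.argmax(np.abs(self.residuals)))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "study_id": [a[0] for a in self.arm_ids],
            "treatment_id": [a[1] for a in self.arm_ids],
            "std_residual": self.residuals,
        })


def standardized_residuals(
    chains: PosteriorChains,
    dataset: TrialDataset | ModelDesign,
    chunk: int = 1024,
) -> ResidualReport:
    """Standardized residuals: (posterior-mean fitted - observed) / sd.

    Normal family: the fitted value is the posterior-mean linear predictor
    (exact, since the predictor is linear in the parameters) and the sd is
    the observation sd used in the likelihood. Poisson family: the fitted
    count is person_years x posterior mean of exp(predictor), compared with
    the observed count on the sqrt(fitted-count) scale.
    """
    design = (dataset if isinstance(dataset, ModelDesign)
              else ModelDesign(dataset, chains.spec))
    state = chains.mean_state()
    arm_ids = [(design.study_ids[s], design.treatment_ids[t])
               for s, t in zip(design.study_idx, design.treat_idx)]
    if design.spec.family == "normal":
        fitted = design.linear_predictor(state)
        if design.spec.variance_mode == "reported_se":
            sd = np.sqrt(design.se2)
        else:
            sd = np.full(design.n_arms,
                         float(np.mean(np.sqrt(chains.sigma2))))
        if np.any(sd == 0):
            raise ValueError("zero observation sd")
        resid = (fitted - design.y) / sd
        return ResidualReport(arm_ids, resid)
    # Poisson: average exp(eta) over draws in chunks
    alpha = chains.alpha.reshape(-1, len(design.study_ids))
    theta = chains.theta.reshape(-1, len(design.treatment_ids))
    beta = chains.beta.reshape(-1, len(design.covariate_names))
    total = np.zeros(design.n_arms)
    n = alpha.shape[0]
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        eta = (alpha[sl][:, design.study_idx]
               + theta[sl][:, design.treat_idx])
        if beta.shape[1]:
            eta += beta[sl] @ design.Z.T
        total += np.exp(eta).sum(axis=0)
    fitted_counts = design.person_years * total / n
    sd = np.sqrt(fitted_counts)
    if np.any(sd == 0):
        raise ValueError("zero fitted count gives zero sd")
    resid = (fitted_counts - design.events) / sd
    return ResidualReport(arm_ids, resid)


# ----------------------------------------------------------------------
# End-to-end driver
# ----------------------------------------------------------------------

@dataclass
class AnalysisResult:
    """Bundle produced by :func:`run_analysis`."""

    dataset: TrialDataset
    network: TreatmentNetwork
    chains: PosteriorChains
    contrasts: list[ContrastSummary]
    placebo_table: pd.DataFrame | None
    residuals: ResidualReport
    diagnostics: DiagnosticReport
    manifest: dict = field(default_factory=dict)


def run_analysis(
    data: str | Path | TrialDataset,
    endpoint: str | None = None,
    spec: ModelSpec | None = None,
    settings: SamplerSettings = SamplerSettings(),
    output_dir: str | Path | None = None,
    study_filter: StudyFilter | None = None,
    margins: Sequence[float] | None = None,
    contrast_pairs: Sequence[tuple[str, str]] | None = None,
    allow_disconnected: bool = False,
    label: str = "analysis",
) -> AnalysisResult:
    """Read -> filter -> network -> fit -> summaries, optionally writing
    contrasts.csv, placebo_ref.csv, residuals.csv, diagnostics.csv and a
    manifest.json run record to ``output_dir``."""
    if isinstance(data, TrialDataset):
        dataset = data
    else:
        if endpoint is None:
            raise ValueError("endpoint is required when reading from a file")
        dataset = read_dataset(data, endpoint)
    endpoint = dataset.endpoint
    if study_filter is not None:
        dataset = filter_studies(dataset, study_filter)
    net = build_network(dataset)
    if not net.is_connected and not allow_disconnected:
        raise RuntimeError(
            f"treatment network has {len(net.components)} components; "
            "cross-component contrasts are prior-driven — pass "
            "allow_disconnected=True to proceed")
    spec = spec or ModelSpec.for_endpoint(endpoint)
    margins = tuple(margins) if margins else DEFAULT_MARGINS[endpoint]
    direction = ENDPOINT_DIRECTIONS[endpoint]

    design = ModelDesign(dataset, spec)
    chains = run_mcmc(design, settings=settings)
    diag = diagnostics(chains)

    if contrast_pairs is None:
        contrast_pairs = list(combinations(chains.treatment_ids, 2))
    contrasts = [
        summarize_contrast(chains, a, b, margins, direction)
        for a, b in contrast_pairs
    ]
    placebo_table = None
    if dataset.placebo() is not None:
        placebo_table = placebo_referenced_effects(chains, dataset)
    residuals = standardized_residuals(chains, design)

    manifest = {
        "label": label,
        "endpoint": endpoint,
        "seed": settings.seed,
        "settings": settings.to_dict(),
        "model_spec": spec.to_dict(),
        "margins": list(margins),
        "direction": direction,
        "n_studies": dataset.n_studies,
        "n_arms": len(dataset.arms),
        "n_treatments": len(dataset.treatments),
        "network_connected": net.is_connected,
        "n_components": len(net.components),
        "max_rhat": diag.max_rhat,
        "diagnostic_flags": diag.flags,
        "n_extreme_residuals": residuals.n_extreme,
    }
    result = AnalysisResult(dataset, net, chains, contrasts, placebo_table,
                            residuals, diag, manifest)
    if output_dir is not None:
        _write_bundle(result, Path(output_dir))
    return result


def _write_bundle(result: AnalysisResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([c.to_row() for c in result.contrasts]).to_csv(
        outdir / "contrasts.csv", index=False)
    if result.placebo_table is not None:
        result.placebo_table.to_csv(outdir / "placebo_ref.csv", index=False)
    result.residuals.to_frame().to_csv(outdir / "residuals.csv", index=False)
    result.diagnostics.to_frame().to_csv(
        outdir / "diagnostics.csv", index=False)
    result.network.write_edge_list(outdir / "network_edges.csv")
    result.network.write_dot(outdir / "network.dot")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    logger.info("analysis bundle written to %s", outdir)
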