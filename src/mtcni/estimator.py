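"""Scikit-learn-style estimator facade over the MTC pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .data import TrialDataset, dataset_from_frame, read_dataset
from .inference import (
    ContrastSummary,
    DEFAULT_MARGINS,
    ENDPOINT_DIRECTIONS,
    ResidualReport,
    placebo_referenced_effects,
    standardized_residuals,
    summarize_contrast,
)
from .model import ModelDesign, ModelSpec
from .network import StudyFilter, build_network, filter_studies
from .sampler import SamplerSettings, diagnostics, run_mcmc


class NetworkMetaAnalysis(BaseEstimator):
    """Covariate-adjusted Bayesian mixed treatment comparison.

    Fits the arm-based hierarchical model (Normal likelihood for continuous
    endpoints, Poisson with person-years offset for exacerbation rates) to
    an arm-level trial dataset by adaptive Metropolis-Hastings MCMC, and
    exposes posterior treatment contrasts, non-inferiority probabilities and
    model-fit residuals.

    Parameters
    ----------
    covariate_set : {"full", "duration_only", "none"}
        Meta-regression covariates entering the linear predictor.
    variance_mode : {"reported_se", "shared_sigma"}
        Continuous-endpoint observation variance: each arm's reported
        squared standard error treated as known (default), or a shared
        residual variance with an Inverse-Gamma(0.001, 0.001) prior.
    n_chains, n_burnin, n_draws, thinning, adapt_window, target_accept,
    initial_step, seed
        MCMC settings; step sizes adapt towards ``target_accept`` during
        burn-in only, and a fixed seed gives bit-identical chains.
    study_filter : StudyFilter, optional
        Sensitivity-analysis study selection applied before fitting.
    allow_disconnected : bool
        Proceed on a disconnected treatment network (cross-component
        contrasts are then prior-driven).

    Attributes
    ----------
    dataset_ : TrialDataset
        The (possibly filtered) dataset that was fitted.
    network_ : TreatmentNetwork
        Treatment network of ``dataset_``.
    chains_ : PosteriorChains
        Posterior draws with adaptation metadata.
    diagnostics_ : DiagnosticReport
        Split-Rhat, effective sample sizes and acceptance flags.

    Examples
    --------
    >>> from mtcni import NetworkMetaAnalysis, make_copd_network
    >>> from mtcni.synthetic import simulate_dataset
    >>> data, truth = simulate_dataset(make_copd_network("fev1"))
    >>> nma = NetworkMetaAnalysis(n_chains=2, n_burnin=500, n_draws=2000)
    >>> summary = nma.fit(data).contrast("FFVI", "FPSAL", margins=[0.05])
    """

    def __init__(
        self,
        covariate_set: str = "full",
        variance_mode: str = "reported_se",
        treatment_prior_sd: float = 100.0,
        covariate_prior_sd: float = 10.0,
        study_mean_prior_sd: float = 10.0,
        variance_prior_shape: float = 0.001,
        variance_prior_rate: float = 0.001,
        n_chains: int = 4,
        n_burnin: int = 10_000,
        n_draws: int = 40_000,
        thinning: int = 1,
        adapt_window: int = 50,
        target_accept: float = 0.44,
        initial_step: float = 0.1,
        seed: int = 0,
        study_filter: StudyFilter | None = None,
        allow_disconnected: bool = False,
    ) -> None:
        self.covariate_set = covariate_set
        self.variance_mode = variance_mode
        self.treatment_prior_sd = treatment_prior_sd
        self.covariate_prior_sd = covariate_prior_sd
        self.study_mean_prior_sd = study_mean_prior_sd
        self.variance_prior_shape = variance_prior_shape
        self.variance_prior_rate = variance_prior_rate
        self.n_chains = n_chains
        self.n_burnin = n_burnin
        self.n_draws = n_draws
        self.thinning = thinning
        self.adapt_window = adapt_window
        self.target_accept = target_accept
        self.initial_step = initial_step
        self.seed = seed
        self.study_filter = study_filter
        self.allow_disconnected = allow_disconnected

    # ------------------------------------------------------------------
    def _model_spec(self, endpoint: str) -> ModelSpec:
        return ModelSpec.for_endpoint(
            endpoint,
            covariate_set=self.covariate_set,
            variance_mode=self.variance_mode,
            treatment_prior_sd=self.treatment_prior_sd,
            covariate_prior_sd=self.covariate_prior_sd,
            study_mean_prior_sd=self.study_mean_prior_sd,
            variance_prior_shape=self.variance_prior_shape,
            variance_prior_rate=self.variance_prior_rate,
        )

    def _sampler_settings(self) -> SamplerSettings:
        return SamplerSettings(
            n_chains=self.n_chains, n_burnin=self.n_burnin,
            n_draws=self.n_draws, thinning=self.thinning,
            adapt_window=self.adapt_window,
            target_accept=self.target_accept,
            initial_step=self.initial_step, seed=self.seed,
        )

    def fit(self, X, y=None, endpoint: str | None = None):
        """Fit the model to a :class:`TrialDataset`, an arm-level DataFrame
        or a CSV path (``endpoint`` required for the latter two)."""
        if isinstance(X, TrialDataset):
            dataset = X
        elif isinstance(X, pd.DataFrame):
            if endpoint is None:
                raise ValueError("endpoint is required with a DataFrame")
            dataset = dataset_from_frame(X, endpoint)
        else:
            if endpoint is None:
                raise ValueError("endpoint is required with a file path")
            dataset = read_dataset(Path(X), endpoint)
        if self.study_filter is not None:
            dataset = filter_studies(dataset, self.study_filter)
        network = build_network(dataset)
        if not network.is_connected and not self.allow_disconnected:
            raise RuntimeError(
                "treatment network is disconnected; set "
                "allow_disconnected=True to fit anyway")
        spec = self._model_spec(dataset.endpoint)
        design = ModelDesign(dataset, spec)
        chains = run_mcmc(design, settings=self._sampler_settings())
        self.dataset_ = dataset
        self.network_ = network
        self.spec_ = spec
        self.design_ = design
        self.chains_ = chains
        self.diagnostics_ = diagnostics(chains)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "chains_"):
            raise NotFittedError(
                "this NetworkMetaAnalysis instance is not fitted yet")

    # -- posterior summaries -------------------------------------------
    def contrast(self, t_new: str, t_ref: str,
                 margins: Sequence[float] | None = None,
                 direction: str | None = None) -> ContrastSummary:
        self._check_fitted()
        endpoint = self.dataset_.endpoint
        return summarize_contrast(
            self.chains_, t_new, t_ref,
            margins if margins is not None else DEFAULT_MARGINS[endpoint],
            direction or ENDPOINT_DIRECTIONS[endpoint])

    def placebo_referenced(self) -> pd.DataFrame:
        self._check_fitted()
        return placebo_referenced_effects(self.chains_, self.dataset_)

    def residuals(self) -> ResidualReport:
        self._check_fitted()
        return standardized_residuals(self.chains_, self.design_)
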