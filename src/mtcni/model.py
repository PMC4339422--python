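"""The arm-based hierarchical model: likelihoods, priors, log-posterior.

The model gives every study an additive effect alpha_s drawn from a common
Normal distribution, alpha_s ~ N(mu, tau^2), and every treatment regimen an
independent effect theta_t with a proper but very diffuse Normal prior.
Observed arm-level outcomes enter through

* a Normal likelihood on the endpoint scale for continuous endpoints,
      Y ~ N(alpha_s + theta_t + beta.Z, s^2),
  where s^2 is either the arm's reported squared standard error (treated as
  known; the default) or a shared residual variance sigma^2 with an
  Inverse-Gamma(0.001, 0.001) prior; and

* a Poisson likelihood for exacerbation counts with a person-years offset,
      Exac ~ Poisson(person_years * rate),  log(rate) = alpha_s + theta_t + beta.Z.

Hyperpriors: mu ~ N(0, 10^2), tau^2 ~ Inverse-Gamma(0.001, 0.001); treatment
effects theta_t ~ N(0, 100^2); covariate coefficients beta_k ~ N(0, 10^2).
All priors are proper, which keeps posteriors integrable even on weak or
disconnected treatment networks.

Because study effects absorb a common shift (adding c to every theta and
subtracting it from mu and every alpha leaves the likelihood unchanged),
only treatment *contrasts* theta_t - theta_t' are likelihood-identified;
the proper priors break the tie, and all reported summaries are contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml
from scipy.special import gammaln

from .data import (
    ArmRecord,
    CovariateVector,
    DEFAULT_DURATION_CUTS,
    TrialDataset,
    covariate_columns,
    estimate_person_years,
    normalize_covariates,
    reconstruct_events,
)

FAMILIES = ("normal", "poisson")
COVARIATE_SETS = ("full", "duration_only", "none")
VARIANCE_MODES = ("reported_se", "shared_sigma")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Endpoint family, covariate set and prior hyperparameters."""

    family: str = "normal"
    covariate_set: str = "full"
    treatment_prior_sd: float = 100.0
    covariate_prior_sd: float = 10.0
    study_mean_prior_sd: float = 10.0
    variance_prior_shape: float = 0.001
    variance_prior_rate: float = 0.001
    variance_mode: str = "reported_se"
    duration_cuts: tuple[float, float, float] = DEFAULT_DURATION_CUTS

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.covariate_set not in COVARIATE_SETS:
            raise ValueError(f"unknown covariate_set {self.covariate_set!r}")
        if self.variance_mode not in VARIANCE_MODES:
            raise ValueError(f"unknown variance_mode {self.variance_mode!r}")
        for name in ("treatment_prior_sd", "covariate_prior_sd",
                     "study_mean_prior_sd", "variance_prior_shape",
                     "variance_prior_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def for_endpoint(cls, endpoint: str, covariate_set: str = "full",
                     **kwargs) -> "ModelSpec":
        family = "poisson" if endpoint == "exacerbation" else "normal"
        return cls(family=family, covariate_set=covariate_set, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["duration_cuts"] = list(self.duration_cuts)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if "duration_cuts" in d:
            d["duration_cuts"] = tuple(d["duration_cuts"])
        return cls(**d)


@dataclass
class ParameterState:
    """One point in parameter space.

    ``alpha`` holds one study effect per study (endpoint units or log-rate
    scale), ``theta`` one effect per treatment, ``beta`` one coefficient per
    covariate column; ``mu``/``tau2`` are the study-effect mean and variance,
    and ``sigma2`` the shared residual variance (normal family,
    ``shared_sigma`` mode only).
    """

    study_ids: tuple[str, ...]
    treatment_ids: tuple[str, ...]
    covariate_names: tuple[str, ...]
    alpha: np.ndarray
    theta: np.ndarray
    beta: np.ndarray
    mu: float = 0.0
    tau2: float = 1.0
    sigma2: float | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha.shape != (len(self.study_ids),):
            raise ValueError("alpha must have one entry per study")
        if self.theta.shape != (len(self.treatment_ids),):
            raise ValueError("theta must have one entry per treatment")
        if self.beta.shape != (len(self.covariate_names),):
            raise ValueError("beta must have one entry per covariate")

    def copy(self) -> "ParameterState":
        return ParameterState(
            self.study_ids, self.treatment_ids, self.covariate_names,
            self.alpha.copy(), self.theta.copy(), self.beta.copy(),
            self.mu, self.tau2, self.sigma2,
        )

    def in_support(self) -> bool:
        if not self.tau2 > 0:
            return False
        if self.sigma2 is not None and not self.sigma2 > 0:
            return False
        return True


class ModelDesign:
    """Preprocessed arrays of one (dataset, spec) pair.

    Covariates are normalised, person-years and event counts reconstructed,
    and arm-level quantities stacked into flat arrays so the likelihood is a
    handful of vectorised operations. This is the representation the sampler
    and the grid oracle share.
    """

    def __init__(self, dataset: TrialDataset, spec: ModelSpec) -> None:
        self.spec = spec
        self.endpoint = dataset.endpoint
        self.study_ids = tuple(dataset.study_ids)
        self.treatment_ids = tuple(dataset.treatment_ids)
        self.covariate_names = covariate_columns(spec.covariate_set)
        study_index = {s: i for i, s in enumerate(self.study_ids)}
        treat_index = {t: i for i, t in enumerate(self.treatment_ids)}

        n = len(dataset.arms)
        self.n_arms = n
        self.study_idx = np.array(
            [study_index[a.study_id] for a in dataset.arms], dtype=int)
        self.treat_idx = np.array(
            [treat_index[a.treatment_id] for a in dataset.arms], dtype=int)
        self.Z = np.zeros((n, len(self.covariate_names)))
        for i, arm in enumerate(dataset.arms):
            z = normalize_covariates(arm, spec.duration_cuts)
            self.Z[i] = z.as_array(self.covariate_names)

        if spec.family == "normal":
            self.y = np.array(
                [a.continuous_payload.mean_change for a in dataset.arms])
            self.se2 = np.array(
                [a.continuous_payload.std_error ** 2 for a in dataset.arms])
        else:
            py = np.array([estimate_person_years(a) for a in dataset.arms])
            self.person_years = py
            self.events = np.array(
                [reconstruct_events(a, p)
                 for a, p in zip(dataset.arms, py)], dtype=float)
            self.log_fact = gammaln(self.events + 1.0)

        # arm index lists per study / treatment, for cheap scalar updates
        self.arms_by_study = [
            np.flatnonzero(self.study_idx == s)
            for s in range(len(self.study_ids))]
        self.arms_by_treatment = [
            np.flatnonzero(self.treat_idx == t)
            for t in range(len(self.treatment_ids))]

    # -- predictor and likelihood --------------------------------------
    def linear_predictor(self, state: ParameterState) -> np.ndarray:
        eta = state.alpha[self.study_idx] + state.theta[self.treat_idx]
        if self.Z.shape[1]:
            eta = eta + self.Z @ state.beta
        return eta

    def loglik_terms(self, eta: np.ndarray,
                     state: ParameterState) -> np.ndarray:
        """Per-arm log-likelihood contributions (constants included)."""
        if self.spec.family == "normal":
            var = self._obs_var(state)
            return -0.5 * (np.log(2.0 * np.pi * var)
                           + (self.y - eta) ** 2 / var)
        lam = self.person_years * np.exp(eta)
        return self.events * np.log(lam) - lam - self.log_fact

    def _obs_var(self, state: ParameterState) -> np.ndarray:
        if self.spec.variance_mode == "reported_se":
            return self.se2
        if state.sigma2 is None:
            raise ValueError("shared_sigma mode requires state.sigma2")
        return np.full_like(self.se2, state.sigma2)

    def observation_sd(self, state: ParameterState) -> np.ndarray:
        """Per-arm observation sd used in the likelihood (normal family)."""
        return np.sqrt(self._obs_var(state))

    def log_likelihood(self, state: ParameterState) -> float:
        if self.n_arms == 0:
            return 0.0
        eta = self.linear_predictor(state)
        if not np.all(np.isfinite(eta)):
            bad = int(np.flatnonzero(~np.isfinite(eta))[0])
            raise FloatingPointError(
                "non-finite linear predictor at arm "
                f"{self.study_ids[self.study_idx[bad]]}/"
                f"{self.treatment_ids[self.treat_idx[bad]]}"
            )
        return float(np.sum(self.loglik_terms(eta, state)))

    # -- priors --------------------------------------------------------
    def log_prior(self, state: ParameterState) -> float:
        spec = self.spec
        if not state.in_support():
            return -np.inf
        lp = float(np.sum(_normal_logpdf(state.alpha, state.mu, state.tau2)))
        lp += _normal_logpdf(state.mu, 0.0, spec.study_mean_prior_sd ** 2)
        lp += _invgamma_logpdf(state.tau2, spec.variance_prior_shape,
                               spec.variance_prior_rate)
        lp += float(np.sum(_normal_logpdf(
            state.theta, 0.0, spec.treatment_prior_sd ** 2)))
        lp += float(np.sum(_normal_logpdf(
            state.beta, 0.0, spec.covariate_prior_sd ** 2)))
        if spec.family == "normal" and spec.variance_mode == "shared_sigma":
            lp += _invgamma_logpdf(state.sigma2, spec.variance_prior_shape,
                                   spec.variance_prior_rate)
        return lp

    def log_posterior(self, state: ParameterState) -> float:
        lp = self.log_prior(state)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(state)

    # -- convenience ---------------------------------------------------
    def new_state(self, alpha=None, theta=None, beta=None, mu=0.0,
                  tau2=1.0, sigma2=None) -> ParameterState:
        S, T, K = (len(self.study_ids), len(self.treatment_ids),
                   len(self.covariate_names))
        if sigma2 is None and (self.spec.family == "normal"
                               and self.spec.variance_mode == "shared_sigma"):
            sigma2 = 1.0
        return ParameterState(
            self.study_ids, self.treatment_ids, self.covariate_names,
            np.zeros(S) if alpha is None else np.asarray(alpha, float),
            np.zeros(T) if theta is None else np.asarray(theta, float),
            np.zeros(K) if beta is None else np.asarray(beta, float),
            mu, tau2, sigma2,
        )


def _normal_logpdf(x, mean, var):
    x = np.asarray(x, dtype=float)
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


def _invgamma_logpdf(x: float, shape: float, rate: float) -> float:
    if not x > 0:
        return -np.inf
    return (shape * np.log(rate) - gammaln(shape)
            - (shape + 1.0) * np.log(x) - rate / x)


# ----------------------------------------------------------------------
# Spec-level operations on single arms / whole datasets
# ----------------------------------------------------------------------

def linear_predictor(state: ParameterState, arm: ArmRecord,
                     z: CovariateVector) -> float:
    """alpha_s + theta_t + beta.Z for one arm (identity link for the normal
    family, log link for the Poisson family)."""
    try:
        s = state.study_ids.index(arm.study_id)
    except ValueError:
        raise KeyError(f"unknown study id {arm.study_id!r}") from None
    try:
        t = state.treatment_ids.index(arm.treatment_id)
    except ValueError:
        raise KeyError(f"unknown treatment id {arm.treatment_id!r}") from None
    zvec = z.as_array(state.covariate_names)
    return float(state.alpha[s] + state.theta[t] + zvec @ state.beta)


def log_likelihood(state: ParameterState, dataset: TrialDataset,
                   spec: ModelSpec | None = None) -> float:
    """Joint log-likelihood of a dataset under a parameter state."""
    spec = spec or ModelSpec.for_endpoint(dataset.endpoint)
    return ModelDesign(dataset, spec).log_likelihood(state)


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Joint log-prior density of a parameter state (−inf off-support)."""
    if not state.in_support():
        return -np.inf
    lp = float(np.sum(_normal_logpdf(state.alpha, state.mu, state.tau2)))
    lp += _normal_logpdf(state.mu, 0.0, spec.study_mean_prior_sd ** 2)
    lp += _invgamma_logpdf(state.tau2, spec.variance_prior_shape,
                           spec.variance_prior_rate)
    lp += float(np.sum(_normal_logpdf(
        state.theta, 0.0, spec.treatment_prior_sd ** 2)))
    lp += float(np.sum(_normal_logpdf(
        state.beta, 0.0, spec.covariate_prior_sd ** 2)))
    if spec.family == "normal" and spec.variance_mode == "shared_sigma":
        lp += _invgamma_logpdf(state.sigma2, spec.variance_prior_shape,
                               spec.variance_prior_rate)
    return lp


def log_posterior(state: ParameterState, dataset: TrialDataset,
                  spec: ModelSpec) -> float:
    lp = log_prior(state, spec)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(state, dataset, spec)
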