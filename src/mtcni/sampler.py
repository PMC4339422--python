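"""Posterior sampling: adaptive Metropolis-Hastings with Gibbs sub-steps.

Scalar parameters without a conjugate full conditional (treatment effects,
covariate coefficients, and study effects in the Poisson family) are updated
by Gaussian random-walk Metropolis steps whose step sizes adapt towards a
0.44 acceptance rate during burn-in only, so the retained draws target the
exact posterior. Conjugate blocks are Gibbs-sampled: the study-effect mean
mu and variance tau^2 always (Normal-Inverse-Gamma), and in the normal
family the study effects alpha_s (Normal) and, in ``shared_sigma`` mode, the
residual variance sigma^2 (Inverse-Gamma).

A brute-force grid oracle (:func:`grid_posterior_oracle`) integrates the
same log-posterior by direct summation over a bounded grid for toy problems
with at most three free parameters; it exists to validate the sampler and is
never part of an analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd

from .data import TrialDataset
from .model import ModelDesign, ModelSpec, ParameterState

logger = logging.getLogger("mtcni")


class InitialisationError(RuntimeError):
    """The initial parameter state has a non-finite log-posterior."""


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC run configuration; the seed is recorded in every output."""

    n_chains: int = 4
    n_burnin: int = 10_000
    n_draws: int = 40_000
    thinning: int = 1
    adapt_window: int = 50
    target_accept: float = 0.44
    initial_step: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_burnin", "n_draws", "thinning",
                     "adapt_window"):
            if getattr(self, name) < 1 and name != "n_burnin":
                raise ValueError(f"{name} must be positive")
        if self.n_burnin < 0:
            raise ValueError("n_burnin must be >= 0")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PosteriorChains:
    """Seeded posterior draws plus adaptation and acceptance metadata.

    Draw arrays have shape ``(n_chains, n_kept, dim)`` (scalar blocks:
    ``(n_chains, n_kept)``); ``n_kept = n_draws // thinning``.
    """

    study_ids: tuple[str, ...]
    treatment_ids: tuple[str, ...]
    covariate_names: tuple[str, ...]
    alpha: np.ndarray
    theta: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    tau2: np.ndarray
    sigma2: np.ndarray | None
    acceptance: dict[str, float]
    step_sizes: dict[str, float]
    step_trajectory: dict[str, np.ndarray]
    settings: SamplerSettings
    spec: ModelSpec

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_kept(self) -> int:
        return self.theta.shape[1]

    def _tidx(self, treatment_id: str) -> int:
        try:
            return self.treatment_ids.index(treatment_id)
        except ValueError:
            raise KeyError(f"treatment {treatment_id!r} not in chains") from None

    def theta_draws(self, treatment_id: str, per_chain: bool = False) -> np.ndarray:
        d = self.theta[:, :, self._tidx(treatment_id)]
        return d if per_chain else d.reshape(-1)

    def contrast_draws(self, t_new: str, t_ref: str,
                       per_chain: bool = False) -> np.ndarray:
        """Per-draw treatment contrast theta_new - theta_ref."""
        d = (self.theta[:, :, self._tidx(t_new)]
             - self.theta[:, :, self._tidx(t_ref)])
        return d if per_chain else d.reshape(-1)

    def mean_state(self) -> ParameterState:
        """Posterior-mean parameter state (for fitted values/residuals)."""
        return ParameterState(
            self.study_ids, self.treatment_ids, self.covariate_names,
            self.alpha.mean(axis=(0, 1)),
            self.theta.mean(axis=(0, 1)),
            self.beta.mean(axis=(0, 1)) if self.beta.size else
            np.zeros(len(self.covariate_names)),
            float(self.mu.mean()),
            float(self.tau2.mean()),
            float(self.sigma2.mean()) if self.sigma2 is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat draws table, one column per scalar parameter."""
        cols: dict[str, np.ndarray] = {}
        for i, s in enumerate(self.study_ids):
            cols[f"alpha[{s}]"] = self.alpha[:, :, i].reshape(-1)
        for i, t in enumerate(self.treatment_ids):
            cols[f"theta[{t}]"] = self.theta[:, :, i].reshape(-1)
        for i, c in enumerate(self.covariate_names):
            cols[f"beta[{c}]"] = self.beta[:, :, i].reshape(-1)
        cols["mu"] = self.mu.reshape(-1)
        cols["tau2"] = self.tau2.reshape(-1)
        if self.sigma2 is not None:
            cols["sigma2"] = self.sigma2.reshape(-1)
        df = pd.DataFrame(cols)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_kept))
        df.insert(1, "draw", np.tile(np.arange(self.n_kept), self.n_chains))
        return df


def _initial_state(design: ModelDesign,
                   fixed: Mapping[str, object]) -> ParameterState:
    """Data-informed start: study effects at crude per-study outcomes."""
    S = len(design.study_ids)
    alpha = np.zeros(S)
    for s in range(S):
        idx = design.arms_by_study[s]
        if design.spec.family == "normal":
            alpha[s] = float(np.mean(design.y[idx]))
        else:
            alpha[s] = float(np.log(
                (np.sum(design.events[idx]) + 0.5)
                / np.sum(design.person_years[idx])))
    state = design.new_state(alpha=alpha, mu=float(np.mean(alpha)), tau2=0.1)
    if design.spec.family == "normal" and \
            design.spec.variance_mode == "shared_sigma":
        state.sigma2 = 0.1
    for name, value in fixed.items():
        if name == "alpha":
            state.alpha = np.broadcast_to(
                np.asarray(value, float), state.alpha.shape).copy()
        elif name in ("mu", "tau2", "sigma2"):
            setattr(state, name, float(value))
        else:
            raise ValueError(f"cannot fix unknown parameter {name!r}")
    if "mu" not in fixed and "alpha" in fixed:
        state.mu = float(np.mean(state.alpha))
    return state


class _StepAdapter:
    """Per-parameter random-walk scale, tuned during burn-in only."""

    def __init__(self, names: Sequence[str], initial: float, window: int,
                 target: float) -> None:
        self.log_step = {n: np.log(initial) for n in names}
        self.window = window
        self.target = target
        self.accepts = {n: 0 for n in names}
        self.batch = 0
        self.trajectory: dict[str, list[float]] = {n: [] for n in names}
        self.frozen = False

    def step(self, name: str) -> float:
        return float(np.exp(self.log_step[name]))

    def record(self, name: str, accepted: bool) -> None:
        if accepted:
            self.accepts[name] += 1

    def maybe_adapt(self, iteration: int) -> None:
        if self.frozen or (iteration + 1) % self.window != 0:
            return
        self.batch += 1
        delta = min(0.25, 1.0 / np.sqrt(self.batch))
        for name in self.log_step:
            rate = self.accepts[name] / self.window
            self.log_step[name] += delta if rate > self.target else -delta
            self.trajectory[name].append(self.step(name))
            self.accepts[name] = 0

    def freeze(self) -> None:
        self.frozen = True
        self.accepts = {n: 0 for n in self.accepts}


def run_mcmc(
    dataset: TrialDataset | ModelDesign,
    spec: ModelSpec | None = None,
    settings: SamplerSettings = SamplerSettings(),
    fixed: Mapping[str, object] | None = None,
) -> PosteriorChains:
    """Draw posterior samples for a dataset under a model specification.

    ``fixed`` pins named blocks (``alpha``, ``mu``, ``tau2``, ``sigma2``) at
    given values instead of sampling them — used by toy validations against
    closed-form and grid oracles. A fixed seed yields bit-identical chains.
    """
    if isinstance(dataset, ModelDesign):
        design = dataset
    else:
        design = ModelDesign(dataset, spec or ModelSpec.for_endpoint(dataset.endpoint))
    spec = design.spec
    fixed = dict(fixed or {})
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)

    n_kept = settings.n_draws // settings.thinning
    S, T, K = (len(design.study_ids), len(design.treatment_ids),
               len(design.covariate_names))
    shared_sigma = (spec.family == "normal"
                    and spec.variance_mode == "shared_sigma")
    out = {
        "alpha": np.empty((settings.n_chains, n_kept, S)),
        "theta": np.empty((settings.n_chains, n_kept, T)),
        "beta": np.empty((settings.n_chains, n_kept, K)),
        "mu": np.empty((settings.n_chains, n_kept)),
        "tau2": np.empty((settings.n_chains, n_kept)),
        "sigma2": np.empty((settings.n_chains, n_kept)) if shared_sigma else None,
    }
    acc_totals: dict[str, list[float]] = {}
    final_steps: dict[str, float] = {}
    trajectories: dict[str, np.ndarray] = {}

    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        chain = _run_single_chain(design, settings, fixed, rng, out, c)
        for name, rate in chain["acceptance"].items():
            acc_totals.setdefault(name, []).append(rate)
        if c == 0:
            final_steps = chain["steps"]
            trajectories = chain["trajectory"]

    return PosteriorChains(
        study_ids=design.study_ids,
        treatment_ids=design.treatment_ids,
        covariate_names=design.covariate_names,
        alpha=out["alpha"], theta=out["theta"], beta=out["beta"],
        mu=out["mu"], tau2=out["tau2"], sigma2=out["sigma2"],
        acceptance={n: float(np.mean(v)) for n, v in acc_totals.items()},
        step_sizes=final_steps,
        step_trajectory=trajectories,
        settings=settings,
        spec=spec,
    )


def _run_single_chain(design: ModelDesign, settings: SamplerSettings,
                      fixed: Mapping[str, object],
                      rng: np.random.Generator,
                      out: dict, chain_idx: int) -> dict:
    spec = design.spec
    S, T, K = (len(design.study_ids), len(design.treatment_ids),
               len(design.covariate_names))
    normal = spec.family == "normal"
    shared_sigma = normal and spec.variance_mode == "shared_sigma"
    a_prior = spec.variance_prior_shape
    b_prior = spec.variance_prior_rate
    theta_var = spec.treatment_prior_sd ** 2
    beta_var = spec.covariate_prior_sd ** 2
    mu_var = spec.study_mean_prior_sd ** 2

    state = _initial_state(design, fixed)
    if not np.isfinite(design.log_posterior(state)):
        raise InitialisationError(
            "initial state has non-finite log-posterior")

    mh_names = ([f"theta[{t}]" for t in design.treatment_ids]
                + [f"beta[{k}]" for k in design.covariate_names])
    if not normal:
        mh_names += [f"alpha[{s}]" for s in design.study_ids]
    # Joint recentering move along the likelihood-flat translation
    # direction (theta + c, alpha - c, mu - c): only the proper priors
    # enter the accept ratio, so this mixes the weakly identified common
    # level that scalar updates traverse slowly.
    use_shift = "alpha" not in fixed and "mu" not in fixed
    if use_shift:
        mh_names.append("shift")
    adapter = _StepAdapter(mh_names, settings.initial_step,
                           settings.adapt_window, settings.target_accept)
    if use_shift:
        # the translation direction is constrained only by the diffuse
        # priors, so its natural scale is far larger than a data-informed
        # parameter's
        adapter.log_step["shift"] = np.log(
            max(settings.initial_step, 1.0))
    acc_count = {n: 0 for n in mh_names}
    # column sparsity for covariate updates
    z_nonzero = [np.flatnonzero(design.Z[:, k]) for k in range(K)]

    eta = design.linear_predictor(state)
    obs_var = design.se2.copy() if normal else None
    if shared_sigma:
        obs_var = np.full(design.n_arms, state.sigma2)

    def loglik_delta(idx: np.ndarray, eta_new_idx: np.ndarray) -> float:
        if normal:
            r_new = design.y[idx] - eta_new_idx
            r_old = design.y[idx] - eta[idx]
            return float(np.sum((r_old ** 2 - r_new ** 2)
                                / (2.0 * obs_var[idx])))
        d_eta = eta_new_idx - eta[idx]
        return float(np.sum(design.events[idx] * d_eta
                            - design.person_years[idx]
                            * (np.exp(eta_new_idx) - np.exp(eta[idx]))))

    n_iter = settings.n_burnin + settings.n_draws
    kept = 0
    for it in range(n_iter):
        in_burnin = it < settings.n_burnin

        # --- Gibbs: alpha (normal family) -----------------------------
        if normal and "alpha" not in fixed:
            resid = design.y - (eta - state.alpha[design.study_idx])
            w = 1.0 / obs_var
            A = np.bincount(design.study_idx, weights=w * resid, minlength=S)
            B = np.bincount(design.study_idx, weights=w, minlength=S)
            prec = B + 1.0 / state.tau2
            mean = (A + state.mu / state.tau2) / prec
            state.alpha = mean + rng.standard_normal(S) / np.sqrt(prec)
            eta = design.linear_predictor(state)

        # --- MH: alpha (Poisson family) -------------------------------
        if not normal and "alpha" not in fixed:
            for s in range(S):
                name = f"alpha[{design.study_ids[s]}]"
                step = adapter.step(name)
                prop = state.alpha[s] + step * rng.standard_normal()
                idx = design.arms_by_study[s]
                d_eta = prop - state.alpha[s]
                delta = loglik_delta(idx, eta[idx] + d_eta)
                delta += ((state.alpha[s] - state.mu) ** 2
                          - (prop - state.mu) ** 2) / (2.0 * state.tau2)
                accepted = np.log(rng.random()) < delta
                if accepted:
                    state.alpha[s] = prop
                    eta[idx] += d_eta
                    if not in_burnin:
                        acc_count[name] += 1
                adapter.record(name, accepted)

        # --- MH: theta -------------------------------------------------
        for t in range(T):
            name = f"theta[{design.treatment_ids[t]}]"
            step = adapter.step(name)
            prop = state.theta[t] + step * rng.standard_normal()
            idx = design.arms_by_treatment[t]
            d_eta = prop - state.theta[t]
            delta = loglik_delta(idx, eta[idx] + d_eta)
            delta += (state.theta[t] ** 2 - prop ** 2) / (2.0 * theta_var)
            accepted = np.log(rng.random()) < delta
            if accepted:
                state.theta[t] = prop
                eta[idx] += d_eta
                if not in_burnin:
                    acc_count[name] += 1
            adapter.record(name, accepted)

        # --- MH: beta ---------------------------------------------------
        for k in range(K):
            name = f"beta[{design.covariate_names[k]}]"
            step = adapter.step(name)
            prop = state.beta[k] + step * rng.standard_normal()
            idx = z_nonzero[k]
            if idx.size:
                d_eta = design.Z[idx, k] * (prop - state.beta[k])
                delta = loglik_delta(idx, eta[idx] + d_eta)
            else:
                d_eta = None
                delta = 0.0
            delta += (state.beta[k] ** 2 - prop ** 2) / (2.0 * beta_var)
            accepted = np.log(rng.random()) < delta
            if accepted:
                state.beta[k] = prop
                if idx.size:
                    eta[idx] += d_eta
                if not in_burnin:
                    acc_count[name] += 1
            adapter.record(name, accepted)

        # --- MH: joint recentering ------------------------------------
        if use_shift:
            step = adapter.step("shift")
            c = step * rng.standard_normal()
            mu_new = state.mu - c
            delta = (-(2.0 * c * float(np.sum(state.theta)) + T * c * c)
                     / (2.0 * theta_var)
                     + (state.mu ** 2 - mu_new ** 2) / (2.0 * mu_var))
            accepted = np.log(rng.random()) < delta
            if accepted:
                state.theta += c
                state.alpha -= c
                state.mu = mu_new
                if not in_burnin:
                    acc_count["shift"] += 1
            adapter.record("shift", accepted)

        # --- Gibbs: mu, tau2 -------------------------------------------
        if "mu" not in fixed:
            prec = S / state.tau2 + 1.0 / mu_var
            mean = np.sum(state.alpha) / state.tau2 / prec
            state.mu = mean + rng.standard_normal() / np.sqrt(prec)
        if "tau2" not in fixed:
            a_post = a_prior + 0.5 * S
            b_post = b_prior + 0.5 * float(
                np.sum((state.alpha - state.mu) ** 2))
            state.tau2 = b_post / rng.gamma(a_post)

        # --- Gibbs: sigma2 (shared-variance normal mode) ----------------
        if shared_sigma and "sigma2" not in fixed:
            resid2 = float(np.sum((design.y - eta) ** 2))
            a_post = a_prior + 0.5 * design.n_arms
            b_post = b_prior + 0.5 * resid2
            state.sigma2 = b_post / rng.gamma(a_post)
            obs_var[:] = state.sigma2

        if in_burnin:
            adapter.maybe_adapt(it)
            if it == settings.n_burnin - 1:
                adapter.freeze()
        else:
            j = it - settings.n_burnin
            if j % settings.thinning == 0:
                kept_idx = j // settings.thinning
                out["alpha"][chain_idx, kept_idx] = state.alpha
                out["theta"][chain_idx, kept_idx] = state.theta
                out["beta"][chain_idx, kept_idx] = state.beta
                out["mu"][chain_idx, kept_idx] = state.mu
                out["tau2"][chain_idx, kept_idx] = state.tau2
                if shared_sigma:
                    out["sigma2"][chain_idx, kept_idx] = state.sigma2
                kept += 1

    acceptance = {n: acc_count[n] / max(settings.n_draws, 1)
                  for n in mh_names}
    return {
        "acceptance": acceptance,
        "steps": {n: adapter.step(n) for n in mh_names},
        "trajectory": {n: np.array(v)
                       for n, v in adapter.trajectory.items()},
    }


# ----------------------------------------------------------------------
# Brute-force grid oracle
# ----------------------------------------------------------------------

class GridError(ValueError):
    """The supplied grid is too narrow for the posterior mass."""


@dataclass
class GridPosterior:
    """Normalised posterior over a small rectangular grid."""

    names: tuple[str, ...]
    axes: tuple[np.ndarray, ...]
    prob: np.ndarray  # normalised joint mass, shape = grid shape

    def marginal(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.names.index(name)
        other = tuple(j for j in range(self.prob.ndim) if j != i)
        return self.axes[i], self.prob.sum(axis=other)

    def mean(self, name: str) -> float:
        x, p = self.marginal(name)
        return float(np.sum(x * p))

    def sd(self, name: str) -> float:
        x, p = self.marginal(name)
        m = np.sum(x * p)
        return float(np.sqrt(np.sum((x - m) ** 2 * p)))

    def expectation(self, fn: Callable[..., float]) -> float:
        """E[fn(param values)] over the joint grid; fn takes the free
        parameters as keyword arguments."""
        grids = np.meshgrid(*self.axes, indexing="ij")
        vals = fn(**{n: g for n, g in zip(self.names, grids)})
        return float(np.sum(vals * self.prob))


def grid_posterior_oracle(
    dataset: TrialDataset | ModelDesign,
    spec: ModelSpec | None = None,
    grid: Mapping[str, np.ndarray] | None = None,
    fixed: Mapping[str, object] | None = None,
    boundary_tol: float = 0.01,
) -> GridPosterior:
    """Marginal posteriors by direct summation over a bounded grid.

    ``grid`` maps free-parameter names (``theta[<id>]``, ``alpha[<id>]``,
    ``beta[<name>]``, ``mu``, ``tau2``, ``sigma2``) to 1-D grids; at most 3
    free parameters. Everything else is held at the ``fixed`` values
    (default 0 / variance 1). Mass exceeding ``boundary_tol`` of the total
    on any outermost grid slice raises :class:`GridError`.
    """
    if isinstance(dataset, ModelDesign):
        design = dataset
    else:
        design = ModelDesign(dataset, spec or ModelSpec.for_endpoint(dataset.endpoint))
    if not grid:
        raise ValueError("a grid over 1-3 free parameters is required")
    if len(grid) > 3:
        raise ValueError("grid oracle supports at most 3 free parameters")
    fixed = dict(fixed or {})
    base = design.new_state(
        mu=float(fixed.get("mu", 0.0)),
        tau2=float(fixed.get("tau2", 1.0)),
    )
    if "sigma2" in fixed:
        base.sigma2 = float(fixed["sigma2"])
    if "alpha" in fixed:
        base.alpha = np.broadcast_to(
            np.asarray(fixed["alpha"], float), base.alpha.shape).copy()

    names = tuple(grid.keys())
    axes = tuple(np.asarray(grid[n], dtype=float) for n in names)
    setters = [_setter_for(design, n) for n in names]
    shape = tuple(len(ax) for ax in axes)
    logp = np.empty(shape)
    state = base.copy()
    for index in np.ndindex(shape):
        for setter, ax, i in zip(setters, axes, index):
            setter(state, float(ax[i]))
        logp[index] = design.log_posterior(state)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    for dim in range(prob.ndim):
        edge = np.take(prob, [0, -1], axis=dim).sum()
        if edge > boundary_tol:
            raise GridError(
                f"{edge:.3%} of posterior mass on the {names[dim]} grid "
                "boundary; widen the grid")
    return GridPosterior(names, axes, prob)


def _setter_for(design: ModelDesign, name: str):
    if name.startswith("theta[") and name.endswith("]"):
        t = design.treatment_ids.index(name[6:-1])
        def set_theta(state, v, t=t):
            state.theta[t] = v
        return set_theta
    if name.startswith("alpha[") and name.endswith("]"):
        s = design.study_ids.index(name[6:-1])
        def set_alpha(state, v, s=s):
            state.alpha[s] = v
        return set_alpha
    if name.startswith("beta[") and name.endswith("]"):
        k = design.covariate_names.index(name[5:-1])
        def set_beta(state, v, k=k):
            state.beta[k] = v
        return set_beta
    if name in ("mu", "tau2", "sigma2"):
        def set_scalar(state, v, n=name):
            setattr(state, n, v)
        return set_scalar
    raise ValueError(f"unknown grid parameter {name!r}")


# ----------------------------------------------------------------------
# Convergence diagnostics
# ----------------------------------------------------------------------

@dataclass
class DiagnosticReport:
    """Split-Rhat / ESS per monitored quantity plus acceptance flags."""

    rhat: dict[str, float]
    ess: dict[str, float]
    acceptance: dict[str, float]
    flags: list[str] = field(default_factory=list)

    @property
    def max_rhat(self) -> float:
        finite = [v for v in self.rhat.values() if np.isfinite(v)]
        return max(finite) if finite else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"quantity": q, "rhat": self.rhat.get(q, np.nan),
                 "ess": self.ess.get(q, np.nan)} for q in self.rhat]
        return pd.DataFrame(rows)


def diagnostics(chains: PosteriorChains,
                rhat_threshold: float = 1.1,
                acceptance_band: tuple[float, float] = (0.15, 0.6),
                ) -> DiagnosticReport:
    """Potential scale reduction (split-Rhat) and effective sample size for
    the monitored quantities (treatment effects, contrasts against the first
    treatment, mu, tau2), plus acceptance-rate flags."""
    monitored: dict[str, np.ndarray] = {}
    for i, t in enumerate(chains.treatment_ids):
        monitored[f"theta[{t}]"] = chains.theta[:, :, i]
    ref = chains.treatment_ids[0]
    for t in chains.treatment_ids[1:]:
        monitored[f"contrast[{t}-{ref}]"] = chains.contrast_draws(
            t, ref, per_chain=True)
    monitored["mu"] = chains.mu
    monitored["tau2"] = chains.tau2

    flags: list[str] = []
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    single = chains.n_chains < 2
    if single:
        flags.append("single chain: split-Rhat unavailable")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in monitored.items():
            if np.allclose(arr.var(), 0.0):
                flags.append(f"{name}: zero variance (constant chain)")
                rhat[name] = float("nan")
                ess[name] = float("nan")
                continue
            rhat[name] = (float("nan") if single
                          else float(az.rhat(az.convert_to_dataset(arr))["x"]))
            ess[name] = float(az.ess(az.convert_to_dataset(arr))["x"])
    for name, value in rhat.items():
        if np.isfinite(value) and value > rhat_threshold:
            flags.append(f"{name}: Rhat {value:.3f} exceeds {rhat_threshold}")
    for name, rate in chains.acceptance.items():
        if not acceptance_band[0] <= rate <= acceptance_band[1]:
            flags.append(
                f"{name}: acceptance {rate:.2f} outside "
                f"[{acceptance_band[0]}, {acceptance_band[1]}]")
    if flags:
        logger.warning("sampler diagnostics: %s", "; ".join(flags))
    return DiagnosticReport(rhat=rhat, ess=ess,
                            acceptance=dict(chains.acceptance), flags=flags)
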