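"""MAP estimation of flexible-model parameters from (error, update) pairs.

Participant (or simulated-agent) updates are modelled as Gaussian around
the flexible model's deterministic predicted update with a s.d. that is
linear in error magnitude, ``sd = UV + LRV * |delta|``.  The likelihood is
evaluated by running the flexible model conditioned on the subject's own
prediction-error sequence, and the total log posterior (likelihood plus
weak priors centred on normative parameter values) is maximized with a
bound-constrained quasi-Newton search from several jittered starts.

Four likelihood variants of increasing complexity are available:

``base``
    five free parameters: hazard, surprise sensitivity, log uncertainty
    underestimation, update variability, learning-rate variability;
``noise_scaled``
    adds a multiplicative scaling of perceived outcome noise;
``noise_scaled_offset``
    adds an additive offset as well (with two noise conditions this lets
    each block's perceived noise float freely);
``noise_mixture``
    replaces the single Gaussian update likelihood with a weighted mixture
    of zero-mean Gaussians whose s.d.s are scaled versions of the total
    predictive uncertainty; scales live on a uniform grid in [0.1, 100]
    with weights from an inverse-gamma density whose shape is fit (low
    shape = more dispersed beliefs about noise).

Model comparison penalizes for parameter count (BIC by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .flexible import FlexibleParams, make_state
from .normative import ModelConfig
from .regression import preprocess_trials

__all__ = [
    "SubjectData",
    "PriorSpec",
    "NoiseMixtureSpec",
    "FitResult",
    "trial_nll",
    "mixture_trial_nll",
    "negative_log_posterior",
    "fit_subject",
    "compare_noise_models",
    "MODEL_IDS",
]

MODEL_IDS = ("base", "noise_scaled", "noise_scaled_offset", "noise_mixture")
_LOG_2PI = math.log(2.0 * math.pi)
MIN_TRIALS = 50


@dataclass(frozen=True)
class SubjectData:
    """Preprocessed per-subject series used by the likelihood."""

    delta: np.ndarray
    update: np.ndarray
    noise_sd: np.ndarray
    is_catch: np.ndarray
    mu: np.ndarray
    bucket: np.ndarray
    block: np.ndarray
    included: np.ndarray

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    @classmethod
    def from_tables(cls, task: pd.DataFrame, behavior: pd.DataFrame) -> "SubjectData":
        trials = preprocess_trials(task, behavior)
        return cls(
            delta=trials["delta"].to_numpy(float),
            update=trials["update"].to_numpy(float),
            noise_sd=trials["noise_sd"].to_numpy(float),
            is_catch=trials["is_catch"].to_numpy(bool),
            mu=trials["helicopter"].to_numpy(float),
            bucket=trials["bucket"].to_numpy(float),
            block=trials["block"].to_numpy(),
            included=trials["included"].to_numpy(bool),
        )


@dataclass(frozen=True)
class PriorSpec:
    """Weak Gaussian priors favouring normative learning parameters."""

    log_uu_sd: float = 2.0
    logit_hazard_mean: float = float(special.logit(0.1))
    logit_hazard_sd: float = 2.0
    ss_mean: float = 1.0
    ss_sd: float = 0.5

    def neg_log_prior(self, params: FlexibleParams) -> float:
        lp = 0.5 * (params.log_uu / self.log_uu_sd) ** 2
        zh = (special.logit(params.hazard) - self.logit_hazard_mean) / self.logit_hazard_sd
        lp += 0.5 * zh * zh
        zs = (params.surprise_sensitivity - self.ss_mean) / self.ss_sd
        lp += 0.5 * zs * zs
        return float(lp)


@dataclass(frozen=True)
class NoiseMixtureSpec:
    """Grid of noise scales with inverse-gamma weights.

    Weights are the inverse-gamma density (shape ``nu``, scale ``nu + 1``
    so that the mode sits at scale 1: unbiased noise perception at the
    mode) evaluated at the grid points and renormalized.
    """

    grid_min: float = 0.1
    grid_max: float = 100.0
    grid_size: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.grid_min <= self.grid_max:
            raise ValueError("grid must be positive and ordered")
        if self.grid_size < 1:
            raise ValueError("grid_size must be >= 1")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.grid_size)

    def log_weights(self, shape_nu: float) -> np.ndarray:
        if shape_nu <= 0:
            raise ValueError("shape must be positive")
        logw = stats.invgamma.logpdf(self.grid, a=shape_nu, scale=shape_nu + 1.0)
        norm = special.logsumexp(logw)
        if not np.isfinite(norm):
            raise FloatingPointError("all mixture weights underflowed")
        return logw - norm


def trial_nll(u: float, u_hat: float, delta: float, uv: float, lrv: float) -> float:
    """Negative log Gaussian density of one update.

    Mean ``u_hat`` and s.d. ``UV + LRV * |delta|``.
    """
    sd = uv + lrv * abs(delta)
    if sd <= 0:
        raise ValueError("update s.d. UV + LRV*|delta| must be positive")
    z = (u - u_hat) / sd
    return 0.5 * (_LOG_2PI + z * z) + math.log(sd)


def mixture_trial_nll(u: float, u_hat: float, delta: float, uv: float,
                      lrv: float, total_sd: float, spec: NoiseMixtureSpec,
                      shape_nu: float) -> float:
    """Negative log density of one update under the noise-scale mixture.

    The residual ``u - u_hat`` is scored against
    ``sum_i p_i N(0, (s_i * total_sd)^2 + (UV + LRV|delta|)^2)`` --
    component s.d.s are the scaled total predictive uncertainty composed in
    quadrature with the response-variability s.d.
    """
    logw = spec.log_weights(shape_nu)
    s = spec.grid
    var = (s * total_sd) ** 2 + (uv + lrv * abs(delta)) ** 2
    r = u - u_hat
    logpdf = -0.5 * (_LOG_2PI + np.log(var) + r * r / var)
    return float(-special.logsumexp(logw + logpdf))


def _conditioned_predictions(data: SubjectData, params: FlexibleParams,
                             cfg: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Predicted updates and total predictive variance per trial.

    Lean re-implementation of the conditioned model run (no data-frame
    overhead) used inside the optimizer's objective.
    """
    state = make_state(params, cfg)
    n = len(data.delta)
    u_hat = np.empty(n)
    total_var = np.empty(n)
    delta = data.delta
    noise = data.noise_sd
    catch = data.is_catch
    mu = data.mu
    bucket = data.bucket
    block = data.block
    prev = None
    for t in range(n):
        if block[t] != prev:
            state.reset()
            prev = block[t]
        d = delta[t]
        omega, tau_in, alpha, sig2_in, w = state.step(d, noise[t],
                                                      bool(catch[t]), mu[t])
        uh = alpha * d
        if not math.isnan(w):
            uh = w * (bucket[t] + uh) + (1.0 - w) * mu[t] - bucket[t]
        u_hat[t] = uh
        sn = state.perceived_sd(noise[t])
        total_var[t] = sig2_in + sn * sn
    return u_hat, total_var


def negative_log_posterior(data: SubjectData, params: FlexibleParams,
                           model_id: str = "base",
                           cfg: ModelConfig | None = None,
                           priors: PriorSpec | None = None,
                           mixture: NoiseMixtureSpec | None = None,
                           likelihood_only: bool = False) -> float:
    """Total NLL of included updates plus weak-prior penalties (nats)."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    cfg = cfg or ModelConfig()
    priors = priors or PriorSpec()
    inc = data.included
    if inc.sum() == 0:
        nll = 0.0
    else:
        u_hat, total_var = _conditioned_predictions(data, params, cfg)
        r = (data.update - u_hat)[inc]
        sd_resp = (params.update_variability
                   + params.learning_rate_variability * np.abs(data.delta[inc]))
        if np.any(sd_resp <= 0):
            raise ValueError("update s.d. must be positive on every trial")
        if model_id == "noise_mixture":
            mixture = mixture or NoiseMixtureSpec()
            logw = mixture.log_weights(params.noise_shape)
            tsd = np.sqrt(total_var[inc])
            var = (mixture.grid[None, :] * tsd[:, None]) ** 2 + sd_resp[:, None] ** 2
            logpdf = -0.5 * (_LOG_2PI + np.log(var) + (r[:, None] ** 2) / var)
            nll = float(-special.logsumexp(logw[None, :] + logpdf, axis=1).sum())
        else:
            z = r / sd_resp
            nll = float(0.5 * np.sum(_LOG_2PI + z * z) + np.sum(np.log(sd_resp)))
        if not np.isfinite(nll):
            bad = int(np.flatnonzero(~np.isfinite(r))[0]) if np.any(~np.isfinite(r)) else -1
            raise FloatingPointError(f"non-finite likelihood (first bad trial {bad})")
    if likelihood_only:
        return nll
    return nll + priors.neg_log_prior(params)


# packed-parameter layout per model_id: (name, lower, upper, default start)
_PACKED = {
    "logit_hazard": (float(special.logit(1e-4)), float(special.logit(0.5)),
                     float(special.logit(0.1))),
    "ss": (0.01, 1.0, 0.9),
    "log_uu": (0.0, 8.0, 0.0),
    "log_uv": (math.log(0.1), math.log(60.0), math.log(5.0)),
    "lrv": (0.0, 2.0, 0.05),
    "log_noise_scale": (math.log(0.2), math.log(5.0), 0.0),
    "noise_offset": (-20.0, 50.0, 0.0),
    "log_noise_shape": (math.log(0.5), math.log(100.0), math.log(10.0)),
}

_FIELDS_BY_MODEL = {
    "base": ["logit_hazard", "ss", "log_uu", "log_uv", "lrv"],
    "noise_scaled": ["logit_hazard", "ss", "log_uu", "log_uv", "lrv",
                     "log_noise_scale"],
    "noise_scaled_offset": ["logit_hazard", "ss", "log_uu", "log_uv", "lrv",
                            "log_noise_scale", "noise_offset"],
    "noise_mixture": ["logit_hazard", "ss", "log_uu", "log_uv", "lrv",
                      "log_noise_scale", "noise_offset", "log_noise_shape"],
}


def _unpack(x: np.ndarray, fields: list[str], cue_sd: float) -> FlexibleParams:
    kv = dict(zip(fields, x))
    return FlexibleParams(
        hazard=float(special.expit(kv["logit_hazard"])),
        surprise_sensitivity=float(kv["ss"]),
        log_uu=float(kv["log_uu"]),
        cue_sd=cue_sd,
        noise_scale=float(math.exp(kv.get("log_noise_scale", 0.0))),
        noise_offset=float(kv.get("noise_offset", 0.0)),
        noise_shape=float(math.exp(kv.get("log_noise_shape", math.log(10.0)))),
        update_variability=float(math.exp(kv["log_uv"])),
        learning_rate_variability=float(kv["lrv"]),
    )


@dataclass
class FitResult:
    """Record of one subject-level MAP fit."""

    params: FlexibleParams
    log_posterior: float
    log_likelihood: float
    n_trials: int
    converged: bool
    n_restarts: int
    model_id: str
    penalty_score: float
    n_params: int

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        d["params"] = asdict(self.params)
        return d


def fit_subject(data: SubjectData, model_id: str = "base",
                n_restarts: int = 10, seed: int = 0,
                cfg: ModelConfig | None = None,
                priors: PriorSpec | None = None,
                mixture: NoiseMixtureSpec | None = None,
                penalty: str = "bic",
                min_trials: int = MIN_TRIALS) -> FitResult:
    """MAP fit of the flexible model to one subject.

    Runs a bound-constrained L-BFGS-B search from a normative-valued start
    plus ``n_restarts - 1`` seeded jittered starts and keeps the best local
    optimum.  Uncertainty underestimation is parameterized (and reported)
    in log units.  ``penalty`` is ``'bic'`` (default) or ``'aic'``.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    if data.n_included < min_trials:
        raise ValueError(
            f"only {data.n_included} included trials; floor is {min_trials}")
    cfg = cfg or ModelConfig()
    priors = priors or PriorSpec()
    fields = _FIELDS_BY_MODEL[model_id]
    lo = np.array([_PACKED[f][0] for f in fields])
    hi = np.array([_PACKED[f][1] for f in fields])
    x0 = np.array([_PACKED[f][2] for f in fields])
    rng = np.random.default_rng(seed)

    def objective(x: np.ndarray) -> float:
        try:
            p = _unpack(x, fields, cfg.cue_sd)
            return negative_log_posterior(data, p, model_id, cfg, priors, mixture)
        except FloatingPointError:
            return 1e12

    starts = [x0]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(lo + rng.random(len(fields)) * (hi - lo))
    best = None
    any_ok = False
    for s in starts:
        res = optimize.minimize(objective, s, method="L-BFGS-B",
                                bounds=list(zip(lo, hi)),
                                options={"maxiter": 300})
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = _unpack(best.x, fields, cfg.cue_sd)
    nll_like = negative_log_posterior(data, params, model_id, cfg, priors,
                                      mixture, likelihood_only=True)
    n = data.n_included
    k = len(fields)
    score = 2.0 * nll_like + (k * math.log(n) if penalty == "bic" else 2.0 * k)
    return FitResult(params=params, log_posterior=-float(best.fun),
                     log_likelihood=-float(nll_like), n_trials=n,
                     converged=any_ok, n_restarts=len(starts),
                     model_id=model_id, penalty_score=float(score), n_params=k)


def compare_noise_models(data: SubjectData, model_ids: Sequence[str] = MODEL_IDS,
                         seed: int = 0, **fit_kwargs) -> list[FitResult]:
    """Fit several likelihood variants and rank them by penalized score.

    Ties in penalty score break deterministically toward the model with
    the fewest parameters.
    """
    if len(model_ids) < 2:
        raise ValueError("need at least two models to compare")
    fits = [fit_subject(data, mid, seed=seed + i, **fit_kwargs)
            for i, mid in enumerate(model_ids)]
    return sorted(fits, key=lambda f: (f.penalty_score, f.n_params))
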