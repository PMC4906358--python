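"""Reduced-Bayesian learning model for change-point (helicopter) tasks.

The agent predicts the location of a hidden mean (the helicopter) that
relocates abruptly with a small per-trial hazard while observations (bags)
scatter around it with known Gaussian noise.  Instead of tracking the full
run-length posterior, the model summarises its belief state with two
quantities that jointly set a trial-by-trial learning rate:

* change-point probability ``omega`` -- the posterior probability that the
  latest outcome followed a relocation, obtained from the likelihood ratio
  of a uniform (post-change) versus Gaussian (no-change) outcome density;
* relative uncertainty ``tau`` -- uncertainty about the mean expressed as a
  fraction of total predictive uncertainty about the next outcome.

The belief update is a delta rule, ``B' = B + alpha * delta`` with
``alpha = omega + (1 - omega) * tau``, so learning is fast after likely
change points or while the estimate is uncertain and slow during stable,
well-learned periods.

On catch trials the helicopter itself is visible and is treated as an
additional Gaussian cue centred on the true mean; belief and uncertainty are
combined with the cue by precision weighting at the end of the trial.

The recursion can be run *generatively* (the model experiences its own
prediction errors) or *conditioned* on an observed prediction-error
sequence, which yields subjective surprise/uncertainty estimates for a
subject whose predictions differ from the model's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ModelConfig",
    "change_point_probability",
    "propagate_uncertainty",
    "normative_update",
    "catch_trial_combine",
    "run_model",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
#: columns of a serialized latent trajectory
TRAJECTORY_COLUMNS = [
    "belief", "delta", "omega", "tau", "sigma2_mu", "alpha", "w", "pred_update",
]


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of the normative observer.

    hazard
        Prior per-trial probability of a helicopter relocation (ground truth
        0.1 in the task).
    noise_sd
        Outcome (bag) standard deviation in screen units; per-trial values
        from a task table override this scalar default.
    outcome_range
        Width of the screen interval on which outcomes live; the post-change
        outcome density is uniform, ``U = 1 / outcome_range``.
    cue_sd
        Standard deviation of the Gaussian likelihood attached to the
        visible helicopter on catch trials.
    initial_tau
        Relative uncertainty entering the first trial of a block.  The first
        outcome of a block always resets the belief (flat-prior limit), so
        this only labels the recorded trajectory.
    """

    hazard: float = 0.1
    noise_sd: float = 10.0
    outcome_range: float = 300.0
    cue_sd: float = 10.0
    initial_tau: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError(f"hazard must lie in [0, 1], got {self.hazard}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.outcome_range <= 0:
            raise ValueError("outcome_range must be positive")
        if self.cue_sd <= 0:
            raise ValueError("cue_sd must be positive")
        if not 0.0 <= self.initial_tau < 1.0:
            raise ValueError("initial_tau must lie in [0, 1)")


def _cpp_scalar(delta: float, tau: float, sig_n2: float, hazard: float,
                surprise_sensitivity: float, u_density: float) -> float:
    """Change-point probability for one prediction error (fast scalar path)."""
    if hazard <= 0.0:
        return 0.0
    if hazard >= 1.0:
        return 1.0
    total_var = sig_n2 / (1.0 - tau)
    expo = -0.5 * delta * delta / total_var
    gauss = math.exp(expo) / (_SQRT_2PI * math.sqrt(total_var)) if expo > -700.0 else 0.0
    if surprise_sensitivity != 1.0:
        # blunted surprise: the outcome likelihood entering change-point
        # detection is raised to a power in (0, 1], flattening it and
        # shifting the surprise threshold toward larger errors
        gauss = gauss ** surprise_sensitivity
    denom = gauss * (1.0 - hazard)
    if denom <= 0.0:
        return 1.0
    odds = (u_density * hazard) / denom
    return odds / (1.0 + odds)


def change_point_probability(delta, tau, cfg: ModelConfig,
                             surprise_sensitivity: float = 1.0):
    """Posterior probability that ``delta`` followed a change point.

    ``Omega = U*H / (U*H + N(delta; 0, sigma_N^2 / (1 - tau)) * (1 - H))``
    where ``U = 1 / outcome_range`` is the uniform post-change outcome
    density.  ``surprise_sensitivity`` < 1 raises the posterior odds to that
    power, flattening the mapping from error magnitude to surprise.

    Accepts scalars or arrays (broadcast); returns the same shape.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr >= 1.0) or np.any(tau_arr < 0.0):
        raise ValueError("tau must lie in [0, 1)")
    if not 0.0 < surprise_sensitivity <= 1.0:
        raise ValueError("surprise_sensitivity must lie in (0, 1]")
    sig_n2 = cfg.noise_sd ** 2
    u_density = 1.0 / cfg.outcome_range
    out = np.vectorize(
        lambda d, t: _cpp_scalar(float(d), float(t), sig_n2, cfg.hazard,
                                 surprise_sensitivity, u_density)
    )(delta, tau_arr)
    if np.isscalar(delta) and np.isscalar(tau):
        return float(out)
    return out


def propagate_uncertainty(omega: float, tau: float, delta: float,
                          cfg: ModelConfig) -> tuple[float, float]:
    """Propagate belief variance one trial forward.

    The posterior over the mean is a mixture of the change (variance
    ``sigma_N^2``) and no-change (variance ``tau * sigma_N^2``) branches,
    separated by the unlearned part of the error, giving

    ``sigma2_mu' = omega*s2 + (1-omega)*tau*s2 + omega*(1-omega)*(delta*(1-tau))^2``

    and ``tau' = sigma2_mu' / (sigma2_mu' + sigma_N^2)``.
    """
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must lie in [0, 1]")
    if not 0.0 <= tau < 1.0:
        raise ValueError("tau must lie in [0, 1)")
    s2 = cfg.noise_sd ** 2
    sig2_mu = (omega * s2 + (1.0 - omega) * tau * s2
               + omega * (1.0 - omega) * (delta * (1.0 - tau)) ** 2)
    return sig2_mu, sig2_mu / (sig2_mu + s2)


def normative_update(belief: float, delta: float, omega: float,
                     tau: float) -> tuple[float, float]:
    """Delta-rule belief update with the normative learning rate.

    ``alpha = omega + (1 - omega) * tau``; returns ``(belief', alpha)``.
    """
    alpha = omega + (1.0 - omega) * tau
    return belief + alpha * delta, alpha


def catch_trial_combine(belief: float, sigma2_mu: float, mu: float,
                        cfg: ModelConfig) -> tuple[float, float, float, float]:
    """Fold the visible-helicopter cue into belief and uncertainty.

    The cue is a Gaussian likelihood centred on the true mean ``mu`` with
    s.d. ``cfg.cue_sd``; precision weighting gives the posterior belief,
    variance and relative uncertainty.  Returns
    ``(belief_post, sigma2_post, tau_post, w)`` where ``w`` is the weight
    retained by the current belief.
    """
    sig_h2 = cfg.cue_sd ** 2
    if sigma2_mu < 0:
        raise ValueError("sigma2_mu must be non-negative")
    if sigma2_mu == 0.0 and sig_h2 == 0.0:
        raise ValueError("degenerate combination: both variances are zero")
    w = sig_h2 / (sig_h2 + sigma2_mu)
    belief_post = w * belief + (1.0 - w) * mu
    sigma2_post = 0.0 if sigma2_mu == 0.0 else 1.0 / (1.0 / sigma2_mu + 1.0 / sig_h2)
    tau_post = sigma2_post / (sigma2_post + cfg.noise_sd ** 2)
    return belief_post, sigma2_post, tau_post, w


class CoreState:
    """Mutable recursion state shared by all model runners.

    Deviation parameters default to neutral values, at which the state
    implements the normative observer exactly.  ``step`` advances one trial
    and returns the quantities recorded in a latent trajectory.
    """

    __slots__ = ("hazard", "ss", "uu", "sig_h2", "s_mult", "s_add",
                 "u_density", "init_tau", "tau", "sig2_mu", "fresh")

    def __init__(self, hazard: float, outcome_range: float, cue_sd: float,
                 initial_tau: float = 0.5, surprise_sensitivity: float = 1.0,
                 uncertainty_divisor: float = 1.0, noise_scale: float = 1.0,
                 noise_offset: float = 0.0) -> None:
        self.hazard = hazard
        self.ss = surprise_sensitivity
        self.uu = uncertainty_divisor
        self.sig_h2 = cue_sd * cue_sd
        self.s_mult = noise_scale
        self.s_add = noise_offset
        self.u_density = 1.0 / outcome_range
        self.init_tau = initial_tau
        self.reset()

    def reset(self) -> None:
        """Start a new block: flat prior, next outcome resets the belief."""
        self.fresh = True
        self.tau = self.init_tau
        self.sig2_mu = -1.0  # sentinel: derived from first trial's noise

    def perceived_sd(self, noise_sd: float) -> float:
        sd = self.s_mult * noise_sd + self.s_add
        return sd if sd > 1e-6 else 1e-6

    def step(self, delta: float, noise_sd: float, is_catch: bool,
             mu: float) -> tuple[float, float, float, float, float]:
        """Advance one trial; returns (omega, tau_in, alpha, sigma2_mu_in, w).

        ``tau_in``/``sigma2_mu_in`` are the values that governed this
        trial's inference; ``w`` is NaN on non-catch trials.  The caller is
        responsible for applying ``alpha`` (and, on catch trials, the cue
        pull with weight ``w``) to whatever belief it maintains.
        """
        sn = self.perceived_sd(noise_sd)
        sn2 = sn * sn
        tau_in = self.tau
        sig2_in = self.sig2_mu if self.sig2_mu >= 0.0 else sn2 * tau_in / (1.0 - tau_in)
        if self.fresh:
            # first outcome of a block: a change point by construction
            omega = 1.0
            self.fresh = False
        else:
            omega = _cpp_scalar(delta, tau_in, sn2, self.hazard, self.ss,
                                self.u_density)
        alpha = omega + (1.0 - omega) * tau_in
        s2 = (omega * sn2 + (1.0 - omega) * tau_in * sn2
              + omega * (1.0 - omega) * (delta * (1.0 - tau_in)) ** 2)
        s2 /= self.uu
        w = math.nan
        if is_catch:
            w = self.sig_h2 / (self.sig_h2 + s2)
            if s2 > 0.0:
                s2 = 1.0 / (1.0 / s2 + 1.0 / self.sig_h2)
        self.sig2_mu = s2
        self.tau = s2 / (s2 + sn2)
        return omega, tau_in, alpha, sig2_in, w


def _as_task_arrays(task: pd.DataFrame):
    bag = task["bag"].to_numpy(dtype=float)
    mu = task["helicopter"].to_numpy(dtype=float)
    noise = task["noise_sd"].to_numpy(dtype=float)
    catch = task["is_catch"].to_numpy(dtype=bool)
    block = task["block"].to_numpy()
    return bag, mu, noise, catch, block


def run_core(task: pd.DataFrame, state: CoreState, mode: str = "generative",
             observed_pe=None, observed_bucket=None,
             screen_center: float = 150.0) -> pd.DataFrame:
    """Run the recursion over a (possibly multi-block) task table.

    ``mode='generative'``: prediction errors come from the model's own
    belief path.  ``mode='conditioned'``: surprise and uncertainty are
    evaluated on ``observed_pe``; if ``observed_bucket`` is given it anchors
    the predicted update on catch trials (the cue pulls the *subject's*
    bucket, not the internal belief path).

    Returns a data frame with columns ``belief, delta, omega, tau,
    sigma2_mu, alpha, w, pred_update``; ``belief`` is the prediction
    entering each trial.
    """
    if mode not in ("generative", "conditioned"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "conditioned" and observed_pe is None:
        raise ValueError("conditioned mode requires an observed prediction-error series")
    bag, mu, noise, catch, block = _as_task_arrays(task)
    n = len(bag)
    if observed_pe is not None:
        observed_pe = np.asarray(observed_pe, dtype=float)
        if len(observed_pe) != n:
            raise ValueError("observed_pe is not aligned with the task table")
    if observed_bucket is not None:
        observed_bucket = np.asarray(observed_bucket, dtype=float)
        if len(observed_bucket) != n:
            raise ValueError("observed_bucket is not aligned with the task table")

    out = np.empty((n, 8), dtype=float)
    belief = screen_center
    prev_block = None
    for t in range(n):
        if block[t] != prev_block:
            state.reset()
            belief = screen_center
            prev_block = block[t]
        base = belief
        if mode == "conditioned":
            delta = observed_pe[t]
            if observed_bucket is not None:
                base = observed_bucket[t]
        else:
            delta = bag[t] - belief
        omega, tau_in, alpha, sig2_in, w = state.step(delta, noise[t],
                                                      bool(catch[t]), mu[t])
        target = base + alpha * delta
        if not math.isnan(w):
            target = w * target + (1.0 - w) * mu[t]
        pred_update = target - base
        # internal belief path follows the same rule around its own belief
        b_next = belief + alpha * delta
        if not math.isnan(w):
            b_next = w * b_next + (1.0 - w) * mu[t]
        out[t] = (belief, delta, omega, tau_in, sig2_in, alpha, w, pred_update)
        belief = b_next
    traj = pd.DataFrame(out, columns=TRAJECTORY_COLUMNS, index=task.index)
    if mode == "conditioned" and observed_bucket is not None:
        traj["belief"] = observed_bucket
    return traj


def run_model(task: pd.DataFrame, cfg: ModelConfig, mode: str = "generative",
              observed_pe=None, observed_bucket=None) -> pd.DataFrame:
    """Run the normative model over a task table (see :func:`run_core`)."""
    state = CoreState(cfg.hazard, cfg.outcome_range, cfg.cue_sd, cfg.initial_tau)
    center = 0.5 * cfg.outcome_range
    return run_core(task, state, mode=mode, observed_pe=observed_pe,
                    observed_bucket=observed_bucket, screen_center=center)
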