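"""Parameterized deviations from the normative change-point learner.

A single flexible model nests the normative observer and three principled
ways of getting it wrong:

* **surprise insensitivity** (``surprise_sensitivity`` < 1): the posterior
  odds of a change point are raised to a power in (0, 1], compressing the
  log-odds and flattening the mapping from error magnitude to surprise, so
  large errors drive less learning;
* **hazard mis-estimation** (``hazard`` != true hazard): a low assumed
  hazard raises the surprise threshold for inferring a change point,
  cutting learning after moderately surprising outcomes;
* **uncertainty underestimation** (``log_uu`` > 0): the variance of the
  predictive distribution over the mean is divided by ``exp(log_uu)`` every
  trial, so relative uncertainty collapses and learning from small,
  unsurprising errors disappears.

Perceived outcome noise may also be scaled and offset relative to ground
truth (``noise_scale``, ``noise_offset``), and response variability is
described by an update-noise intercept (``update_variability``, screen
units) and slope in error magnitude (``learning_rate_variability``).

At neutral values the flexible model reproduces the normative trajectory
bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .normative import CoreState, ModelConfig, run_core

__all__ = [
    "FlexibleParams",
    "apply_surprise_sensitivity",
    "apply_uncertainty_underestimation",
    "run_flexible",
    "params_for_kind",
    "MODEL_KINDS",
]

#: canonical agent presets (simulation values for the deviant observers)
MODEL_KINDS = (
    "normative",
    "surprise_insensitive",
    "low_hazard",
    "uncertainty_underestimation",
    "fixed_learning_rate",
)


@dataclass(frozen=True)
class FlexibleParams:
    """Parameter vector of the flexible model.

    ``log_uu`` is the natural log of the uncertainty-underestimation
    divisor (0 = normative; fits are reported on this scale because the
    divisor is positively skewed).  ``noise_shape`` is the inverse-gamma
    shape of the noise-dispersion mixture and only matters for the
    ``noise_mixture`` likelihood.
    """

    hazard: float = 0.1
    surprise_sensitivity: float = 1.0
    log_uu: float = 0.0
    cue_sd: float = 10.0
    noise_scale: float = 1.0
    noise_offset: float = 0.0
    noise_shape: float = 10.0
    update_variability: float = 0.0
    learning_rate_variability: float = 0.0

    @property
    def uu(self) -> float:
        """Uncertainty-underestimation divisor on the natural scale."""
        return math.exp(self.log_uu)

    def __post_init__(self) -> None:
        if not 0.0 < self.hazard < 1.0:
            raise ValueError("hazard must lie in (0, 1)")
        if not 0.0 < self.surprise_sensitivity <= 1.0:
            raise ValueError("surprise_sensitivity must lie in (0, 1]")
        if self.log_uu < 0.0:
            raise ValueError("log_uu must be >= 0 (divisor >= 1)")
        if self.cue_sd <= 0:
            raise ValueError("cue_sd must be positive")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if self.noise_shape <= 0:
            raise ValueError("noise_shape must be positive")
        if self.update_variability < 0 or self.learning_rate_variability < 0:
            raise ValueError("response-variability terms must be non-negative")

    def to_json(self) -> str:
        payload = asdict(self)
        payload["encoding"] = {"log_uu": "log", "others": "linear"}
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FlexibleParams":
        payload = json.loads(text)
        payload.pop("encoding", None)
        return cls(**payload)


def apply_surprise_sensitivity(omega, ss: float, hazard: float = 0.1,
                               outcome_range: float = 300.0):
    """Blunt change-point probability by flattening the outcome likelihood.

    Recovers the Gaussian (no-change) likelihood implied by ``omega``,
    raises it to the power ``ss`` and renormalizes:

    ``omega' = U*H / (U*H + N**ss * (1 - H))``.

    ``ss = 1`` is the identity; 0 and 1 are fixed points for any ``ss``
    and the transform is monotone in ``omega``.
    """
    if not 0.0 < ss <= 1.0:
        raise ValueError("surprise_sensitivity must lie in (0, 1]")
    om = np.asarray(omega, dtype=float)
    if np.any(om < 0) or np.any(om > 1):
        raise ValueError("omega must lie in [0, 1]")
    uh = hazard / outcome_range
    with np.errstate(divide="ignore", invalid="ignore"):
        # N*(1-H) implied by the likelihood-ratio form of omega
        gauss = np.where((om > 0) & (om < 1),
                         uh * (1.0 - om) / (np.maximum(om, 1e-300) * (1.0 - hazard)),
                         np.nan)
        odds = uh / (gauss ** ss * (1.0 - hazard))
        out = odds / (1.0 + odds)
    out = np.where(om <= 0.0, 0.0, np.where(om >= 1.0, 1.0, out))
    return float(out) if np.isscalar(omega) else out


def apply_uncertainty_underestimation(sigma2_mu, uu: float):
    """Divide the belief variance by the underestimation constant ``uu``.

    Applied once per trial after variance propagation, before relative
    uncertainty (and hence before the next trial's surprise) is computed.
    """
    if uu < 1.0:
        raise ValueError("uncertainty-underestimation divisor must be >= 1")
    s2 = np.asarray(sigma2_mu, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("sigma2_mu must be non-negative")
    out = s2 / uu
    return float(out) if np.isscalar(sigma2_mu) else out


def make_state(params: FlexibleParams, cfg: ModelConfig) -> CoreState:
    """Recursion state for the flexible model (hazard/SS/UU/noise from params)."""
    return CoreState(
        hazard=params.hazard,
        outcome_range=cfg.outcome_range,
        cue_sd=params.cue_sd,
        initial_tau=cfg.initial_tau,
        surprise_sensitivity=params.surprise_sensitivity,
        uncertainty_divisor=params.uu,
        noise_scale=params.noise_scale,
        noise_offset=params.noise_offset,
    )


def run_flexible(task: pd.DataFrame, params: FlexibleParams, cfg: ModelConfig,
                 mode: str = "generative", observed_pe=None,
                 observed_bucket=None) -> pd.DataFrame:
    """Run the flexible model over a task table.

    Identical contract to :func:`helilearn.normative.run_model`; hazard,
    surprise sensitivity, uncertainty underestimation, perceived noise and
    the cue s.d. are taken from ``params``.
    """
    state = make_state(params, cfg)
    return run_core(task, state, mode=mode, observed_pe=observed_pe,
                    observed_bucket=observed_bucket,
                    screen_center=0.5 * cfg.outcome_range)


def params_for_kind(kind: str, cue_sd: float = 10.0,
                    update_variability: float = 0.0,
                    learning_rate_variability: float = 0.0) -> FlexibleParams:
    """Simulation presets for the named observer variants."""
    base = FlexibleParams(cue_sd=cue_sd, update_variability=update_variability,
                          learning_rate_variability=learning_rate_variability)
    if kind in ("normative", "fixed_learning_rate"):
        return base
    if kind == "surprise_insensitive":
        return replace(base, surprise_sensitivity=0.2)
    if kind == "low_hazard":
        return replace(base, hazard=0.001)
    if kind == "uncertainty_underestimation":
        return replace(base, log_uu=math.log(10.0))
    raise ValueError(f"unknown model kind {kind!r}")
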