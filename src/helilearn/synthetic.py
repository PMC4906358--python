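"""Synthetic helicopter-task sessions, simulated agents and cohorts.

The generator reproduces the statistics of the predictive-inference task:
a hidden helicopter on a 0-300 screen relocates with per-trial hazard 0.1,
drops a bag whose position is Gaussian around the helicopter with a
blockwise s.d. of 10 or 25 (two 200-trial blocks), the helicopter is
visible on 10% of trials (catch trials) and bag contents are gold or rocks
with equal probability.  Bag draws falling off screen are redrawn until in
range.

Agents place a bucket on every trial.  Their deterministic update comes
from a (possibly deviant) flexible model conditioned on their own realized
prediction errors; the realized update adds Gaussian response noise with
s.d. ``UV + LRV * |delta|`` (update variability plus learning-rate
variability).

Cohorts pair each simulated subject with covariates (age group, age,
fluid-intelligence and working-memory scores) so that the downstream
group analyses can run without human data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .flexible import MODEL_KINDS, FlexibleParams, make_state, params_for_kind
from .normative import ModelConfig

__all__ = [
    "TaskConfig",
    "AgentSpec",
    "CohortSpec",
    "Subject",
    "generate_task_block",
    "generate_session",
    "simulate_agent",
    "score_coins",
    "generate_cohort",
]

TASK_COLUMNS = ["trial", "block", "helicopter", "bag", "noise_sd",
                "is_changepoint", "is_catch", "is_gold"]
BEHAVIOR_COLUMNS = ["trial", "block", "bucket"]
SCHEMA_VERSION = "helilearn-task-v1"


@dataclass(frozen=True)
class TaskConfig:
    """Ground-truth statistics of a simulated session."""

    n_trials_per_block: int = 200
    noise_sds: tuple[float, ...] = (10.0, 25.0)
    hazard: float = 0.1
    catch_rate: float = 0.1
    screen_min: float = 0.0
    screen_max: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_block < 1:
            raise ValueError("n_trials_per_block must be >= 1")
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError("hazard must lie in [0, 1]")
        if not 0.0 <= self.catch_rate <= 1.0:
            raise ValueError("catch_rate must lie in [0, 1]")
        if self.screen_min >= self.screen_max:
            raise ValueError("screen_min must be below screen_max")
        if any(sd <= 0 for sd in self.noise_sds):
            raise ValueError("noise_sds must be strictly positive")

    @property
    def screen_center(self) -> float:
        return 0.5 * (self.screen_min + self.screen_max)

    @property
    def outcome_range(self) -> float:
        return self.screen_max - self.screen_min

    def model_config(self, noise_sd: float | None = None,
                     cue_sd: float = 10.0) -> ModelConfig:
        """Normative observer matched to this task's ground truth."""
        return ModelConfig(hazard=self.hazard,
                           noise_sd=noise_sd or self.noise_sds[0],
                           outcome_range=self.outcome_range, cue_sd=cue_sd)


@dataclass(frozen=True)
class AgentSpec:
    """A simulated subject: latent model plus response variability."""

    model_kind: str = "normative"
    params: FlexibleParams = field(default_factory=FlexibleParams)
    update_variability: float = 0.0
    learning_rate_variability: float = 0.0
    fixed_learning_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.update_variability < 0 or self.learning_rate_variability < 0:
            raise ValueError("UV and LRV must be non-negative")

    @classmethod
    def of_kind(cls, kind: str, uv: float = 0.0, lrv: float = 0.0,
                seed: int = 0, **extra) -> "AgentSpec":
        return cls(model_kind=kind, params=params_for_kind(kind),
                   update_variability=uv, learning_rate_variability=lrv,
                   seed=seed, **extra)


def _draw_bag(rng: np.random.Generator, mean: float, sd: float,
              lo: float, hi: float) -> float:
    """Gaussian draw redrawn until it lands on the screen."""
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise RuntimeError("bag redraw failed; noise s.d. incompatible with screen")


def generate_task_block(cfg: TaskConfig, noise_sd: float | None = None,
                        block: int = 0,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate one block of ground-truth task state.

    The helicopter starts uniform on the screen and relocates to a fresh
    uniform position with probability ``cfg.hazard`` on every trial
    (independently of catch status); bags are Gaussian around it with
    ``noise_sd`` (default: first entry of ``cfg.noise_sds``).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sd = float(noise_sd if noise_sd is not None else cfg.noise_sds[0])
    if sd <= 0:
        raise ValueError("noise_sd must be strictly positive")
    n = cfg.n_trials_per_block
    lo, hi = cfg.screen_min, cfg.screen_max
    cps = rng.random(n) < cfg.hazard
    catch = rng.random(n) < cfg.catch_rate
    gold = rng.random(n) < 0.5
    heli = np.empty(n)
    bag = np.empty(n)
    pos = rng.uniform(lo, hi)
    for t in range(n):
        if t > 0 and cps[t]:
            pos = rng.uniform(lo, hi)
        heli[t] = pos
        bag[t] = _draw_bag(rng, pos, sd, lo, hi)
    return pd.DataFrame({
        "trial": np.arange(n), "block": block, "helicopter": heli, "bag": bag,
        "noise_sd": sd, "is_changepoint": cps, "is_catch": catch,
        "is_gold": gold,
    })


def generate_session(cfg: TaskConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One session: one block per entry of ``cfg.noise_sds``, concatenated."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    blocks = [generate_task_block(cfg, sd, block=b, rng=rng)
              for b, sd in enumerate(cfg.noise_sds)]
    return pd.concat(blocks, ignore_index=True)


def simulate_agent(task: pd.DataFrame, agent: AgentSpec,
                   cfg: TaskConfig | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate an agent's bucket placements over a session.

    The agent's model is conditioned on its own *realized* prediction
    errors: each trial the deterministic update is computed from the
    current model state, response noise with s.d. ``UV + LRV*|delta|`` is
    added, and the bucket is clamped to the screen.  The first bucket of
    each block sits at the screen centre.
    """
    cfg = cfg or TaskConfig()
    if rng is None:
        rng = np.random.default_rng(agent.seed)
    model_cfg = cfg.model_config()
    state = make_state(agent.params, model_cfg)
    fixed_lr = agent.model_kind == "fixed_learning_rate"
    lo, hi = cfg.screen_min, cfg.screen_max
    uv, lrv = agent.update_variability, agent.learning_rate_variability

    bag = task["bag"].to_numpy(dtype=float)
    mu = task["helicopter"].to_numpy(dtype=float)
    noise = task["noise_sd"].to_numpy(dtype=float)
    catch = task["is_catch"].to_numpy(dtype=bool)
    block = task["block"].to_numpy()

    n = len(bag)
    bucket = np.empty(n)
    prev_block = None
    pos = cfg.screen_center
    for t in range(n):
        if block[t] != prev_block:
            state.reset()
            pos = cfg.screen_center
            prev_block = block[t]
        bucket[t] = pos
        delta = bag[t] - pos
        omega, tau_in, alpha, _, w = state.step(delta, noise[t],
                                                bool(catch[t]), mu[t])
        if fixed_lr:
            # pure delta rule: constant rate, helicopter cue ignored
            u_hat = agent.fixed_learning_rate * delta
        else:
            target = pos + alpha * delta
            if not math.isnan(w):
                target = w * target + (1.0 - w) * mu[t]
            u_hat = target - pos
        sd = uv + lrv * abs(delta)
        u = u_hat if sd == 0.0 else u_hat + rng.normal(0.0, sd)
        pos = min(max(pos + u, lo), hi)
    return pd.DataFrame({"trial": task["trial"].to_numpy(),
                         "block": block, "bucket": bucket})


def score_coins(task: pd.DataFrame, behavior: pd.DataFrame,
                falloff_width: float = 100.0) -> int:
    """Total coins earned: gold trials pay linearly in bucket-bag distance.

    Per gold trial ``coins = max(0, round(200 * (1 - d / falloff_width)))``
    with ``d = |bag - bucket|``; rock trials pay nothing.
    """
    if len(task) != len(behavior):
        raise ValueError("task and behaviour tables differ in length")
    d = np.abs(task["bag"].to_numpy(float) - behavior["bucket"].to_numpy(float))
    per_trial = np.maximum(0.0, np.round(200.0 * (1.0 - d / falloff_width)))
    per_trial[~task["is_gold"].to_numpy(bool)] = 0.0
    return int(per_trial.sum())


@dataclass(frozen=True)
class CohortSpec:
    """Group-level parameter and covariate distributions for a cohort.

    Defaults encode the observed age phenotype: older adults underestimate
    uncertainty more (higher mean log-UU), select learning rates more
    variably (higher LRV) and are less sensitive to surprise, while hazard
    assumptions do not differ.  The within-group log-UU spread (0.75) makes
    the group phenotypes distinct latent populations; the spread of raw
    parameter *estimates* in fitted data is wider because it folds in
    estimation noise.  ``age_per_log_uu`` optionally couples age to log-UU
    within group (years per log unit) for explanatory-model recovery
    studies.
    """

    log_uu_mean_young: float = 1.5
    log_uu_mean_old: float = 2.7
    log_uu_sd: float = 0.75
    ss_mean_young: float = 0.51
    ss_mean_old: float = 0.40
    ss_sd: float = 0.08
    hazard: float = 0.1
    uv_mean: float = 5.0
    uv_sd: float = 1.5
    lrv_mean_young: float = 0.05
    lrv_mean_old: float = 0.10
    lrv_sd: float = 0.03
    cue_sd: float = 10.0
    age_range_young: tuple[float, float] = (20.0, 30.0)
    age_range_old: tuple[float, float] = (56.0, 80.0)
    raven_mean_young: float = 28.0
    raven_mean_old: float = 22.0
    raven_sd: float = 4.0
    ospan_mean_young: float = 50.0
    ospan_mean_old: float = 38.0
    ospan_sd: float = 10.0
    age_per_log_uu: float = 0.0

    def null(self) -> "CohortSpec":
        """Spec with all group effects removed (old == young)."""
        return replace(self,
                       log_uu_mean_old=self.log_uu_mean_young,
                       ss_mean_old=self.ss_mean_young,
                       lrv_mean_old=self.lrv_mean_young,
                       raven_mean_old=self.raven_mean_young,
                       ospan_mean_old=self.ospan_mean_young)


@dataclass(frozen=True)
class Subject:
    subject: int
    group: str
    age: float
    raven: float
    ospan: float
    agent: AgentSpec


def generate_cohort(n_young: int, n_old: int,
                    spec: CohortSpec | None = None,
                    seed: int = 0) -> list[Subject]:
    """Draw a cohort of simulated subjects with covariates.

    Every subject gets an agent whose flexible-model parameters are drawn
    from its group's distributions (log-UU truncated at 0, SS clipped to
    (0.05, 1], UV floored at 0.5, LRV at 0).
    """
    if n_young < 1 or n_old < 1:
        raise ValueError("need at least one subject per group")
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    subjects: list[Subject] = []
    sid = 0
    for group, n in (("young", n_young), ("old", n_old)):
        young = group == "young"
        luu_m = spec.log_uu_mean_young if young else spec.log_uu_mean_old
        ss_m = spec.ss_mean_young if young else spec.ss_mean_old
        lrv_m = spec.lrv_mean_young if young else spec.lrv_mean_old
        ages = spec.age_range_young if young else spec.age_range_old
        rav_m = spec.raven_mean_young if young else spec.raven_mean_old
        osp_m = spec.ospan_mean_young if young else spec.ospan_mean_old
        for _ in range(n):
            log_uu = max(0.0, rng.normal(luu_m, spec.log_uu_sd))
            ss = float(np.clip(rng.normal(ss_m, spec.ss_sd), 0.05, 1.0))
            uv = max(0.5, rng.normal(spec.uv_mean, spec.uv_sd))
            lrv = max(0.0, rng.normal(lrv_m, spec.lrv_sd))
            params = FlexibleParams(hazard=spec.hazard,
                                    surprise_sensitivity=ss, log_uu=log_uu,
                                    cue_sd=spec.cue_sd,
                                    update_variability=uv,
                                    learning_rate_variability=lrv)
            agent = AgentSpec(model_kind="normative", params=params,
                              update_variability=uv,
                              learning_rate_variability=lrv,
                              seed=int(rng.integers(0, 2**31 - 1)))
            age = rng.uniform(*ages) + spec.age_per_log_uu * (log_uu - luu_m)
            subjects.append(Subject(
                subject=sid, group=group, age=float(age),
                raven=float(rng.normal(rav_m, spec.raven_sd)),
                ospan=float(rng.normal(osp_m, spec.ospan_sd)),
                agent=agent))
            sid += 1
    return subjects


def cohort_table(subjects: Sequence[Subject]) -> pd.DataFrame:
    """Covariate table (one row per subject) for the explanatory models."""
    return pd.DataFrame({
        "subject": [s.subject for s in subjects],
        "group": [s.group for s in subjects],
        "age": [s.age for s in subjects],
        "raven": [s.raven for s in subjects],
        "ospan": [s.ospan for s in subjects],
        "log_uu_true": [s.agent.params.log_uu for s in subjects],
        "lrv_true": [s.agent.params.learning_rate_variability for s in subjects],
    })
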