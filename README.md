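# helilearn

Reduced-Bayesian change-point learning models — and the descriptive and
inferential analyses built on them — for the *helicopter* predictive-inference
task, aimed at computational cognitive scientists studying how surprise,
uncertainty and hazard-rate beliefs regulate error-driven learning (for
example, across healthy aging).

In the task, a hidden helicopter on a 0–300 screen drops a bag each trial;
the bag lands Gaussian-distributed around the helicopter (s.d. 10 or 25 by
block), and the helicopter relocates abruptly with hazard *H* = 0.1. On 10%
of trials (catch trials) the helicopter is visible. The subject moves a
bucket to predict the next bag.

## The model

The normative observer summarises its belief state with two quantities that
jointly set a trial-by-trial learning rate:

- **change-point probability** ("surprise")
  `Ω = U·H / (U·H + N(δ; 0, σ²_N/(1−τ))·(1−H))`,
  the posterior that prediction error δ followed a relocation, with `U = 1/300`
  the uniform post-change outcome density;
- **relative uncertainty**
  `τ = σ²_μ / (σ²_μ + σ²_N)`, the share of predictive variance due to not
  knowing the helicopter's position, propagated by the mixture rule
  `σ²_μ' = Ω σ²_N + (1−Ω) τ σ²_N + Ω(1−Ω) (δ(1−τ))²`.

Beliefs follow a delta rule `B' = B + αδ` with `α = Ω + (1−Ω)τ`. On catch
trials the visible helicopter acts as a Gaussian cue combined with the belief
by precision weighting. A *flexible* superset adds principled deviations —
surprise insensitivity (SS), hazard mis-estimation, uncertainty
underestimation (UU), mis-scaled noise — and reduces to the normative model
bit-for-bit at neutral parameter values.

On top of that sit:

- **synthetic_task / cohorts** (`helilearn.synthetic`): task sessions with the
  statistics above, simulated agents (normative and deviant, with update
  noise `UV + LRV·|δ|`), and covariate-bearing cohorts;
- **MAP fitting** (`helilearn.fitting`): subject-level fits of the flexible
  model to (error, update) pairs under weak normative-centred priors, with
  four likelihood variants up to a noise-scale mixture, compared by BIC;
- **windowed regression** (`helilearn.regression`): trial exclusions,
  model-derived regressors, heteroscedasticity weights, weighted ridge
  solves and 90 sliding error-magnitude bins;
- **group inference** (`helilearn.inference`): cluster-mass permutation
  tests (sign- and label-flipping), leave-one-subject-out coefficient
  extraction and nested-F explanatory models of age;
- **pipeline/CLI** (`helilearn.pipeline`, `helilearn` command): one seeded
  run of simulate → fit → regress → infer with a reproducibility manifest.

## Worked example

```python
import helilearn as hl

cfg = hl.TaskConfig(seed=7)                       # 2 blocks x 200 trials
task = hl.generate_session(cfg)
agent = hl.AgentSpec.of_kind("uncertainty_underestimation", uv=3.0, seed=1)
beh = hl.simulate_agent(task, agent, cfg)
print(f"coins: {hl.score_coins(task, beh)}")

traj = hl.run_model(task, cfg.model_config())      # normative latents
print(traj[["omega", "tau", "alpha"]].describe().loc[["mean", "max"]].round(3))
```

```
coins: 30628
      omega    tau  alpha
mean  0.118  0.255  0.343
max   1.000  0.678  1.000
```

The agent earned 30,628 of a possible 39,000 coins. The normative latents
show what the task demands: surprise is usually near zero but saturates at
change points, relative uncertainty spikes after one and decays with each
well-predicted outcome, and the learning rate spans the range from near 0
(stable periods) to 1 (relocations).

Fitting the flexible model to this agent's behaviour recovers its deviation
(true log-UU = log 10 ≈ 2.30):

```python
from helilearn import fitting
data = fitting.SubjectData.from_tables(task, beh)
fit = fitting.fit_subject(data, "base", seed=0)
print(round(fit.params.log_uu, 2))                 # -> 2.24
```

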