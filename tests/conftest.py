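import numpy as np
import pandas as pd
import pytest

import helilearn as hl


@pytest.fixture(scope="session")
def task_cfg() -> hl.TaskConfig:
    return hl.TaskConfig(seed=7)


@pytest.fixture(scope="session")
def model_cfg(task_cfg) -> hl.ModelConfig:
    return task_cfg.model_config()


@pytest.fixture(scope="session")
def session_task(task_cfg) -> pd.DataFrame:
    """One two-block task session (s.d. 10 then 25) at a fixed seed."""
    return hl.generate_session(task_cfg)


@pytest.fixture(scope="session")
def normative_errors(session_task, model_cfg) -> np.ndarray:
    """Prediction errors experienced by the generative normative model."""
    return hl.run_model(session_task, model_cfg)["delta"].to_numpy()


def pooled_sessions(kind: str, n_sessions: int, uv: float, lrv: float = 0.0,
                    seed0: int = 500, cfg: hl.TaskConfig | None = None):
    """Simulate one agent over many sessions, pooled as one long subject."""
    cfg = cfg or hl.TaskConfig(seed=7)
    tasks, behs = [], []
    for i in range(n_sessions):
        t = hl.generate_session(hl.TaskConfig(seed=seed0 + i))
        agent = hl.AgentSpec.of_kind(kind, uv=uv, lrv=lrv, seed=i)
        b = hl.simulate_agent(t, agent, cfg)
        t = t.copy()
        t["block"] += 2 * i
        b["block"] += 2 * i
        tasks.append(t)
        behs.append(b)
    return (pd.concat(tasks, ignore_index=True),
            pd.concat(behs, ignore_index=True))
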