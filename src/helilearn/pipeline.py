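"""End-to-end orchestration: simulate -> model -> fit -> regress -> infer.

A single seeded configuration drives cohort generation, task simulation,
subject-level MAP fits, the windowed regression and the group-level
permutation/LOSO/age analyses, writing every intermediate artifact plus a
manifest (config hash, per-file content hashes, stage timings) so that a
re-run with the same configuration reproduces every output bit for bit.

The global seed is fanned out to independent per-stage streams with
``numpy.random.SeedSequence.spawn``, so each stage is reproducible in
isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fitting, inference, regression, synthetic
from .normative import ModelConfig
from .synthetic import AgentSpec, CohortSpec, Subject, TaskConfig

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures",
           "write_table", "read_table", "simulate_cohort"]

SCHEMA_LINE = "# helilearn-table-v1"


def write_table(df: pd.DataFrame, path: Path) -> None:
    """Write a delimited table with a versioned schema header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(SCHEMA_LINE + "\n")
        df.to_csv(fh, index=False)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs, with the task's published statistics
    as defaults."""

    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    n_young: int = 8
    n_old: int = 8
    fit_model_id: str = "base"
    fit_restarts: int = 3
    ridge: float = regression.DEFAULT_RIDGE
    n_bins: int = regression.N_BINS
    window_frac: float = regression.WINDOW_FRAC
    n_permutations: int = 1000
    smooth_width: int = 5
    cue_sd: float = 10.0
    seed: int = 0

    def to_yaml(self) -> str:
        payload = asdict(self)
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        payload = yaml.safe_load(text)
        task = payload.pop("task", {})
        if "noise_sds" in task:
            task["noise_sds"] = tuple(task["noise_sds"])
        cohort = payload.pop("cohort", {})
        for k in ("age_range_young", "age_range_old"):
            if k in cohort:
                cohort[k] = tuple(cohort[k])
        return cls(task=TaskConfig(**task), cohort=CohortSpec(**cohort), **payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def simulate_cohort(subjects: list[Subject], cfg: TaskConfig,
                    seed: int) -> tuple[list[pd.DataFrame], list[pd.DataFrame]]:
    """One task session and one behaviour series per subject."""
    streams = np.random.SeedSequence(seed).spawn(len(subjects))
    tasks, behaviors = [], []
    for subj, ss in zip(subjects, streams):
        rng = np.random.default_rng(ss)
        task = synthetic.generate_session(cfg, rng=rng)
        beh = synthetic.simulate_agent(task, subj.agent, cfg, rng=rng)
        tasks.append(task)
        behaviors.append(beh)
    return tasks, behaviors


def run_pipeline(cfg: PipelineConfig, out_dir: Path) -> dict:
    """Execute every stage on a synthetic cohort; returns the manifest.

    Any stage failure is recorded in the manifest (stage name and error)
    before the exception is re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]
    manifest: dict = {"config": yaml.safe_load(cfg.to_yaml()),
                      "config_hash": hashlib.sha256(cfg.to_yaml().encode()).hexdigest(),
                      "stages": {}, "hashes": {}, "completed": False}
    t_all = time.perf_counter()

    def _finish_stage(name: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3),
                                    "files": [f.name for f in files]}
        for f in files:
            manifest["hashes"][f.name] = _sha256(f)

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        subjects = synthetic.generate_cohort(cfg.n_young, cfg.n_old, cfg.cohort,
                                             seed=stage_seed[0])
        tasks, behaviors = simulate_cohort(subjects, cfg.task, stage_seed[1])
        files = []
        for subj, task, beh in zip(subjects, tasks, behaviors):
            tp = out / f"task_{subj.subject:03d}.csv"
            bp = out / f"behavior_{subj.subject:03d}.csv"
            write_table(task, tp)
            write_table(beh, bp)
            files += [tp, bp]
        cov = synthetic.cohort_table(subjects)
        cp = out / "cohort.csv"
        write_table(cov, cp)
        _finish_stage(stage, t0, files + [cp])

        stage = "fit"
        t0 = time.perf_counter()
        fit_rows = []
        for subj, task, beh in zip(subjects, tasks, behaviors):
            data = fitting.SubjectData.from_tables(task, beh)
            res = fitting.fit_subject(data, cfg.fit_model_id,
                                      n_restarts=cfg.fit_restarts,
                                      seed=stage_seed[2] + subj.subject,
                                      cfg=cfg.task.model_config(cue_sd=cfg.cue_sd))
            row = {"subject": subj.subject, "group": subj.group,
                   "model_id": res.model_id,
                   "log_posterior": res.log_posterior,
                   "penalty_score": res.penalty_score,
                   "converged": res.converged}
            row.update({k: v for k, v in dataclasses.asdict(res.params).items()})
            fit_rows.append(row)
        fits = pd.DataFrame(fit_rows)
        fp = out / "fits.csv"
        write_table(fits, fp)
        _finish_stage(stage, t0, [fp])

        stage = "regress"
        t0 = time.perf_counter()
        cfgs = [cfg.task.model_config(cue_sd=cfg.cue_sd) for _ in subjects]
        windowed = regression.analyze_cohort(tasks, behaviors, cfgs,
                                             ridge=cfg.ridge, n_bins=cfg.n_bins,
                                             window_frac=cfg.window_frac)
        long = pd.concat([w.to_frame(subj.subject)
                          for w, subj in zip(windowed, subjects)],
                         ignore_index=True)
        wp = out / "windowed_coefficients.csv"
        write_table(long, wp)
        _finish_stage(stage, t0, [wp])

        stage = "infer"
        t0 = time.perf_counter()
        groups = np.array([s.group for s in subjects])
        results: dict = {"cluster_tests": {}, "group_fit_tests": {}}
        for coef in ("delta", "delta_x_uncertainty", "delta_x_surprise",
                     "helicopter"):
            j = regression.COEF_NAMES.index(coef)
            mat = np.stack([w.coefficients[:, j] for w in windowed])
            young = mat[groups == "young"]
            old = mat[groups == "old"]
            test = inference.cluster_mass_permutation_test(
                young, old, n_permutations=cfg.n_permutations,
                seed=stage_seed[3], smooth_width=cfg.smooth_width)
            results["cluster_tests"][coef] = {
                "clusters": test.clusters,
                "n_permutations": test.n_permutations,
            }
            if len(test.significant) > 0 and young.shape[0] >= 3 and old.shape[0] >= 3:
                loso_vals = inference.loso_extract(young, old)
                results.setdefault("loso", {})[coef] = loso_vals.tolist()
        from scipy import stats as sstats
        for param in ("log_uu", "learning_rate_variability"):
            y = fits.loc[fits["group"] == "young", param]
            o = fits.loc[fits["group"] == "old", param]
            t, p = sstats.ttest_ind(o, y)
            results["group_fit_tests"][param] = {"t": float(t), "p": float(p)}
        cov = synthetic.cohort_table(subjects)
        age_model = inference.age_explanatory_model(
            cov["age"].to_numpy(),
            {"log_uu": fits["log_uu"].to_numpy()},
            {"raven": cov["raven"].to_numpy(), "ospan": cov["ospan"].to_numpy()})
        results["age_model_comparisons"] = [
            {"reduced": r, "full": f, "F": F, "p": p}
            for r, f, F, p in age_model.comparisons]
        ip = out / "inference.json"
        ip.write_text(json.dumps(results, indent=2, sort_keys=True))
        _finish_stage(stage, t0, [ip])
        manifest["completed"] = True
    except Exception as exc:  # noqa: BLE001 - manifest must record the failure
        manifest["failed_stage"] = stage
        manifest["error"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
        raise
    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def make_fixtures(seed: int = 1234, out_dir: Path | str = "fixtures") -> dict:
    """Deterministic miniature cohort for fast tests.

    Six subjects (all five observer kinds plus a second normative agent),
    two 100-trial blocks each; regenerating with the same seed reproduces
    every file byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = TaskConfig(n_trials_per_block=100, seed=seed)
    kinds = list(synthetic.MODEL_KINDS) + ["normative"]
    streams = np.random.SeedSequence(seed).spawn(len(kinds))
    rows, files = [], []
    for i, (kind, ss) in enumerate(zip(kinds, streams)):
        rng = np.random.default_rng(ss)
        agent = AgentSpec.of_kind(kind, uv=3.0, lrv=0.05, seed=i)
        task = synthetic.generate_session(cfg, rng=rng)
        beh = synthetic.simulate_agent(task, agent, cfg, rng=rng)
        tp, bp = out / f"task_{i:03d}.csv", out / f"behavior_{i:03d}.csv"
        write_table(task, tp)
        write_table(beh, bp)
        files += [tp, bp]
        rows.append({"subject": i, "model_kind": kind,
                     "uv": 3.0, "lrv": 0.05})
    cp = out / "fixture_cohort.csv"
    write_table(pd.DataFrame(rows), cp)
    files.append(cp)
    return {f.name: _sha256(f) for f in files}
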