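"""Descriptive learning analysis: exclusions, design matrix, weighted ridge
regression and sliding error-magnitude bins.

Trial-by-trial updates ``u_t = B_{t+1} - B_t`` (bucket displacement) are
regressed on prediction errors ``delta_t = bag_t - B_t`` and on the
interaction of ``delta`` with five mean-centred factors: model-derived
surprise (change-point probability) and uncertainty (relative uncertainty),
the block's noise condition, trial value (gold vs rocks) and helicopter
visibility.  Updates toward the visible helicopter are carried by a
``(helicopter - bucket) * visibility`` term and a centre-of-screen bias by
``(centre - bucket)``.

Because residuals grow with error magnitude, an unweighted initialization
regression is fit per subject, residuals are pooled, their variance is
measured in sliding windows of error magnitude, and each trial is weighted
by the inverse variance of its window.  The final solve adds a ridge
penalty (0.1 by default, intercept unpenalized).

The same model is then refit in 90 sliding bins of relative error magnitude
``|delta| / sigma_N`` (each bin holds 10% of the data, bounds advance by
one percentile), producing the coefficient-by-surprise-level profiles that
the group-level permutation tests consume.  Inside each bin the interaction
factors are re-centred on the bin's own trials, so the ``delta``
coefficient reads as the learning rate at that bin's typical surprise and
uncertainty (leaving the factors centred on the subject's grand mean would
make the interactions collinear with ``delta`` inside a narrow bin and the
per-bin learning rate unidentifiable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .normative import ModelConfig, run_model

__all__ = [
    "COEF_NAMES",
    "preprocess_trials",
    "compute_model_regressors",
    "build_design",
    "estimate_heteroscedastic_weights",
    "ridge_weighted_solve",
    "sliding_window_fit",
    "analyze_cohort",
]

#: design-matrix columns, in order
COEF_NAMES = [
    "intercept",
    "delta",
    "delta_x_surprise",
    "delta_x_uncertainty",
    "delta_x_noise",
    "delta_x_value",
    "delta_x_visibility",
    "helicopter",
    "centre_bias",
]

DEFAULT_RIDGE = 0.1
N_BINS = 90
WINDOW_FRAC = 0.10
MAX_DEVIATION = 15.0  # screen units from any plausible delta-rule update


def _segment_distance(x: float, a: float, b: float) -> float:
    """Distance from ``x`` to the closed interval between ``a`` and ``b``."""
    lo, hi = (a, b) if a <= b else (b, a)
    if x < lo:
        return lo - x
    if x > hi:
        return x - hi
    return 0.0


def preprocess_trials(task: pd.DataFrame, behavior: pd.DataFrame) -> pd.DataFrame:
    """Compute errors/updates and apply the trial exclusion rules.

    Exclusions: first and last trial of each block; trials with a zero
    prediction error; trials whose next bucket placement falls more than 15
    screen units from every possible delta-rule update, i.e. from the
    segment between the current bucket and the bag (unioned with the
    segment toward the helicopter on catch trials).

    Returns the full per-trial table with ``delta``, ``update``,
    ``rel_err`` and an ``included`` flag; the excluded fraction is stored
    in ``df.attrs['excluded_fraction']`` (relative to trials with a defined
    update).
    """
    if len(task) != len(behavior):
        raise ValueError("task and behaviour tables differ in length")
    df = task.reset_index(drop=True).copy()
    bucket = behavior["bucket"].to_numpy(dtype=float)
    bag = df["bag"].to_numpy(dtype=float)
    mu = df["helicopter"].to_numpy(dtype=float)
    block = df["block"].to_numpy()
    n = len(df)

    delta = bag - bucket
    update = np.full(n, np.nan)
    update[:-1] = bucket[1:] - bucket[:-1]
    last_of_block = np.ones(n, dtype=bool)
    last_of_block[:-1] = block[:-1] != block[1:]
    first_of_block = np.ones(n, dtype=bool)
    first_of_block[1:] = block[1:] != block[:-1]

    included = ~(first_of_block | last_of_block)
    included &= delta != 0.0
    deviant = np.zeros(n, dtype=bool)
    is_catch = df["is_catch"].to_numpy(bool)
    for t in np.flatnonzero(included):
        nxt = bucket[t + 1]
        dist = _segment_distance(nxt, bucket[t], bag[t])
        if is_catch[t]:
            dist = min(dist, _segment_distance(nxt, bucket[t], mu[t]))
        deviant[t] = dist > MAX_DEVIATION
    included &= ~deviant

    df["bucket"] = bucket
    df["delta"] = delta
    df["update"] = update
    df["rel_err"] = np.abs(delta) / df["noise_sd"].to_numpy(float)
    df["included"] = included
    candidates = ~(first_of_block | last_of_block)
    if included.sum() == 0:
        raise ValueError("all trials excluded; nothing to analyse")
    df.attrs["excluded_fraction"] = 1.0 - included.sum() / max(1, candidates.sum())
    return df


def compute_model_regressors(task: pd.DataFrame, behavior: pd.DataFrame,
                             cfg: ModelConfig) -> pd.DataFrame:
    """Subjective surprise and uncertainty for a subject's error sequence.

    Runs the normative model (ground-truth hazard and noise) conditioned on
    the subject's own prediction errors; returns per-trial ``surprise``
    (change-point probability) and ``uncertainty`` (relative uncertainty)
    aligned to the task table.
    """
    bucket = behavior["bucket"].to_numpy(dtype=float)
    delta = task["bag"].to_numpy(dtype=float) - bucket
    traj = run_model(task, cfg, mode="conditioned", observed_pe=delta,
                     observed_bucket=bucket)
    return pd.DataFrame({"surprise": traj["omega"].to_numpy(),
                         "uncertainty": traj["tau"].to_numpy()},
                        index=task.index)


@dataclass
class RegressionDataset:
    """Included trials of one subject, ready for design-matrix assembly.

    Holds the raw per-trial quantities; :meth:`design` mean-centres the
    five interaction factors over whichever subset of rows is being fit
    (the whole dataset for the full-model fits, the bin's trials for the
    sliding-window fits).  Regressors are left in natural units so the
    ``delta`` coefficient reads as a learning rate.
    """

    delta: np.ndarray
    update: np.ndarray
    rel_err: np.ndarray
    surprise: np.ndarray
    uncertainty: np.ndarray
    noise_sd: np.ndarray
    value: np.ndarray
    visibility: np.ndarray
    mu: np.ndarray
    bucket: np.ndarray
    screen_center: float = 150.0

    def __len__(self) -> int:
        return len(self.delta)

    @classmethod
    def from_tables(cls, trials: pd.DataFrame, regressors: pd.DataFrame,
                    screen_center: float = 150.0) -> "RegressionDataset":
        inc = trials["included"].to_numpy(bool)
        return cls(
            delta=trials.loc[inc, "delta"].to_numpy(float),
            update=trials.loc[inc, "update"].to_numpy(float),
            rel_err=trials.loc[inc, "rel_err"].to_numpy(float),
            surprise=regressors.loc[inc, "surprise"].to_numpy(float),
            uncertainty=regressors.loc[inc, "uncertainty"].to_numpy(float),
            noise_sd=trials.loc[inc, "noise_sd"].to_numpy(float),
            value=trials.loc[inc, "is_gold"].to_numpy(float),
            visibility=trials.loc[inc, "is_catch"].to_numpy(float),
            mu=trials.loc[inc, "helicopter"].to_numpy(float),
            bucket=trials.loc[inc, "bucket"].to_numpy(float),
            screen_center=screen_center,
        )

    def design(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Design matrix and response for ``rows`` (default: all trials).

        Columns are ordered as :data:`COEF_NAMES`; the five interaction
        factors are mean-centred over the selected rows.
        """
        idx = np.arange(len(self)) if rows is None else np.asarray(rows)
        d = self.delta[idx]

        def centred(x):
            x = x[idx]
            return x - x.mean()

        vis = self.visibility[idx]
        A = np.column_stack([
            np.ones_like(d),
            d,
            d * centred(self.surprise),
            d * centred(self.uncertainty),
            d * centred(self.noise_sd),
            d * centred(self.value),
            d * centred(self.visibility),
            (self.mu[idx] - self.bucket[idx]) * vis,
            self.screen_center - self.bucket[idx],
        ])
        return A, self.update[idx]


def build_design(trials: pd.DataFrame, regressors: pd.DataFrame,
                 screen_center: float = 150.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subject-level design matrix (factors centred on all included trials).

    Returns ``(A, y, rel_err)``; see :class:`RegressionDataset`.
    """
    ds = RegressionDataset.from_tables(trials, regressors, screen_center)
    A, y = ds.design()
    return A, y, ds.rel_err


def _window_bounds(n: int, n_bins: int = N_BINS,
                   window_frac: float = WINDOW_FRAC) -> list[tuple[int, int]]:
    """Index bounds of sliding percentile windows over ``n`` sorted trials.

    Window ``p`` spans one window width starting at percentile
    ``p * (100 - width) / (n_bins - 1)``; for the default 90 bins of 10%
    width the lower bound advances by one percentile per bin (90/89, to be
    exact) and the windows tile the full [0, 100] range.
    """
    width_pct = window_frac * 100.0
    step = (100.0 - width_pct) / max(1, n_bins - 1)
    bounds = []
    for p in range(n_bins):
        lo_pct = p * step
        lo = int(np.floor(lo_pct * n / 100.0))
        hi = min(n, int(np.floor((lo_pct + width_pct) * n / 100.0)))
        lo = min(lo, n - 1)
        hi = max(hi, lo + 1)  # never an empty window
        bounds.append((lo, hi))
    return bounds


def estimate_heteroscedastic_weights(designs: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
                                     var_floor: float = 1e-6) -> list[np.ndarray]:
    """Inverse-variance weights from pooled initialization-regression residuals.

    Each subject gets an ordinary (unweighted, unpenalized) least-squares
    fit of the full design; residuals are pooled across subjects, their
    variance is computed in sliding windows of relative error magnitude
    (10% of the pooled data, advancing one percentile) and every trial is
    weighted by the inverse variance of the window whose centre is nearest
    its own percentile rank.  Zero-variance windows are floored at
    ``var_floor``.
    """
    resid_all, rel_all, owner = [], [], []
    for s, (A, y, rel) in enumerate(designs):
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid_all.append(y - A @ beta)
        rel_all.append(rel)
        owner.append(np.full(len(y), s))
    resid = np.concatenate(resid_all)
    rel = np.concatenate(rel_all)
    owner = np.concatenate(owner)
    n = len(resid)

    order = np.argsort(rel, kind="stable")
    sorted_resid = resid[order]
    bounds = _window_bounds(n)
    win_var = np.array([max(var_floor, float(np.var(sorted_resid[lo:hi])))
                        for lo, hi in bounds])
    centers = np.array([(lo + hi) / 2.0 for lo, hi in bounds])

    rank = np.empty(n)
    rank[order] = np.arange(n)
    # nearest window centre by percentile rank
    idx = np.clip(np.searchsorted(centers, rank), 0, len(centers) - 1)
    left = np.clip(idx - 1, 0, len(centers) - 1)
    idx = np.where(np.abs(centers[left] - rank) <= np.abs(centers[idx] - rank),
                   left, idx)
    weights = 1.0 / win_var[idx]
    return [weights[owner == s] for s in range(len(designs))]


def ridge_weighted_solve(A: np.ndarray, y: np.ndarray,
                         weights: np.ndarray | None = None,
                         ridge: float = DEFAULT_RIDGE,
                         penalize_intercept: bool = False) -> np.ndarray:
    """Solve ``beta = (A'PA + R)^-1 A'Py`` with ``R = ridge * I``.

    ``P`` is the diagonal inverse-variance weight matrix (identity if
    ``weights`` is None); the intercept (first column) is left unpenalized
    unless requested.  Raises ``np.linalg.LinAlgError`` on a singular
    system at ``ridge = 0``.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    if ridge < 0:
        raise ValueError("ridge parameter must be non-negative")
    if weights is None:
        weights = np.ones(len(y))
    R = np.eye(A.shape[1]) * ridge
    if not penalize_intercept and A.shape[1] > 0:
        R[0, 0] = 0.0
    AtP = A.T * weights
    return np.linalg.solve(AtP @ A + R, AtP @ y)


@dataclass
class WindowedCoefficients:
    """Per-bin coefficient profiles for one subject."""

    coefficients: np.ndarray        # (n_bins, n_coefs)
    bin_median_rel_err: np.ndarray  # (n_bins,)
    bin_counts: np.ndarray          # (n_bins,)
    coef_names: list[str]

    def to_frame(self, subject: int | str = 0) -> pd.DataFrame:
        rows = []
        for b in range(len(self.bin_counts)):
            for j, name in enumerate(self.coef_names):
                rows.append((subject, b, name, self.coefficients[b, j],
                             self.bin_median_rel_err[b], self.bin_counts[b]))
        return pd.DataFrame(rows, columns=["subject", "bin", "coefficient_name",
                                           "value", "bin_median_rel_err", "n"])


def sliding_window_fit(dataset: RegressionDataset,
                       weights: np.ndarray | None = None,
                       ridge: float = DEFAULT_RIDGE,
                       n_bins: int = N_BINS,
                       window_frac: float = WINDOW_FRAC) -> WindowedCoefficients:
    """Refit the full model in sliding bins of relative error magnitude.

    Trials are ranked by ``|delta| / sigma_N``; bin ``p`` spans percentiles
    ``[p, p + 10]`` so each of the 90 bins holds 10% of the subject's data
    (+-1 trial).  Interaction factors are re-centred within each bin.  With
    fewer trials than bins the bin count is reduced with a warning.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    if n < n_bins:
        import warnings
        warnings.warn(f"only {n} trials for {n_bins} bins; reducing bins to {n}")
        n_bins = n
    if weights is None:
        weights = np.ones(n)
    order = np.argsort(dataset.rel_err, kind="stable")
    bounds = _window_bounds(n, n_bins, window_frac)
    coefs = np.empty((n_bins, len(COEF_NAMES)))
    med = np.empty(n_bins)
    counts = np.empty(n_bins, dtype=int)
    for b, (lo, hi) in enumerate(bounds):
        rows = order[lo:hi]
        A, y = dataset.design(rows)
        coefs[b] = ridge_weighted_solve(A, y, weights[rows], ridge)
        med[b] = float(np.median(dataset.rel_err[rows]))
        counts[b] = hi - lo
    return WindowedCoefficients(coefs, med, counts, list(COEF_NAMES))


def analyze_cohort(tasks: Sequence[pd.DataFrame],
                   behaviors: Sequence[pd.DataFrame],
                   cfgs: Sequence[ModelConfig],
                   ridge: float = DEFAULT_RIDGE,
                   n_bins: int = N_BINS,
                   window_frac: float = WINDOW_FRAC) -> list[WindowedCoefficients]:
    """Full descriptive analysis for a cohort of subjects.

    Preprocesses every subject, pools residuals for the heteroscedasticity
    weights, then runs the sliding-window fit per subject.
    """
    datasets, designs = [], []
    for task, beh, cfg in zip(tasks, behaviors, cfgs):
        trials = preprocess_trials(task, beh)
        regs = compute_model_regressors(task, beh, cfg)
        ds = RegressionDataset.from_tables(trials, regs,
                                           screen_center=0.5 * cfg.outcome_range)
        A, y = ds.design()
        datasets.append(ds)
        designs.append((A, y, ds.rel_err))
    weight_lists = estimate_heteroscedastic_weights(designs)
    return [sliding_window_fit(ds, w, ridge, n_bins, window_frac)
            for ds, w in zip(datasets, weight_lists)]
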