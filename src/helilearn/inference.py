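"""Group-level inference over binned regression coefficients.

Coefficient profiles (subjects x error-magnitude bins) are smoothed with a
centred moving average, tested bin-wise with t-tests, and contiguous runs
of significant bins are summarized by their *cluster mass* (number of bins
times mean |t| within the cluster).  Familywise error is controlled by
comparing each observed mass against the permutation distribution of the
maximum cluster mass (sign-flipping subjects for one-group tests, shuffling
group labels for two-group tests).

Per-subject scalars are extracted from the binned profiles with a
leave-one-subject-out (LOSO) rule -- each subject's value is read from the
bin with the largest between-group |t| computed *without* that subject --
which avoids the circularity of picking the extraction bin on the full
sample.  The extracted values (or fitted model parameters) then enter
ordinary regressions explaining age, compared with nested F-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "smooth_across_bins",
    "cluster_mass_permutation_test",
    "ClusterTestResult",
    "loso_extract",
    "nested_f_test",
    "age_explanatory_model",
    "AgeModelResult",
]


def smooth_across_bins(coeffs: np.ndarray, width: int = 5) -> np.ndarray:
    """Centred moving average along the last axis with edge truncation.

    ``width`` must be odd; ``width = 1`` is the identity.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be an odd positive integer")
    x = np.atleast_2d(np.asarray(coeffs, dtype=float))
    n = x.shape[-1]
    if width > n:
        raise ValueError(f"width {width} exceeds number of bins {n}")
    if width == 1:
        out = x.copy()
    else:
        half = width // 2
        csum = np.concatenate([np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)],
                              axis=-1)
        idx_hi = np.minimum(np.arange(n) + half + 1, n)
        idx_lo = np.maximum(np.arange(n) - half, 0)
        out = (csum[..., idx_hi] - csum[..., idx_lo]) / (idx_hi - idx_lo)
    return out[0] if np.asarray(coeffs).ndim == 1 else out


def _one_sample_t(x: np.ndarray) -> np.ndarray:
    """Column-wise one-sample t statistics (zero for zero-variance columns)."""
    n = x.shape[0]
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
    return t


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise pooled-variance two-sample t statistics."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (a.mean(axis=0) - b.mean(axis=0)) / se, 0.0)
    return t


def _clusters_from_t(t: np.ndarray, t_crit: float) -> list[tuple[int, int, float]]:
    """Maximal runs of |t| above threshold -> (start, end, mass)."""
    sig = np.abs(t) > t_crit
    clusters = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            seg = np.abs(t[start:i])
            clusters.append((start, i - 1, float(len(seg) * seg.mean())))
            start = None
    if start is not None:
        seg = np.abs(t[start:])
        clusters.append((start, len(t) - 1, float(len(seg) * seg.mean())))
    return clusters


def _max_mass(t: np.ndarray, t_crit: float) -> float:
    cl = _clusters_from_t(t, t_crit)
    return max((m for _, _, m in cl), default=0.0)


@dataclass
class ClusterTestResult:
    """Clusters of contiguous significant bins with permutation p-values."""

    clusters: list[tuple[int, int, float, float]]  # (start, end, mass, p)
    t_per_bin: np.ndarray
    smooth_width: int
    n_permutations: int
    test_kind: str  # "one-group-vs-zero" | "two-group"

    @property
    def significant(self) -> list[tuple[int, int, float, float]]:
        return [c for c in self.clusters if c[3] < 0.05]


def cluster_mass_permutation_test(group_a: np.ndarray,
                                  group_b: np.ndarray | None = None,
                                  n_permutations: int = 10_000,
                                  alpha_forming: float = 0.05,
                                  seed: int = 0,
                                  smooth_width: int = 1) -> ClusterTestResult:
    """Cluster-mass permutation test over binned coefficients.

    One group: tests the mean profile against zero with sign-flipping
    permutations.  Two groups: tests the group difference with label
    permutations.  Cluster-forming threshold is the two-sided t critical
    value at ``alpha_forming``; the null summary per permutation is the
    maximum cluster mass, and cluster p-values use the (count + 1) /
    (n_permutations + 1) estimator.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    if a.shape[0] < 2:
        raise ValueError("need at least two subjects per group")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations; p-values will be coarse")
    if smooth_width > 1:
        a = smooth_across_bins(a, smooth_width)
    rng = np.random.default_rng(seed)

    if group_b is None:
        n, nb = a.shape
        df = n - 1
        t_crit = float(stats.t.ppf(1.0 - alpha_forming / 2.0, df))
        t_obs = _one_sample_t(a)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            null[i] = _max_mass(_one_sample_t(a * signs[i][:, None]), t_crit)
        kind = "one-group-vs-zero"
    else:
        b = np.atleast_2d(np.asarray(group_b, dtype=float))
        if b.shape[0] < 2:
            raise ValueError("need at least two subjects per group")
        if smooth_width > 1:
            b = smooth_across_bins(b, smooth_width)
        na = a.shape[0]
        pooled = np.vstack([a, b])
        df = pooled.shape[0] - 2
        t_crit = float(stats.t.ppf(1.0 - alpha_forming / 2.0, df))
        t_obs = _two_sample_t(a, b)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(pooled.shape[0])
            null[i] = _max_mass(_two_sample_t(pooled[perm[:na]], pooled[perm[na:]]),
                                t_crit)
        kind = "two-group"

    clusters = []
    for start, end, mass in _clusters_from_t(t_obs, t_crit):
        p = (np.count_nonzero(null >= mass) + 1.0) / (n_permutations + 1.0)
        clusters.append((start, end, mass, float(p)))
    return ClusterTestResult(clusters=clusters, t_per_bin=t_obs,
                             smooth_width=smooth_width,
                             n_permutations=n_permutations, test_kind=kind)


def loso_extract(group_a: np.ndarray, group_b: np.ndarray,
                 return_bins: bool = False):
    """Leave-one-subject-out extraction of per-subject scalars.

    For each subject, the between-group t-statistic is computed per bin on
    all *other* subjects and the subject's own value is read from the bin
    with the maximum |t| (ties break to the lowest bin index).  Returns the
    values in group order (A then B), optionally with the chosen bins.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need at least three subjects per group")
    values, bins = [], []
    for g, other, mat in (("a", b, a), ("b", a, b)):
        for s in range(mat.shape[0]):
            rest = np.delete(mat, s, axis=0)
            t = _two_sample_t(rest, other) if g == "a" else _two_sample_t(other, rest)
            bin_idx = int(np.argmax(np.abs(t)))  # argmax takes lowest on ties
            values.append(mat[s, bin_idx])
            bins.append(bin_idx)
    values = np.asarray(values)
    bins = np.asarray(bins)
    return (values, bins) if return_bins else values


def nested_f_test(rss_reduced: float, df_reduced: float,
                  rss_full: float, df_full: float) -> tuple[float, float]:
    """F-test comparing nested least-squares models.

    ``F = ((RSS_r - RSS_f) / (df_r - df_f)) / (RSS_f / df_f)``, with the
    p-value from the F(df_r - df_f, df_f) distribution.
    """
    if df_full >= df_reduced:
        raise ValueError("full model must use more parameters (smaller residual df)")
    if rss_full > rss_reduced * (1.0 + 1e-12):
        raise ValueError("full-model RSS exceeds reduced-model RSS; models not nested")
    dfn = df_reduced - df_full
    f = ((rss_reduced - rss_full) / dfn) / (rss_full / df_full)
    p = float(stats.f.sf(f, dfn, df_full))
    return float(f), p


@dataclass
class AgeModelResult:
    """Explanatory regressions of age on task measures and covariates."""

    models: dict                      # name -> dict(rss, df, coef, se, terms)
    comparisons: list[tuple[str, str, float, float]]  # (reduced, full, F, p)
    condition_numbers: dict = field(default_factory=dict)


def _ols(X: np.ndarray, y: np.ndarray):
    cond = float(np.linalg.cond(X))
    if cond > 1e10:
        warnings.warn(f"ill-conditioned design (cond={cond:.2e}); "
                      "using pseudo-inverse")
        beta = np.linalg.pinv(X) @ y
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = len(y) - np.linalg.matrix_rank(X)
    sigma2 = rss / df if df > 0 else np.nan
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0, None))
    return beta, se, rss, df, cond


def age_explanatory_model(age: np.ndarray,
                          task_measures: dict[str, np.ndarray],
                          covariates: dict[str, np.ndarray] | None = None) -> AgeModelResult:
    """Nested explanatory models of age.

    Builds (1) intercept only, (2) intercept + task measures (LOSO
    coefficients or fitted parameters), (3) model 2 + covariates, plus a
    covariates-only model, and compares them with nested F-tests --
    including the key comparison of covariates-only against the full
    model (does the task measure explain age beyond the covariates?).
    """
    age = np.asarray(age, dtype=float)
    n = len(age)
    ones = np.ones((n, 1))
    meas = [np.asarray(v, float).reshape(n, 1) for v in task_measures.values()]
    covs = [np.asarray(v, float).reshape(n, 1)
            for v in (covariates or {}).values()]

    designs = {"intercept": (ones, ["intercept"])}
    if meas:
        designs["measures"] = (np.hstack([ones] + meas),
                               ["intercept", *task_measures])
    if covs:
        designs["covariates"] = (np.hstack([ones] + covs),
                                 ["intercept", *covariates])
        if meas:
            designs["full"] = (np.hstack([ones] + meas + covs),
                               ["intercept", *task_measures, *covariates])

    models, conds = {}, {}
    for name, (X, terms) in designs.items():
        beta, se, rss, df, cond = _ols(X, age)
        ci = 1.96 * se
        models[name] = {"terms": terms, "coef": beta, "se": se, "ci95": ci,
                        "rss": rss, "df": df}
        conds[name] = cond

    comparisons = []
    pairs = [("intercept", "measures"), ("measures", "full"),
             ("covariates", "full"), ("intercept", "covariates")]
    for red, full in pairs:
        if red in models and full in models:
            mr, mf = models[red], models[full]
            if mf["df"] < mr["df"] and set(mr["terms"]) < set(mf["terms"]):
                f, p = nested_f_test(mr["rss"], mr["df"], mf["rss"], mf["df"])
                comparisons.append((red, full, f, p))
    return AgeModelResult(models=models, comparisons=comparisons,
                          condition_numbers=conds)
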