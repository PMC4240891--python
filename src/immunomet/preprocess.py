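"""Cohort assembly preprocessing for pooled microarray datasets.

The stages, applied in order, mirror how multi-dataset GEO cohorts are
consolidated before any scoring or modeling:

1. ``dedup_profiles`` — drop redundant profiles (the same tumor deposited
   in more than one dataset, or hybridization repeats) detected by very
   high pairwise sample correlation.
2. ``filter_outliers`` — drop arrays whose overall signal-intensity
   distribution sits far below the cohort (failed hybridizations).
3. ``restrict_common_probes`` — intersect probe panels across array
   platforms.
4. ``quantile_normalize`` — force every sample onto the common
   mean-of-sorted reference distribution.
5. ``combat_adjust`` — parametric empirical-Bayes location/scale batch
   correction across the originating datasets.

Every stage is a pure transformation returning a new matrix plus, where
samples are removed, a machine-readable report.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

__all__ = [
    "dedup_profiles",
    "filter_outliers",
    "restrict_common_probes",
    "quantile_normalize",
    "combat_adjust",
]

log = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


def dedup_profiles(matrix: ExpressionMatrix, threshold: float = 0.99
                   ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove redundant sample profiles by pairwise Pearson correlation.

    For every sample pair correlated above ``threshold`` the later sample
    (by input column order) is removed; the earlier one is kept. Returns
    the deduplicated matrix and a report with columns
    ``removed_id, kept_id, correlation``.
    """
    if matrix.n_samples < 2:
        raise PreprocessError("dedup requires at least 2 samples")
    x = matrix.values.to_numpy()
    corr = np.corrcoef(x, rowvar=False)
    ids = matrix.sample_ids
    kept: list[int] = []
    rows = []
    for j in range(len(ids)):
        partner = next((i for i in kept if corr[i, j] > threshold), None)
        if partner is None:
            kept.append(j)
        else:
            rows.append({"removed_id": ids[j], "kept_id": ids[partner],
                         "correlation": float(corr[partner, j])})
    report = pd.DataFrame(rows, columns=["removed_id", "kept_id", "correlation"])
    if len(rows):
        log.info("dedup_profiles removed %d redundant profiles", len(rows))
    return matrix.subset_samples([ids[i] for i in kept]), report


def filter_outliers(matrix: ExpressionMatrix, k: float = 3.0,
                    min_drop: float = 0.5) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop arrays with abnormally low signal-intensity distributions.

    A sample is an outlier when its median intensity lies more than ``k``
    robust deviations (normal-consistent MAD) below the cohort median of
    per-sample medians, and at least ``min_drop`` log2 units below it —
    the absolute floor keeps tightly homogeneous cohorts from flagging
    samples on a noise-scale MAD. Only the low side is screened: the
    failure mode is weak hybridization signal.
    """
    if matrix.n_samples < 4:
        raise PreprocessError("outlier screening requires at least 4 samples")
    medians = matrix.values.median(axis=0)
    center = float(medians.median())
    scale = float(stats.median_abs_deviation(medians, scale="normal"))
    cutoff = center - max(k * scale, min_drop)
    bad = medians.index[medians < cutoff]
    report = pd.DataFrame({"removed_id": bad, "median_intensity": medians.loc[bad].to_numpy()})
    keep = [s for s in matrix.sample_ids if s not in set(bad)]
    if len(bad):
        log.info("filter_outliers removed %d low-signal arrays", len(bad))
    return matrix.subset_samples(keep), report


def restrict_common_probes(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the probes shared by all of them.

    Probe order follows the first matrix. Sample sets are untouched.
    """
    if not matrices:
        raise PreprocessError("no matrices given")
    common = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        common &= set(m.probe_ids)
    if not common:
        raise PreprocessError("probe panels have empty intersection")
    order = [p for p in matrices[0].probe_ids if p in common]
    return [m.subset_probes(order) for m in matrices]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples to the mean-of-sorted reference.

    After normalization every sample's sorted value vector equals the
    across-sample mean of sorted vectors; within-sample ranks are
    preserved. Ties receive the mean of the reference values spanned by
    their average rank (interpolated), so the map is deterministic.
    """
    if not matrix.is_complete():
        raise PreprocessError("quantile normalization requires a complete matrix")
    x = matrix.values.to_numpy()
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.batch)


def _combat_priors(delta_hat: np.ndarray) -> tuple[float, float]:
    # method-of-moments inverse-gamma hyperparameters for the scale prior
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    a = (2 * s2 + m**2) / s2
    b = (m * s2 + m**3) / s2
    return a, b


def _combat_it_sol(z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
                   g_bar: float, t2: float, a: float, b: float,
                   conv: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    # EB shrinkage of per-batch gene effects toward the batch-level priors
    n = np.isfinite(z).sum(axis=1)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max((np.abs(g_new - g_old) / np.abs(g_old)).max(),
                     (np.abs(d_new - d_old) / np.abs(d_old)).max())
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_adjust(matrix: ExpressionMatrix, batch: pd.Series | None = None
                  ) -> ExpressionMatrix:
    """Parametric empirical-Bayes batch adjustment (location and scale).

    Follows the standard ComBat recipe with an intercept-only design:
    standardize each probe using the weighted grand mean and pooled
    variance, estimate per-batch location/scale effects, shrink them
    toward batch-level normal / inverse-gamma priors, and back-transform.
    The per-probe overall mean is preserved up to numerical tolerance.

    A single batch is an identity transformation; a batch with fewer than
    two samples is an error naming the batch.
    """
    if batch is None:
        batch = matrix.batch
    if batch is None:
        raise PreprocessError("no batch labels supplied")
    batch = batch.reindex(matrix.values.columns)
    if not matrix.is_complete():
        raise PreprocessError("batch adjustment requires a complete matrix")

    levels = list(pd.unique(batch))
    sizes = batch.value_counts()
    small = [str(b) for b in levels if sizes[b] < 2]
    if small:
        raise PreprocessError(f"batch with fewer than 2 samples: {small}")
    if len(levels) == 1:
        return ExpressionMatrix(matrix.values.copy(), matrix.batch)

    x = matrix.values.to_numpy()
    n_array = x.shape[1]
    masks = [np.asarray(batch == b) for b in levels]
    n_batches = np.array([m.sum() for m in masks], dtype=float)

    # per-batch gene means; grand mean weighted by batch size; pooled variance
    b_hat = np.stack([x[:, m].mean(axis=1) for m in masks], axis=1)  # genes x batches
    grand = b_hat @ (n_batches / n_array)
    fitted = np.zeros_like(x)
    for i, m in enumerate(masks):
        fitted[:, m] = b_hat[:, [i]]
    var_pooled = ((x - fitted) ** 2).mean(axis=1)
    if np.any(var_pooled <= 0):
        var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)

    z = (x - grand[:, None]) / sd[:, None]

    adjusted = np.empty_like(x)
    for i, m in enumerate(masks):
        zi = z[:, m]
        g_hat = zi.mean(axis=1)
        d_hat = zi.var(axis=1, ddof=1)
        g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
        a, b = _combat_priors(d_hat)
        g_star, d_star = _combat_it_sol(zi, g_hat, d_hat, g_bar, t2, a, b)
        adjusted[:, m] = (zi - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = adjusted * sd[:, None] + grand[:, None]
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.batch)
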