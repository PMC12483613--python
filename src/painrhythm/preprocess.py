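"""Count-matrix triage and normalization for the blood transcriptome arm.

The raw input is a transcripts x samples integer count matrix with a sample
sheet (participant, day/night time point, sequencing batch, sex, phenotype).
This module provides:

* TMM (trimmed mean of M-values) library-size normalization factors;
* nonspecific filtering keeping the most variable transcripts by median
  absolute deviation (top 30 % by default);
* a three-metric sample-outlier triage (sum of inter-sample distances,
  Kolmogorov-Smirnov statistic versus the pooled intensity distribution, and
  Hoeffding's D on the sample's MA-plot against a median pseudo-reference),
  flagging by Tukey's far-out Q3 + 3 IQR fence and removing a sample only when it
  is flagged both before and after normalization, or by multiple metrics
  after normalization;
* a median log-ratio batch centering used in place of a full empirical-Bayes
  batch model (batch also enters the differential-expression design directly);
* a log2 counts-per-million transform with a small prior count, used as the
  variance-flattening transform feeding the filtering and network stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ExprMatrix:
    """Transcripts x samples matrix plus its sample sheet.

    ``values`` holds raw integer counts or transformed real values; the frame
    index carries transcript ids and columns carry sample ids, which must
    match the sample sheet's index.  ``norm_factors`` are TMM factors keyed by
    sample (geometric mean 1) when computed.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    norm_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise ValueError("transcript and sample ids must be unique")
        if self.norm_factors is not None and (self.norm_factors <= 0).any():
            raise ValueError("normalization factors must be positive")

    @property
    def lib_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)

    def effective_lib_sizes(self) -> pd.Series:
        f = self.norm_factors if self.norm_factors is not None else 1.0
        return self.lib_sizes * f


def tmm_factors(
    m: ExprMatrix,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
    ref: str | None = None,
) -> pd.Series:
    """TMM normalization factors, rescaled to geometric mean 1.

    For each sample a weighted trimmed mean of log2 expression ratios (M) to
    a reference sample is computed over transcripts expressed in both, with
    the most extreme 30 % of M values and 5 % of average log-abundances (A)
    trimmed and inverse-variance (delta-method) weights.  The reference is
    the library whose upper-quartile relative abundance is closest to the
    cohort mean (pinning the reference makes the result sample-order
    invariant).
    """
    counts = m.values.to_numpy(float)
    lib = counts.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"all-zero samples: {list(m.values.columns[zero])}")
    if ref is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(m.values.columns).index(ref)
    r = counts[:, ref_idx]
    nr = lib[ref_idx]
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        y = counts[:, j]
        keep = (y > 0) & (r > 0)
        if keep.sum() < 10:
            logger.warning("too few shared nonzero transcripts for %s; factor 1", m.values.columns[j])
            continue
        yk, rk = y[keep], r[keep]
        M = np.log2((yk / lib[j]) / (rk / nr))
        A = 0.5 * np.log2((yk / lib[j]) * (rk / nr))
        w = (lib[j] - yk) / (lib[j] * yk) + (nr - rk) / (nr * rk)
        lo_m, hi_m = np.quantile(M, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(A, [abundance_trim, 1 - abundance_trim])
        sel = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if not sel.any():
            continue
        f = np.sum(M[sel] / w[sel]) / np.sum(1.0 / w[sel])
        factors[j] = 2.0**f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.values.columns, name="tmm_factor")


def log_cpm(m: ExprMatrix, factors: pd.Series | None = None, prior: float = 0.5) -> ExprMatrix:
    """log2 counts-per-million on TMM-effective library sizes.

    value = log2((count + prior) / (lib_size * factor) * 1e6).
    """
    if factors is None:
        factors = m.norm_factors if m.norm_factors is not None else pd.Series(1.0, index=m.values.columns)
    eff = m.lib_sizes * factors
    vals = np.log2((m.values + prior).div(eff, axis=1) * 1e6)
    return ExprMatrix(vals, m.samples.copy(), factors.copy())


def mad_filter(m: ExprMatrix, keep_fraction: float = 0.30) -> ExprMatrix:
    """Keep the top fraction of transcripts by median absolute deviation.

    Ranks rows of ``m.values`` (pass the transformed matrix to rank on
    log-CPM) by MAD and retains the top ceil(keep_fraction * n_rows), breaking
    MAD ties by transcript id so the selection is deterministic.
    """
    n = m.values.shape[0]
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if n < int(np.ceil(1 / keep_fraction)):
        raise ValueError("too few transcripts for the requested fraction")
    vals = m.values.to_numpy(float)
    mad = np.median(np.abs(vals - np.median(vals, axis=1, keepdims=True)), axis=1)
    k = int(np.ceil(keep_fraction * n))
    order = sorted(range(n), key=lambda i: (-mad[i], str(m.values.index[i])))
    keep = sorted(order[:k], key=lambda i: i)  # preserve original row order
    out = m.values.iloc[keep]
    return ExprMatrix(out, m.samples.copy(), None if m.norm_factors is None else m.norm_factors.copy())


def hoeffding_d(x: np.ndarray, y: np.ndarray) -> float:
    """Hoeffding's D statistic of dependence between two vectors.

    Classic rank-based formula (scaled by 30 as in the original definition);
    ties handled with midranks.  D is near 0 under independence and grows
    with monotone or non-monotone dependence.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 5:
        raise ValueError("Hoeffding's D needs n >= 5")
    R = stats.rankdata(x)
    S = stats.rankdata(y)
    # Q_i: 1 + number of points with both coordinates strictly below point i,
    # with tie corrections
    Q = np.empty(n)
    for i in range(n):
        below = (x < x[i]) & (y < y[i])
        tx = (x == x[i]) & (y < y[i])
        ty = (x < x[i]) & (y == y[i])
        txy = (x == x[i]) & (y == y[i])
        Q[i] = 1 + below.sum() + 0.5 * tx.sum() + 0.5 * ty.sum() + 0.25 * (txy.sum() - 1)
    D1 = np.sum((Q - 1) * (Q - 2))
    D2 = np.sum((R - 1) * (R - 2) * (S - 1) * (S - 2))
    D3 = np.sum((R - 2) * (S - 2) * (Q - 1))
    D = 30.0 * ((n - 2) * (n - 3) * D1 + D2 - 2 * (n - 2) * D3) / (
        n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    )
    return float(D)


def _tukey_flags(scores: np.ndarray, k: float = 3.0) -> np.ndarray:
    # Tukey's far-out fence; the inner 1.5*IQR fence flags several percent of
    # samples in perfectly homogeneous cohorts at these cohort sizes
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    return scores > q3 + k * (q3 - q1)


def _outlier_scores(vals: np.ndarray) -> np.ndarray:
    """(n_samples, 3) matrix of distance-sum, KS, and Hoeffding-D scores."""
    n = vals.shape[1]
    dist = np.zeros(n)
    for j in range(n):
        dist[j] = sum(np.mean(np.abs(vals[:, j] - vals[:, k])) for k in range(n) if k != j)
    pooled = vals.ravel()
    ks = np.array([stats.ks_2samp(vals[:, j], pooled).statistic for j in range(n)])
    med = np.median(vals, axis=1)
    hd = np.empty(n)
    for j in range(n):
        a = 0.5 * (vals[:, j] + med)
        mm = vals[:, j] - med
        hd[j] = hoeffding_d(a, mm)
    return np.column_stack([dist, ks, hd])


def outlier_flag(m: ExprMatrix, prior: float = 0.5) -> pd.DataFrame:
    """Three-metric sample-outlier report with the two-clause removal rule.

    Scores are computed twice: before normalization on raw log2 counts
    (library-depth differences included, as in array-QC practice) and after
    TMM library-size normalization on log-CPM.  Each metric flags samples
    above the Q3 + 1.5 IQR fence of the cohort's scores.  A sample's removal
    verdict is true when it is flagged (by any metric) both before and after
    normalization, or when two or more metrics flag it after normalization -
    two screens that respond to different failure modes, so a homogeneous
    cohort is rarely touched.
    """
    if m.values.shape[1] < 4:
        raise ValueError("outlier triage needs >= 4 samples")
    before = _outlier_scores(np.log2(m.values.to_numpy(float) + prior))
    after = _outlier_scores(log_cpm(m, tmm_factors(m), prior).values.to_numpy())
    fb = np.column_stack([_tukey_flags(before[:, k]) for k in range(3)])
    fa = np.column_stack([_tukey_flags(after[:, k]) for k in range(3)])
    verdict = (fb.any(axis=1) & fa.any(axis=1)) | (fa.sum(axis=1) >= 2)
    report = pd.DataFrame(
        {
            "dist_sum": after[:, 0],
            "ks": after[:, 1],
            "hoeffding_d": after[:, 2],
            "flag_before": fb.any(axis=1),
            "flag_after_dist": fa[:, 0],
            "flag_after_ks": fa[:, 1],
            "flag_after_hd": fa[:, 2],
            "remove": verdict,
        },
        index=m.values.columns,
    )
    return report


def batch_adjust(m: ExprMatrix, batch: pd.Series | None = None) -> ExprMatrix:
    """Remove per-gene multiplicative batch shifts by median log-ratio centering.

    On the log2(count + 0.5) scale, each gene's per-batch median is shifted to
    the gene's grand median; counts are back-transformed and re-rounded to
    non-negative integers.  Singleton batches are passed through with a
    warning (their shift is not estimable).
    """
    if batch is None:
        batch = m.samples["batch"]
    batch = batch.astype(str)
    levels = sorted(batch.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 batches")
    logv = np.log2(m.values.to_numpy(float) + 0.5)
    grand = np.median(logv, axis=1, keepdims=True)
    adj = logv.copy()
    for lev in levels:
        cols = np.flatnonzero((batch == lev).to_numpy())
        if cols.size < 2:
            logger.warning("batch %s has a single sample; passed through unadjusted", lev)
            continue
        shift = np.median(logv[:, cols], axis=1, keepdims=True) - grand
        adj[:, cols] -= shift
    counts = np.maximum(np.round(2.0**adj - 0.5), 0).astype(int)
    out = pd.DataFrame(counts, index=m.values.index, columns=m.values.columns)
    return ExprMatrix(out, m.samples.copy(), None)
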