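"""Signed weighted coexpression networks, modules, and eigengene association.

Pipeline, applied independently to day and night sample sets:

1. Pearson correlation between transcripts on the batch-adjusted, transformed
   matrix; signed adjacency a_ij = ((1 + r_ij) / 2)^beta, with the
   soft-threshold beta chosen as the smallest power whose connectivity
   distribution fits a scale-free topology (log-log degree regression
   R^2 >= 0.80).
2. Topological overlap TOM_ij = (sum_u a_iu a_uj + a_ij) /
   (min(k_i, k_j) + 1 - a_ij); modules are branches of the average-linkage
   dendrogram of 1 - TOM, identified by an adaptive tree cut with a minimum
   module size (static-height cut available as fallback); unassigned
   transcripts are labelled 'grey'.
3. Module eigengenes (first principal component of the standardized member
   profiles, sign-anchored to the module mean profile); modules are
   iteratively merged while any two eigengenes correlate at or above the
   merge threshold (0.30, as an absolute correlation by default).
4. Module-trait association of each eigengene with the rhythmic-increasing
   phenotype, as a binary logistic GLM or a multinomial GLM with the
   rhythmic-increasing level as reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort_stats import _mnlogit_newton

logger = logging.getLogger(__name__)

GREY = "grey"


@dataclass
class NetworkConfig:
    beta: int | None = None  # None -> pick by scale-free fit
    candidate_betas: tuple[int, ...] = tuple(range(1, 21))
    target_r2: float = 0.80
    min_module_size: int = 10
    merge_threshold: float = 0.30
    merge_use_abs: bool = True
    cut_method: str = "hybrid"  # or "static"
    cut_height_frac: float = 0.92

    def __post_init__(self) -> None:
        if self.beta is not None and (self.beta < 1 or int(self.beta) != self.beta):
            raise ValueError("beta must be an integer >= 1")
        if not 0 < self.merge_threshold < 1:
            raise ValueError("merge_threshold must be in (0, 1)")


@dataclass
class ModuleSet:
    """Module membership, eigengenes and (optional) trait associations."""

    labels: pd.Series  # transcript -> module name ('grey' = unassigned)
    eigengenes: pd.DataFrame  # samples x modules, unit norm
    var_explained: pd.Series
    beta: int | None = None
    trait: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _cor_rows(values: pd.DataFrame) -> np.ndarray:
    v = values.to_numpy(float)
    sd = v.std(axis=1)
    if np.any(sd == 0):
        bad = list(values.index[sd == 0])
        raise ValueError(f"constant transcripts (zero variance): {bad[:10]}")
    r = np.corrcoef(v)
    return np.clip(r, -1.0, 1.0)


def signed_adjacency(values: pd.DataFrame, beta: int) -> np.ndarray:
    """Signed adjacency ((1 + r)/2)^beta with unit diagonal."""
    a = ((1.0 + _cor_rows(values)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10 p(k) ~ log10 k regression over degree bins.

    Positive when the degree distribution decays (negative slope), the
    scale-free signature; follows the usual discretized connectivity fit.
    """
    k = k[k > 0]
    if len(k) < n_bins or k.max() == k.min():
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    centers, freq = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() > 0:
            centers.append(np.mean(k[sel]))
            freq.append(sel.mean())
    x = np.log10(np.array(centers))
    y = np.log10(np.array(freq) + 1e-12)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return 0.0
    slope, _, r, _, _ = stats.linregress(x, y)
    if not np.isfinite(r):
        return 0.0
    return float(-np.sign(slope) * r**2)


def pick_soft_threshold(
    values: pd.DataFrame,
    candidate_betas: tuple[int, ...] = tuple(range(1, 21)),
    target_r2: float = 0.80,
    min_mean_k: float = 2.0,
) -> tuple[int, pd.DataFrame]:
    """Choose beta: smallest candidate reaching the scale-free fit target.

    Returns the chosen power and the per-candidate fit table (signed R^2 and
    mean connectivity).  Candidates whose network is degenerately sparse
    (mean connectivity below ``min_mean_k``) are not eligible: at high powers
    the handful of surviving edges can produce a spuriously good log-log fit.
    When no eligible candidate reaches the target, the best-fitting eligible
    candidate is used.
    """
    r = _cor_rows(values)
    s = (1.0 + r) / 2.0
    np.fill_diagonal(s, 0.0)
    rows = []
    for b in candidate_betas:
        k = (s**b).sum(axis=1)
        rows.append({"beta": b, "signed_r2": scale_free_fit(k), "mean_k": float(k.mean())})
    tab = pd.DataFrame(rows)
    eligible = tab[tab["mean_k"] >= min_mean_k]
    if not len(eligible):
        eligible = tab
    ok = eligible[eligible["signed_r2"] >= target_r2]
    if len(ok):
        beta = int(ok["beta"].iloc[0])
    else:
        beta = int(eligible.loc[eligible["signed_r2"].idxmax(), "beta"])
    return beta, tab


def tom(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Topological overlap matrix and its dissimilarity 1 - TOM.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k the connectivity (row sum minus the
    diagonal); TOM_ii = 1.
    """
    a = np.asarray(adjacency, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    l = a @ a - a * np.diag(a)[None, :] - np.diag(a)[:, None] * a
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return t, 1.0 - t


def _static_labels(Z: np.ndarray, n: int, height: float, min_size: int) -> np.ndarray:
    raw = fcluster(Z, t=height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    nxt = 1
    for c in np.unique(raw):
        idx = np.flatnonzero(raw == c)
        if len(idx) >= min_size:
            labels[idx] = nxt
            nxt += 1
    return labels


def detect_modules(
    dissimilarity: np.ndarray,
    min_size: int = 10,
    method: str = "hybrid",
    cut_height_frac: float = 0.92,
    coherence_frac: float = 0.90,
    reassign_frac: float = 0.10,
) -> np.ndarray:
    """Cluster 1 - TOM by average linkage and cut the tree into modules.

    The dendrogram is severed at ``cut_height_frac`` of the root merge height;
    clusters with at least ``min_size`` leaves become candidate modules.
    method='hybrid' (default, a simplified adaptive branch cut) additionally
    (a) requires a candidate's core to be coherent - mean pairwise
    dissimilarity below ``coherence_frac`` of the cut height - so that loose
    aggregates of unconnected transcripts are not called modules, and
    (b) reassigns each unassigned transcript to the nearest module when its
    mean dissimilarity to that module is within the module's own scatter plus
    ``reassign_frac`` of the remaining gap to the cut height.
    method='static' applies the plain height cut with the min-size rule only.

    Returns integer labels, 0 = unassigned ('grey').  Oversplit fragments of
    one true module are recombined downstream by eigengene merging.
    """
    d = np.asarray(dissimilarity, float)
    n = d.shape[0]
    if n < min_size:
        logger.warning(
            "fewer transcripts (%d) than min module size (%d): all unassigned", n, min_size
        )
        return np.zeros(n, dtype=int)
    Z = linkage(squareform(d, checks=False), method="average")
    height = float(cut_height_frac * Z[-1, 2])
    labels = _static_labels(Z, n, height, min_size)
    if method == "static":
        return labels
    if method != "hybrid":
        raise ValueError(f"unknown cut method {method!r}")

    def _scatter(idx: np.ndarray) -> float:
        sub = d[np.ix_(idx, idx)]
        return float(sub[np.triu_indices(len(idx), 1)].mean())

    relabeled = np.zeros(n, dtype=int)
    nxt = 1
    scatter: dict[int, float] = {}
    for mlab in np.unique(labels):
        if mlab == 0:
            continue
        idx = np.flatnonzero(labels == mlab)
        s = _scatter(idx)
        if s <= coherence_frac * height:
            relabeled[idx] = nxt
            scatter[nxt] = s
            nxt += 1
    labels = relabeled
    mods = [m for m in np.unique(labels) if m != 0]
    if not mods:
        return labels
    for i in np.flatnonzero(labels == 0):
        dists = {mlab: float(d[i, labels == mlab].mean()) for mlab in mods}
        best = min(dists, key=dists.get)
        radius = scatter[best] + reassign_frac * max(height - scatter[best], 0.0)
        if dists[best] <= radius:
            labels[i] = best
    return labels


def eigengenes(
    values: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First-PC eigengene per module, sign-anchored, unit norm.

    Member profiles are z-scored across samples before the SVD; the variance
    explained is the leading singular value's share.  The eigengene sign is
    fixed so it correlates positively with the module's mean standardized
    profile.
    """
    mods = sorted(set(labels) - {GREY, 0})
    me = {}
    ve = {}
    for mlab in mods:
        members = labels.index[labels == mlab]
        sub = values.loc[members].to_numpy(float)
        if sub.shape[0] < 2:
            raise ValueError(f"module {mlab} has fewer than 2 transcripts")
        z = (sub - sub.mean(axis=1, keepdims=True))
        sd = sub.std(axis=1, keepdims=True)
        z = z / np.where(sd == 0, 1.0, sd)
        U, s, Vt = np.linalg.svd(z, full_matrices=False)
        v = Vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(v, mean_profile) < 0:
            v = -v
        me[str(mlab)] = v / np.linalg.norm(v)
        ve[str(mlab)] = float(s[0] ** 2 / np.sum(s**2))
    me_df = pd.DataFrame(me, index=values.columns)
    return me_df, pd.Series(ve, name="var_explained")


def merge_modules(
    values: pd.DataFrame,
    labels: pd.Series,
    threshold: float = 0.30,
    use_abs: bool = True,
) -> ModuleSet:
    """Iteratively merge the most-correlated eigengene pair above threshold.

    After each merge the combined module's eigengene is recomputed;
    iteration stops when every pairwise eigengene correlation is below the
    threshold or a single module remains.
    """
    labels = labels.copy().astype(object)
    while True:
        me, ve = eigengenes(values, labels)
        mods = list(me.columns)
        if len(mods) < 2:
            break
        c = np.corrcoef(me.to_numpy().T)
        c = np.abs(c) if use_abs else c
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] < threshold:
            break
        keep, absorb = mods[i], mods[j]
        labels[labels.astype(str) == absorb] = keep
    me, ve = eigengenes(values, labels)
    return ModuleSet(labels, me, ve)


def module_trait(
    eigengene_df: pd.DataFrame,
    phenotype: pd.Series,
    mode: str = "binary",
    reference: str = "rhythmic_up",
) -> pd.DataFrame:
    """Associate each module eigengene with the rhythmic-increasing phenotype.

    binary: logistic GLM of (phenotype == reference) on the eigengene;
    multinomial: baseline-category GLM with the reference level first, one
    row per non-reference contrast.  Constant eigengenes are flagged and not
    fitted.
    """
    ph = phenotype.loc[eigengene_df.index].astype(str)
    if ph.nunique() < 2:
        raise ValueError("phenotype has a single level")
    rows = []
    for mod in eigengene_df.columns:
        x = eigengene_df[mod].to_numpy(float)
        if np.std(x) == 0:
            rows.append({"module": mod, "contrast": "any", "beta": np.nan, "p": np.nan, "constant": True})
            continue
        X = np.column_stack([np.ones(len(x)), (x - x.mean()) / x.std()])
        if mode == "binary":
            y = (ph == reference).to_numpy(float)
            Y = np.column_stack([1 - y, y])
            B, cov, sep, _ = _mnlogit_newton(X, Y)
            se = np.sqrt(max(cov[1, 1], 0.0))
            z = B[1, 0] / se if se > 0 else np.nan
            rows.append(
                {
                    "module": mod,
                    "contrast": f"{reference}_vs_rest",
                    "beta": float(B[1, 0]),
                    "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                    "constant": False,
                    "separated": sep,
                }
            )
        elif mode == "multinomial":
            levels = [reference] + sorted(set(ph) - {reference})
            Y = np.column_stack([(ph == lev).to_numpy(float) for lev in levels])
            B, cov, sep, _ = _mnlogit_newton(X, Y)
            p_dim = X.shape[1]
            for k, lev in enumerate(levels[1:]):
                se = np.sqrt(max(cov[k * p_dim + 1, k * p_dim + 1], 0.0))
                z = B[1, k] / se if se > 0 else np.nan
                rows.append(
                    {
                        "module": mod,
                        "contrast": f"{lev}_vs_{reference}",
                        "beta": float(B[1, k]),
                        "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                        "constant": False,
                        "separated": sep,
                    }
                )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)


def build_network_modules(values: pd.DataFrame, config: NetworkConfig | None = None) -> ModuleSet:
    """End-to-end: adjacency -> TOM -> tree cut -> eigengenes -> merging."""
    config = config or NetworkConfig()
    if config.beta is None:
        beta, fit_tab = pick_soft_threshold(values, config.candidate_betas, config.target_r2)
    else:
        beta, fit_tab = int(config.beta), None
    a = signed_adjacency(values, beta)
    _, diss = tom(a)
    raw = detect_modules(diss, config.min_module_size, config.cut_method, config.cut_height_frac)
    labels = pd.Series(
        [f"M{int(v)}" if v != 0 else GREY for v in raw], index=values.index, name="module"
    )
    assigned = labels[labels != GREY]
    if assigned.empty:
        return ModuleSet(labels, pd.DataFrame(index=values.columns), pd.Series(dtype=float), beta)
    ms = merge_modules(values.loc[assigned.index], assigned, config.merge_threshold, config.merge_use_abs)
    full = pd.Series(GREY, index=values.index, name="module", dtype=object)
    full.loc[ms.labels.index] = ms.labels
    return ModuleSet(full, ms.eigengenes, ms.var_explained, beta, meta={"fit_table": fit_tab})
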