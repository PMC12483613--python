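"""Gene-set analysis: over-representation and running-sum enrichment.

Two flavors are used downstream of the differential-expression and network
stages:

* ORA — hypergeometric over-representation of a query gene list (DETs or a
  module's members) against named sets, with term-size filtering (10-500
  after intersection with the background) and Benjamini-Hochberg adjustment.
* GSEA — the classic weighted Kolmogorov-Smirnov running sum over a ranked
  gene list (e.g. genes ordered by the opioid x time interaction statistic),
  with a seeded gene-permutation null; when the number of possible set
  placements is small the null is enumerated exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class GmtError(ValueError):
    """Malformed GMT line (reports the 1-based line number)."""


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: member list}.

    Each line is name <TAB> description <TAB> member1 <TAB> member2 ...
    Duplicated members within a set are dropped (order-preserving, logged);
    lines with no members or duplicate set names raise.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtError(f"line {lineno}: expected name, description and >=1 member")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise GmtError(f"line {lineno}: set {name!r} has no members")
            if name in sets:
                raise GmtError(f"line {lineno}: duplicate set name {name!r}")
            seen: dict[str, None] = {}
            for m in members:
                if m in seen:
                    logger.info("GMT set %s: duplicate member %s dropped", name, m)
                seen[m] = None
            sets[name] = list(seen)
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, descriptions.get(name, "na"), *members]) + "\n")


def ora(
    query: list[str],
    sets: dict[str, list[str]],
    background: list[str],
    min_size: int = 10,
    max_size: int = 500,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list against gene sets.

    Sets are intersected with the background and filtered to
    [min_size, max_size]; the upper-tail hypergeometric p is
    P(overlap >= observed) drawing |query| genes from the background.
    Adjusted p-values are Benjamini-Hochberg; ``significant`` applies the
    adjusted-p < alpha cut.
    """
    bg = set(background)
    q = set(query)
    stray = sorted(q - bg)
    if stray:
        raise ValueError(f"query genes not in background: {stray[:10]}")
    N, n = len(bg), len(q)
    rows = []
    for name, members in sets.items():
        inset = set(members) & bg
        K = len(inset)
        if K < min_size or K > max_size:
            continue
        k = len(inset & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "size": K, "overlap": k, "p": p})
    tab = pd.DataFrame(rows)
    if tab.empty:
        return tab
    tab = tab.sort_values("p", kind="stable").reset_index(drop=True)
    m = len(tab)
    ranked = tab["p"].to_numpy() * m / np.arange(1, m + 1)
    tab["p_adj"] = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    tab["significant"] = tab["p_adj"] < alpha
    return tab


def enrichment_score(
    stats_ranked: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0
) -> tuple[float, int, np.ndarray]:
    """Running-sum enrichment score for one set on a ranked list.

    ``stats_ranked`` is the ranking statistic in descending order and
    ``hit_mask`` marks set members at those positions.  Hits advance the sum
    by |stat|^weight (normalized), misses retreat uniformly; the ES is the
    running sum's most extreme excursion (the positive extremum wins an exact
    magnitude tie).  Returns (es, extremum index, running sum).
    """
    n = len(stats_ranked)
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValueError("set must be a proper non-empty subset of the ranking")
    w = np.abs(stats_ranked) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hit_mask.astype(float)
        denom = float(nh)
    steps = hit_w / denom - (~hit_mask) / float(n - nh)
    run = np.cumsum(steps)
    i_max, i_min = int(np.argmax(run)), int(np.argmin(run))
    # positive extremum wins ties (to accumulation-order tolerance)
    if abs(run[i_max]) >= abs(run[i_min]) - 1e-12:
        return float(run[i_max]), i_max, run
    return float(run[i_min]), i_min, run


@dataclass
class GseaResult:
    set_name: str
    size: int
    es: float
    nes: float
    p: float
    n_perm: int
    exact: bool
    leading_edge: list[str]


def gsea(
    ranking: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 10_000,
    seed: int | None = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Ranked-list running-sum enrichment with a gene-permutation null.

    ``ranking`` maps unique gene ids to the ranking statistic (most positive
    = top).  For each set (intersected with the ranking; intersections < 2
    are skipped with a log entry) the ES null is built by redrawing the set's
    positions uniformly: exact enumeration over all C(n, k) placements when
    that count is at most ``n_perm``, otherwise ``n_perm`` seeded draws.  The
    p-value is one-sided on the observed ES's sign; NES divides by the mean
    |ES| of same-sign null scores.  The leading edge contains the hits at or
    before (after, for negative ES) the running-sum extremum.
    """
    if ranking.index.duplicated().any():
        raise ValueError("ranking gene ids must be unique")
    order = ranking.sort_values(ascending=False, kind="stable")
    genes = order.index.to_numpy()
    vals = order.to_numpy(float)
    n = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sets.items():
        idx = sorted(pos[g] for g in set(members) if g in pos)
        k = len(idx)
        if k < 2:
            logger.info("set %s: intersection with ranking < 2, skipped", name)
            continue
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es, ext, _run = enrichment_score(vals, mask, weight)
        total = math.comb(n, k)
        exact = total <= n_perm
        if exact:
            null = np.empty(total)
            for j, combo in enumerate(combinations(range(n), k)):
                mm = np.zeros(n, dtype=bool)
                mm[list(combo)] = True
                null[j] = enrichment_score(vals, mm, weight)[0]
            if es >= 0:
                p = float(np.mean(null >= es - 1e-12))
            else:
                p = float(np.mean(null <= es + 1e-12))
            nperm_used = total
        else:
            null = np.empty(n_perm)
            for j in range(n_perm):
                mm = np.zeros(n, dtype=bool)
                mm[rng.choice(n, size=k, replace=False)] = True
                null[j] = enrichment_score(vals, mm, weight)[0]
            if es >= 0:
                p = float((1 + np.sum(null >= es - 1e-12)) / (1 + n_perm))
            else:
                p = float((1 + np.sum(null <= es + 1e-12)) / (1 + n_perm))
            nperm_used = n_perm
        same_sign = null[null >= 0] if es >= 0 else -null[null < 0]
        nes = float(es / np.mean(same_sign)) if len(same_sign) and np.mean(same_sign) > 0 else np.nan
        if es >= 0:
            le = [genes[i] for i in idx if i <= ext]
        else:
            le = [genes[i] for i in idx if i >= ext]
        rows.append(
            GseaResult(name, k, es, nes, p, nperm_used, exact, le).__dict__
        )
    return pd.DataFrame(rows)
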