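"""Group-level cohort statistics.

Covers the comparisons used to contrast the pain phenotypes: multinomial
logistic regression odds ratios against the rhythmic-increasing reference
(with explicit quasi-complete-separation handling), Fisher's exact test
including the Freeman-Halton r x c extension, Kruskal-Wallis and one-way
ANOVA + Tukey HSD group comparisons, Spearman correlation, day->night percent
change of blood-cell counts, and 2^-ddCt qPCR fold changes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: |beta| beyond which a multinomial/logistic coefficient is treated as
#: diverging (quasi-complete separation); e^15 ~ 3.3e6 on the OR scale.
BETA_GUARD = 15.0
MAX_ITER = 100


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient; names the collinear columns."""


# ---------------------------------------------------------------------------
# multinomial logistic regression
# ---------------------------------------------------------------------------

def _softmax_baseline(eta: np.ndarray) -> np.ndarray:
    """Class probabilities for baseline-category logits (reference first)."""
    z = np.hstack([np.zeros((eta.shape[0], 1)), eta])
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _mnlogit_loglik(B: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    P = _softmax_baseline(X @ B)
    return float(np.sum(Y * np.log(np.clip(P, 1e-300, None))))


def _mnlogit_newton(
    X: np.ndarray,
    Y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = MAX_ITER,
    tol: float = 1e-10,
    beta_guard: float = BETA_GUARD,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Newton-Raphson for the baseline-category multinomial logit.

    Returns (B, cov, separated, n_iter).  B is (p, K-1) with the reference
    class first in Y.  Iteration stops when the log-likelihood improvement is
    below tol, the iteration cap is hit, or a coefficient crosses the
    divergence guard (quasi-complete separation); in the latter case the
    separated flag is set and the guarded coefficients are reported as-is.
    """
    n, p = X.shape
    K = Y.shape[1]
    B = np.zeros((p, K - 1))
    ll = _mnlogit_loglik(B, X, Y)
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        P = _softmax_baseline(X @ B)
        G = X.T @ (Y[:, 1:] - P[:, 1:]) - ridge * B  # (p, K-1)
        # block Hessian over (K-1) classes
        H = np.zeros((p * (K - 1), p * (K - 1)))
        for a in range(K - 1):
            for b in range(K - 1):
                w = P[:, a + 1] * ((1.0 if a == b else 0.0) - P[:, b + 1])
                H[a * p:(a + 1) * p, b * p:(b + 1) * p] = -(X.T * w) @ X
        H -= ridge * np.eye(p * (K - 1))
        try:
            step = np.linalg.solve(H, -G.T.reshape(-1))
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(f"singular Hessian in multinomial fit: {exc}") from exc
        B_new = B + step.reshape(K - 1, p).T
        # step-halving keeps the log-likelihood monotone
        ll_new = _mnlogit_loglik(B_new, X, Y) - 0.5 * ridge * np.sum(B_new**2)
        shrink = 0
        while ll_new < ll - 1e-12 and shrink < 30:
            step *= 0.5
            B_new = B + step.reshape(K - 1, p).T
            ll_new = _mnlogit_loglik(B_new, X, Y) - 0.5 * ridge * np.sum(B_new**2)
            shrink += 1
        B = B_new
        if np.max(np.abs(B)) > beta_guard:
            separated = True
            break
        if ll_new - ll < tol * (abs(ll) + 1.0):
            ll = ll_new
            break
        ll = ll_new
    P = _softmax_baseline(X @ B)
    H = np.zeros((p * (K - 1), p * (K - 1)))
    for a in range(K - 1):
        for b in range(K - 1):
            w = P[:, a + 1] * ((1.0 if a == b else 0.0) - P[:, b + 1])
            H[a * p:(a + 1) * p, b * p:(b + 1) * p] = (X.T * w) @ X
    H += ridge * np.eye(p * (K - 1))
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full_like(H, np.nan)
    return B, cov, separated, it


def build_design(
    table: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate design matrix; binaries/categoricals dummy-coded."""
    cols: list[np.ndarray] = [np.ones(len(table))]
    names = ["intercept"]
    for c in covariates:
        v = table[c]
        if v.dtype == bool or v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(v.astype(str)))
            for lev in levels[1:]:
                cols.append((v.astype(str) == lev).to_numpy(float))
                names.append(f"{c}[{lev}]")
        else:
            cols.append(v.to_numpy(float))
            names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad, kept = [], [X[:, [0]]]
        for j in range(1, X.shape[1]):
            cand = np.column_stack(kept + [X[:, j]])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                kept.append(X[:, [j]])
            else:
                bad.append(names[j])
        raise SingularDesignError(f"collinear design columns: {bad}")
    return X, names


def fit_multinomial_or(
    table: pd.DataFrame,
    covariates: list[str],
    reference: str = "rhythmic_up",
    phenotype_col: str = "phenotype",
    beta_guard: float = BETA_GUARD,
    ridge: float = 0.0,
) -> pd.DataFrame:
    """Multinomial logistic regression ORs versus a reference phenotype.

    Fits one joint baseline-category model of phenotype on the listed
    covariates and reports, per (phenotype contrast x covariate), the log
    odds beta, OR = e^beta, Wald 95 % CI = e^(beta +/- 1.96 se), p-value, and a
    separation flag.  When a covariate pattern perfectly predicts membership
    (e.g. an exposure absent from the reference class) the fitted coefficient
    diverges; iteration is stopped at the divergence guard and the OR reported
    at the guarded coefficient with ``separated=True`` - the estimate is then
    a bounded sentinel, not a finite MLE.  ``ridge > 0`` enables a small L2
    penalty as an optional stabilised fit.
    """
    pheno = table[phenotype_col].astype(str)
    levels = [reference] + sorted(set(pheno) - {reference})
    if reference not in set(pheno):
        raise ValueError(f"reference level {reference!r} absent")
    if len(levels) < 2:
        raise ValueError("need >=2 phenotype levels")
    Y = np.column_stack([(pheno == lev).to_numpy(float) for lev in levels])
    if len(table) <= len(covariates) + 1:
        raise ValueError("more covariates than observations per level")
    X, names = build_design(table, covariates)
    B, cov, separated, _ = _mnlogit_newton(X, Y, ridge=ridge, beta_guard=beta_guard)
    p = X.shape[1]
    rows = []
    for k, lev in enumerate(levels[1:]):
        for j, name in enumerate(names):
            beta = B[j, k]
            se = math.sqrt(max(cov[k * p + j, k * p + j], 0.0)) if np.isfinite(
                cov[k * p + j, k * p + j]
            ) else np.nan
            flagged = separated and abs(beta) > beta_guard * 0.99
            z = beta / se if se and se > 0 else np.nan
            with np.errstate(over="ignore"):
                rows.append(
                {
                    "contrast": f"{lev}_vs_{reference}",
                    "covariate": name,
                    "beta": beta,
                    "se": se,
                    "or": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - 1.96 * se)) if np.isfinite(se) else np.nan,
                    "ci_high": float(np.exp(beta + 1.96 * se)) if np.isfinite(se) else np.nan,
                    "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                    "separated": bool(flagged),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact contingency tests
# ---------------------------------------------------------------------------

def _log_table_prob(t: np.ndarray, lr: np.ndarray, lc: np.ndarray, ln: float) -> float:
    """log P(table | margins) under the hypergeometric (fixed-margins) model."""
    return float(lr.sum() + lc.sum() - ln - gammaln(t + 1).sum())


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(i, remaining_cols, rows):
        if i == r - 1:
            last = np.asarray(remaining_cols)
            if (last >= 0).all():
                yield rows + [last]
            return
        target = row_sums[i]

        def fill(j, left, row):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from fill(j + 1, left - v, row + [v])

        for row in fill(0, target, []):
            rem = [remaining_cols[j] - row[j] for j in range(c)]
            yield from rec(i + 1, rem, rows + [np.asarray(row)])

    yield from rec(0, list(col_sums), [])


def _enumeration_size(row_sums, col_sums) -> float:
    """Cheap upper bound on the number of margin-preserving tables."""
    c = len(col_sums)
    out = 1.0
    for rs in row_sums[:-1]:
        out *= (min(rs, max(col_sums)) + 1) ** (c - 1)
    return out


def fisher_exact(
    table: np.ndarray | list,
    max_tables: float = 2e6,
    n_mc: int = 100_000,
    seed: int | None = 0,
) -> float:
    """Two-sided Fisher exact p for an r x c table of non-negative counts.

    2 x 2 tables use the standard hypergeometric rule (probability of tables
    at most as likely as the observed one).  Larger tables use the
    Freeman-Halton extension: full enumeration over all tables with the
    observed margins when that enumeration is affordable, otherwise a seeded
    Monte-Carlo estimate drawing tables from the fixed-margins null
    (Patefield sampling).
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    if t.shape == (2, 2):
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    lr = gammaln(row_sums + 1)
    lc = gammaln(col_sums + 1)
    ln = gammaln(t.sum() + 1)
    lp_obs = _log_table_prob(t, lr, lc, ln)
    tol = 1e-7 * abs(lp_obs) + 1e-12
    if _enumeration_size(row_sums, col_sums) <= max_tables:
        p = 0.0
        for cand in _enumerate_tables(list(row_sums), list(col_sums)):
            lp = _log_table_prob(np.vstack(cand), lr, lc, ln)
            if lp <= lp_obs + tol:
                p += math.exp(lp)
        return float(min(p, 1.0))
    rng = np.random.default_rng(seed)
    rt = stats.random_table(row_sums, col_sums)
    draws = rt.rvs(n_mc, method="patefield", random_state=rng)
    lps = np.array([_log_table_prob(d, lr, lc, ln) for d in draws])
    return float((1 + np.sum(lps <= lp_obs + tol)) / (1 + n_mc))


# ---------------------------------------------------------------------------
# group comparisons, correlation, small formulas
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    statistic: float
    p: float
    pairwise: pd.DataFrame | None = None


def group_compare(groups: dict[str, np.ndarray], mode: str = "kruskal") -> GroupComparison:
    """Compare a continuous variable across phenotype groups.

    mode='kruskal': tie-corrected Kruskal-Wallis H with chi-square p.
    mode='anova_tukey': ordinary one-way ANOVA F plus Tukey HSD pairwise
    adjusted p-values (studentized range on the pooled variance).
    """
    empty = [k for k, v in groups.items() if len(np.atleast_1d(v)) == 0]
    if empty:
        raise ValueError(f"empty groups: {empty}")
    names = sorted(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    if len(data) < 2:
        raise ValueError("need >=2 groups")
    if mode == "kruskal":
        flat = np.concatenate(data)
        if np.all(flat == flat[0]):
            return GroupComparison(0.0, 1.0)
        h, p = stats.kruskal(*data)
        return GroupComparison(float(h), float(p))
    if mode == "anova_tukey":
        if any(len(d) < 2 for d in data):
            raise ValueError("anova needs >=2 values per group")
        f, p = stats.f_oneway(*data)
        res = stats.tukey_hsd(*data)
        rows = []
        for i, j in itertools.combinations(range(len(data)), 2):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "diff": float(np.mean(data[i]) - np.mean(data[j])),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
        return GroupComparison(float(f), float(p), pd.DataFrame(rows))
    raise ValueError(f"unknown mode {mode!r}")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with t-approx p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def pct_change(day_value: float, night_value: float) -> float:
    """Day -> night percent change, 100 * (night - day) / day."""
    if day_value == 0:
        raise ZeroDivisionError("percent change undefined for day value 0")
    return 100.0 * (night_value - day_value) / day_value


def ddct_fold_change(
    ct_target_cond: float, ct_ref_cond: float, ct_target_ctrl: float, ct_ref_ctrl: float
) -> float:
    """Relative qPCR quantification 2^-ddCt as a fold change."""
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
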