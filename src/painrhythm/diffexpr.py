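"""Negative-binomial GLM differential expression and replication models.

Per-transcript counts are modelled as NB(mu, alpha) with Var = mu + alpha*mu^2
and a log link, log mu = offset + X beta, where the offset is the log
TMM-effective library size and X carries the study covariates (sequencing
batch, sex, day/night time point, phenotype, ...).  Per-gene dispersions are
estimated by maximizing the Cox-Reid adjusted profile likelihood, with a
common-dispersion fallback for genes whose estimate fails.  Contrasts are
tested by likelihood-ratio tests with Bonferroni control over the tested
transcript family (the whole matrix, or a candidate gene-set subset).

The replication-cohort analysis regresses two-visit expression on
``age + sex + RIN + smoker + resolved + time + opioids + time:opioids`` and
ranks genes by the Wald statistic of the interaction term; a positive sign
means expression in opioid users lingered or rose over time relative to
nonusers.  A plain logistic model provides the opioid -> chronicity odds
ratio with OR = e^beta and CI = e^(beta +/- 1.96 se).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .cohort_stats import BETA_GUARD, SingularDesignError
from .preprocess import ExprMatrix

logger = logging.getLogger(__name__)

_MIN_ALPHA = 1e-8
_MAX_ALPHA = 50.0


@dataclass
class DesignSpec:
    """Model terms for per-transcript regression.

    ``terms`` are sample-sheet column names; categorical / boolean columns are
    dummy-coded against their first (sorted) level, numeric columns enter
    as-is.  ``interaction`` multiplies the coded columns of two terms (both
    main effects must be listed).  ``contrast`` names the term whose coded
    columns are dropped for the likelihood-ratio test.
    """

    terms: list[str]
    contrast: str
    interaction: tuple[str, str] | None = None
    contrast_level: str | None = None  # restrict LRT to one coded level

    def __post_init__(self) -> None:
        if self.interaction is not None:
            a, b = self.interaction
            if a not in self.terms or b not in self.terms:
                raise ValueError("interaction requires both main effects in terms")


def build_design_matrix(samples: pd.DataFrame, spec: DesignSpec) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix for a DesignSpec; returns (X, contrast column names)."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    coded: dict[str, list[str]] = {}
    for t in spec.terms:
        v = samples[t]
        if v.dtype == bool or v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(v.astype(str)))
            names = []
            for lev in levels[1:]:
                nm = f"{t}[{lev}]"
                cols[nm] = (v.astype(str) == lev).to_numpy(float)
                names.append(nm)
            coded[t] = names
        else:
            cols[t] = v.to_numpy(float)
            coded[t] = [t]
    if spec.interaction is not None:
        a, b = spec.interaction
        inter_names = []
        for na in coded[a]:
            for nb in coded[b]:
                nm = f"{na}:{nb}"
                cols[nm] = cols[na] * cols[nb]
                inter_names.append(nm)
        coded[f"{a}:{b}"] = inter_names
        contrast_key = f"{a}:{b}" if spec.contrast == f"{a}:{b}" else spec.contrast
    X = pd.DataFrame(cols, index=samples.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = []
        kept = [X.iloc[:, [0]].to_numpy()]
        for j in range(1, X.shape[1]):
            cand = np.column_stack(kept + [X.iloc[:, j].to_numpy()])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                kept.append(X.iloc[:, [j]].to_numpy())
            else:
                bad.append(X.columns[j])
        raise SingularDesignError(f"design not full rank; collinear columns: {bad}")
    contrast_cols = coded.get(spec.contrast, [spec.contrast])
    if spec.contrast_level is not None:
        want = f"{spec.contrast}[{spec.contrast_level}]"
        contrast_cols = [c for c in contrast_cols if c == want]
        if not contrast_cols:
            raise ValueError(f"unknown contrast level {spec.contrast_level!r}")
    return X, contrast_cols


# ---------------------------------------------------------------------------
# NB GLM internals
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha < _MIN_ALPHA:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv)
            - gammaln(inv)
            - gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _nb_irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """IRLS for a log-link NB GLM with known dispersion.

    Returns (beta, mu, XtWX, converged).  The working response update is the
    standard Fisher-scoring step; convergence is relative change of the
    log-likelihood below tol.
    """
    n, p = X.shape
    beta = np.zeros(p)
    # start from a saturated-ish intercept
    beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
    eta = offset + X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    ll = _nb_loglik(y, mu, alpha)
    converged = False
    XtWX = np.eye(p)
    for _ in range(max_iter):
        W = mu / (1.0 + alpha * mu)  # mu^2 / Var
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        XtWX = XtW @ X
        try:
            beta_new = np.linalg.solve(XtWX, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, mu, XtWX, False
        step = beta_new - beta
        for _half in range(20):
            cand = beta + step
            eta_c = offset + X @ cand
            mu_c = np.exp(np.clip(eta_c, -30, 30))
            ll_c = _nb_loglik(y, mu_c, alpha)
            if np.isfinite(ll_c) and ll_c >= ll - 1e-10:
                break
            step = step / 2.0
        beta, eta, mu = cand, eta_c, mu_c
        if abs(ll_c - ll) < tol * (abs(ll) + 1.0):
            ll = ll_c
            converged = True
            break
        ll = ll_c
    W = mu / (1.0 + alpha * mu)
    XtWX = (X.T * W) @ X
    return beta, mu, XtWX, converged


def _apl(y, X, offset, alpha) -> float:
    """Cox-Reid adjusted profile log-likelihood at a given dispersion."""
    beta, mu, XtWX, _ = _nb_irls(y, X, offset, alpha)
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return _nb_loglik(y, mu, alpha) - 0.5 * logdet


def estimate_dispersion(y, X, offset) -> float | None:
    """Per-gene dispersion by maximizing the adjusted profile likelihood.

    Optimizes over log10(alpha) in [-8, log10(50)] with a bounded scalar
    search; returns None when the search fails or the data are degenerate
    (all-zero gene).
    """
    if np.all(y == y[0]):
        return None
    try:
        res = optimize.minimize_scalar(
            lambda la: -_apl(y, X, offset, 10.0**la),
            bounds=(np.log10(_MIN_ALPHA), np.log10(_MAX_ALPHA)),
            method="bounded",
            options={"xatol": 0.01, "maxiter": 40},
        )
    except (np.linalg.LinAlgError, FloatingPointError):
        return None
    if not np.isfinite(res.fun):
        return None
    return float(10.0**res.x)


@dataclass
class GeneFit:
    gene: str
    beta: pd.Series
    se: pd.Series
    alpha: float
    loglik: float
    converged: bool


@dataclass
class FitResult:
    """Per-transcript NB GLM fits plus everything needed for contrasts."""

    fits: dict[str, GeneFit]
    X: pd.DataFrame
    contrast_cols: list[str]
    offset: np.ndarray
    counts: pd.DataFrame
    dropped: list[str] = field(default_factory=list)
    common_dispersion: float = 0.0


def fit_nb_glm(
    m: ExprMatrix,
    spec: DesignSpec,
    dispersion: float | None = None,
) -> FitResult:
    """Fit the NB GLM to every transcript of a count matrix.

    Offsets are log TMM-effective library sizes (factors of 1 when absent).
    ``dispersion`` forces a common value for every gene (useful for the
    near-Poisson limiting case); otherwise each gene's dispersion is the CR
    adjusted-profile-likelihood maximizer, with the median of successful
    estimates as fallback.  All-zero genes are dropped and reported.
    """
    X, contrast_cols = build_design_matrix(m.samples, spec)
    Xv = X.to_numpy(float)
    offset = np.log(m.effective_lib_sizes().to_numpy(float))
    counts = m.values
    dropped = [g for g in counts.index if counts.loc[g].sum() == 0]
    if dropped:
        logger.info("dropping %d all-zero transcripts", len(dropped))
    kept = counts.drop(index=dropped)

    alphas: dict[str, float | None] = {}
    if dispersion is not None:
        for g in kept.index:
            alphas[g] = dispersion
        common = dispersion
    else:
        for g in kept.index:
            alphas[g] = estimate_dispersion(kept.loc[g].to_numpy(float), Xv, offset)
        ok = [a for a in alphas.values() if a is not None]
        common = float(np.median(ok)) if ok else 0.1
        for g, a in alphas.items():
            if a is None:
                alphas[g] = common

    fits: dict[str, GeneFit] = {}
    for g in kept.index:
        y = kept.loc[g].to_numpy(float)
        a = alphas[g]
        beta, mu, XtWX, conv = _nb_irls(y, Xv, offset, a)
        try:
            cov = np.linalg.inv(XtWX)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(Xv.shape[1], np.nan)
        fits[g] = GeneFit(
            g,
            pd.Series(beta, index=X.columns),
            pd.Series(se, index=X.columns),
            a,
            _nb_loglik(y, mu, a),
            conv,
        )
    return FitResult(fits, X, contrast_cols, offset, kept, dropped, common)


def _lrt_table(fr: FitResult) -> pd.DataFrame:
    """Likelihood-ratio test of the contrast columns, gene by gene."""
    Xfull = fr.X.to_numpy(float)
    keep_cols = [c for c in fr.X.columns if c not in fr.contrast_cols]
    Xred = fr.X[keep_cols].to_numpy(float)
    df = len(fr.contrast_cols)
    rows = []
    for g, fit in fr.fits.items():
        y = fr.counts.loc[g].to_numpy(float)
        _, mu_r, _, _ = _nb_irls(y, Xred, fr.offset, fit.alpha)
        ll_r = _nb_loglik(y, mu_r, fit.alpha)
        stat = max(2.0 * (fit.loglik - ll_r), 0.0)
        p = stats.chi2.sf(stat, df)
        # log2 fold change of the first contrast column
        b = fit.beta[fr.contrast_cols[0]]
        rows.append({"gene": g, "log2fc": b / np.log(2), "stat": stat, "p": p, "sign": int(np.sign(b))})
    return pd.DataFrame(rows).set_index("gene")


def contrast_de(fr: FitResult, alpha: float = 0.05) -> pd.DataFrame:
    """DE table with Bonferroni-adjusted p over all fitted transcripts.

    ``det`` marks differentially expressed transcripts (adjusted p < alpha);
    ``sign`` is the direction of the first contrast coefficient.
    """
    tab = _lrt_table(fr)
    m = len(tab)
    tab["p_bonf"] = np.minimum(tab["p"] * m, 1.0)
    tab["det"] = tab["p_bonf"] < alpha
    return tab


def candidate_de(fr: FitResult, gene_sets: dict[str, list[str]], alpha: float = 0.05) -> pd.DataFrame:
    """Candidate DE restricted to the union of gene sets.

    The Bonferroni family is the candidate subset only (its size after
    intersection with the fitted matrix).
    """
    union = sorted({g for members in gene_sets.values() for g in members})
    present = [g for g in union if g in fr.fits]
    if not present:
        missing = [g for g in union if g not in fr.fits]
        raise ValueError(f"no candidate genes present in matrix; missing: {missing[:10]}")
    tab = _lrt_table(fr).loc[present]
    tab["p_bonf"] = np.minimum(tab["p"] * len(present), 1.0)
    tab["det"] = tab["p_bonf"] < alpha
    return tab


def interaction_de(
    m: ExprMatrix,
    spec: DesignSpec | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Opioid x time interaction model for the two-visit replication cohort.

    Participants with a single visit are excluded (logged).  Returns a table
    ranked from the most positive to the most negative interaction Wald
    statistic; a positive statistic means the gene's expression trajectory in
    opioid users stayed up relative to nonusers.
    """
    if spec is None:
        spec = DesignSpec(
            terms=["age", "sex", "rin", "smoker", "resolved", "time", "opioids"],
            contrast="opioids:time",
            interaction=("opioids", "time"),
        )
    visits = m.samples.groupby("participant").size()
    incomplete = visits[visits < 2].index.tolist()
    if incomplete:
        logger.info("excluding %d single-visit participants: %s", len(incomplete), incomplete)
        keep = m.samples["participant"].isin(visits[visits >= 2].index)
        m = ExprMatrix(m.values.loc[:, keep[keep].index], m.samples.loc[keep[keep].index])
    fr = fit_nb_glm(m, spec, dispersion=dispersion)
    rows = []
    for g, fit in fr.fits.items():
        c = fr.contrast_cols[0]
        b, s = fit.beta[c], fit.se[c]
        z = b / s if s and s > 0 else np.nan
        rows.append({"gene": g, "beta_interaction": b, "stat": z, "p": 2 * stats.norm.sf(abs(z))})
    tab = pd.DataFrame(rows).set_index("gene").sort_values("stat", ascending=False)
    return tab


def logistic_or(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: list[str] | None = None,
) -> dict:
    """Logistic odds ratio of a binary outcome on a binary exposure.

    Maximum-likelihood logistic fit (via statsmodels); the OR is e^beta and
    the 95 % CI is e^(beta +/- 1.96 se).  A coefficient beyond the divergence
    guard marks separation.
    """
    import statsmodels.api as sm

    covariates = covariates or []
    y = table[outcome].astype(float)
    Xcols = {"intercept": np.ones(len(table)), exposure: table[exposure].astype(float)}
    for c in covariates:
        v = table[c]
        if v.dtype == bool or v.dtype == object:
            levels = sorted(pd.unique(v.astype(str)))
            for lev in levels[1:]:
                Xcols[f"{c}[{lev}]"] = (v.astype(str) == lev).to_numpy(float)
        else:
            Xcols[c] = v.to_numpy(float)
    X = pd.DataFrame(Xcols, index=table.index)
    fit = sm.Logit(y, X).fit(disp=False, maxiter=100)
    beta = float(fit.params[exposure])
    se = float(fit.bse[exposure])
    separated = abs(beta) > BETA_GUARD
    return {
        "beta": beta,
        "se": se,
        "or": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - 1.96 * se)),
        "ci_high": float(np.exp(beta + 1.96 * se)),
        "p": float(fit.pvalues[exposure]),
        "separated": separated,
    }
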