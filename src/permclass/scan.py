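"""Single-SNP association scan with covariate adjustment, plus LD pruning.

The baseline model is the logistic regression

    logit Pr(HTN = 1) = Smoke + Age + Sex + Age x Sex + Mother + Father + Pedigree

fitted on the stacked individual x exam rows (the three repeated measurements
per participant enter as three observations, which is what gives the two
time-varying covariates, Age and Smoke, their power).  Each SNP is then added
to the baseline as a genotype-category factor (missing ``XX`` is a level of
its own, reference = most frequent genotype) and scored by the likelihood-ratio
test of the extended against the baseline model.  SNPs are ranked by ascending
p-value; ties keep genotype-column order.

Linkage-disequilibrium pruning works on minor-allele dose (0/1/2, missing
excluded pairwise) with a greedy forward pass in column order: a SNP is kept
iff its |Pearson r| with every previously kept SNP is below the threshold;
with threshold 1 only exact duplicates (|r| = 1) are removed.

Fitting is iteratively reweighted least squares (IRLS) written on numpy:
aliased columns are dropped up front (greedy, keep-first), steps are halved whenever
a step would increase the deviance, and quasi-complete separation is flagged
when a standardized coefficient runs past a documented bound while the
deviance is still falling — the regime where adding many rare-genotype
indicators stops the fit from converging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import CovariateEncoder, genotype_indicators, ordered_levels
from .io_gaw import MISSING_TOKEN, Cohort

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "fit_baseline",
    "scan_snp",
    "rank_snps",
    "scan_cohort",
    "quantitative_scan",
    "allele_dose",
    "ld_prune",
]

logger = logging.getLogger(__name__)

#: relative deviance-change convergence tolerance for IRLS
IRLS_TOL = 1e-8
#: IRLS iteration cap
IRLS_MAX_ITER = 100
#: separation bound on |coefficient| after scaling by the column's SD
SEPARATION_BOUND = 15.0


@dataclass
class LogisticFit:
    """A maximum-likelihood logistic fit on an expanded numeric design."""

    columns: list[str]
    coef: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    deviance: float
    converged: bool
    separation_flag: bool
    n_obs: int
    n_iter: int
    dropped: list[str] = field(default_factory=list)

    def coef_series(self) -> pd.Series:
        return pd.Series(self.coef, index=self.columns)

    def wald_p_values(self) -> pd.Series:
        se = np.sqrt(np.clip(np.diag(self.cov), 0.0, np.inf))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, self.coef / se, np.inf)
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.columns)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.columns].to_numpy(float) @ self.coef

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return _sigmoid(self.linear_predictor(X))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return -2.0 * float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove linearly dependent columns, keeping the earliest independent set.

    Greedy Gram-Schmidt in column order: a column whose residual after
    projection onto the already-kept columns is (numerically) zero is
    aliased and dropped, so later columns never displace earlier terms.
    """
    if X.shape[1] == 0:
        return X, [], []
    basis: list[np.ndarray] = []
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        x = X[:, j].astype(float)
        norm = np.linalg.norm(x)
        r = x.copy()
        for q in basis:
            r -= (q @ r) * q
        # re-orthogonalize once for numerical safety
        for q in basis:
            r -= (q @ r) * q
        rnorm = np.linalg.norm(r)
        if norm == 0.0 or rnorm <= 1e-8 * norm:
            dropped.append(names[j])
        else:
            basis.append(r / rnorm)
            keep.append(j)
    return X[:, keep], [names[j] for j in keep], dropped


def fit_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    warm_start: dict[str, float] | None = None,
    tol: float = IRLS_TOL,
    max_iter: int = IRLS_MAX_ITER,
    separation_bound: float = SEPARATION_BOUND,
) -> LogisticFit:
    """Fit a logistic regression by IRLS.

    Parameters
    ----------
    X
        Numeric design matrix (include a ``const`` column for the intercept).
    y
        Binary response in {0, 1}, one entry per row of ``X``.
    warm_start
        Optional starting coefficients keyed by column name; columns absent
        from the mapping start at zero.  Used by the scan to reuse the
        baseline solution when a SNP block is appended.

    Aliased (linearly dependent) columns are dropped with a logged warning;
    a design of rank zero is an error.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")

    names = list(X.columns)
    mat = X.to_numpy(dtype=float)
    mat, kept, dropped = _drop_aliased(mat, names)
    if dropped:
        logger.warning("dropping aliased design columns: %s", dropped)
    if mat.shape[1] == 0:
        raise ValueError("design matrix has rank zero")

    col_sd = mat.std(axis=0)
    beta = np.zeros(mat.shape[1])
    if warm_start:
        for j, name in enumerate(kept):
            beta[j] = warm_start.get(name, 0.0)

    eta = mat @ beta
    mu = _sigmoid(eta)
    deviance = _binomial_deviance(y, mu)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xw = mat * w[:, None]
        try:
            step_beta = np.linalg.solve(xw.T @ mat, xw.T @ z)
        except np.linalg.LinAlgError:
            step_beta, *_ = np.linalg.lstsq(xw.T @ mat, xw.T @ z, rcond=None)

        # step-halving keeps the deviance nonincreasing across iterations
        new_beta = step_beta
        for _ in range(25):
            new_eta = mat @ new_beta
            new_mu = _sigmoid(new_eta)
            new_dev = _binomial_deviance(y, new_mu)
            if new_dev <= deviance * (1.0 + 1e-12) + 1e-12:
                break
            new_beta = 0.5 * (new_beta + beta)
        delta = deviance - new_dev
        beta, eta, mu = new_beta, new_eta, new_mu
        deviance = new_dev

        scaled = np.abs(beta) * np.where(col_sd > 0, col_sd, 0.0)
        if scaled.size and np.max(scaled) > separation_bound and delta > 0:
            separated = True
            break
        if abs(delta) / (abs(deviance) + 0.1) < tol:
            converged = True
            break

    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    fisher = (mat * w[:, None]).T @ mat
    try:
        cov = np.linalg.inv(fisher)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(fisher)

    return LogisticFit(
        columns=kept,
        coef=beta,
        cov=cov,
        log_likelihood=-deviance / 2.0,
        deviance=deviance,
        converged=converged,
        separation_flag=separated,
        n_obs=len(y),
        n_iter=it,
        dropped=dropped,
    )


def fit_baseline(
    cohort: Cohort,
    encoder: CovariateEncoder | None = None,
) -> tuple[LogisticFit, pd.DataFrame, np.ndarray, CovariateEncoder]:
    """Fit the covariate-only baseline model on the stacked exam rows."""
    if encoder is None:
        encoder = CovariateEncoder().fit(cohort.phenotypes)
    X = encoder.transform(cohort.phenotypes)
    y = cohort.phenotypes["htn"].to_numpy(float)
    fit = fit_logistic(X, y)
    return fit, X, y, encoder


def scan_snp(
    baseline_fit: LogisticFit,
    X_base: pd.DataFrame,
    y: np.ndarray,
    tokens: np.ndarray,
    snp_id: str,
) -> tuple[float, int]:
    """Likelihood-ratio test of one SNP added to the baseline model.

    Returns ``(p_value, df)`` where df counts the non-aliased genotype
    indicator columns actually added.  A SNP monomorphic in the cohort adds
    nothing and reports ``(1.0, 0)``.
    """
    if not baseline_fit.converged or baseline_fit.separation_flag:
        raise ValueError("baseline fit must be converged and separation-free")
    levels = ordered_levels(tokens)
    if len(levels) <= 1:
        logger.info("SNP %s is monomorphic; p = 1", snp_id)
        return 1.0, 0
    G, _ = genotype_indicators(tokens, snp_id, levels=levels)
    G.index = X_base.index
    X_ext = pd.concat([X_base, G], axis=1)
    warm = dict(zip(baseline_fit.columns, baseline_fit.coef))
    ext = fit_logistic(X_ext, y, warm_start=warm)
    df_test = sum(1 for c in ext.columns if c in G.columns)
    if df_test == 0:
        return 1.0, 0
    lrt = max(0.0, 2.0 * (ext.log_likelihood - baseline_fit.log_likelihood))
    return float(stats.chi2.sf(lrt, df_test)), df_test


def rank_snps(scan: pd.DataFrame, flags: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach ranks (ascending p, ties by column order) to a per-SNP scan table.

    ``scan`` needs columns ``snp_id`` and ``p_value`` in genotype-column
    order.  Pruned SNPs (from an ``ld_prune`` flag table) receive no rank;
    ranks over the retained SNPs are a permutation of 1..n_retained.
    """
    out = scan.copy().reset_index(drop=True)
    if flags is not None:
        pruned = flags["pruned"].reindex(out["snp_id"]).fillna(False).to_numpy(bool)
        reason = flags["prune_reason"].reindex(out["snp_id"]).fillna("none").to_numpy()
    else:
        pruned = np.zeros(len(out), dtype=bool)
        reason = np.array(["none"] * len(out), dtype=object)
    out["pruned"] = pruned
    out["prune_reason"] = reason
    out["rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    retained = np.flatnonzero(~pruned)
    order = retained[np.argsort(out.loc[retained, "p_value"].to_numpy(), kind="stable")]
    out.loc[order, "rank"] = np.arange(1, len(order) + 1)
    return out


def scan_cohort(
    cohort: Cohort,
    response: str = "htn",
    prune_r: float | None = None,
    encoder: CovariateEncoder | None = None,
) -> pd.DataFrame:
    """Scan every SNP against the chosen response; optionally LD-prune first.

    For ``response="htn"`` each SNP is scored by the logistic likelihood-ratio
    test; for ``"sbp"``/``"dbp"`` by the OLS F-test of the genotype block
    (see :func:`quantitative_scan`).  Pruned SNPs are not scanned
    (``p_value`` NaN) and carry their pruning reason.
    """
    flags = None
    snp_ids = cohort.snp_ids
    scan_ids = snp_ids
    if prune_r is not None:
        kept, flags = ld_prune(cohort.genotypes, prune_r)
        scan_ids = kept

    geno = cohort.genotypes.reindex(cohort.phenotypes["individual_id"])
    if response == "htn":
        baseline, X_base, y, _ = fit_baseline(cohort, encoder=encoder)
        results = {
            snp: scan_snp(baseline, X_base, y, geno[snp].to_numpy(), snp)
            for snp in scan_ids
        }
    elif response in ("sbp", "dbp"):
        results = quantitative_scan(cohort, response, snp_ids=scan_ids, encoder=encoder)
        results = {snp: (p, df) for snp, p, df in
                   results[["snp_id", "p_value", "df"]].itertuples(index=False)}
    else:
        raise ValueError(f"unknown response {response!r}")

    scan = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "p_value": [results.get(s, (np.nan, 0))[0] for s in snp_ids],
            "df": [results.get(s, (np.nan, 0))[1] for s in snp_ids],
        }
    )
    return rank_snps(scan, flags)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def quantitative_scan(
    cohort: Cohort,
    response: str,
    snp_ids: list[str] | None = None,
    encoder: CovariateEncoder | None = None,
) -> pd.DataFrame:
    """Per-SNP F-tests with SBP or DBP as a quantitative response.

    Ordinary least squares on the same covariate terms; the genotype-indicator
    block is scored by the partial F-test.  Monomorphic SNPs report p = 1.
    """
    if response not in ("sbp", "dbp"):
        raise ValueError("quantitative response must be 'sbp' or 'dbp'")
    if encoder is None:
        encoder = CovariateEncoder().fit(cohort.phenotypes)
    X_base_df = encoder.transform(cohort.phenotypes)
    y = cohort.phenotypes[response].to_numpy(float)
    X_base = X_base_df.to_numpy(float)
    rss0, rank0 = _ols_rss(X_base, y)
    n = len(y)

    geno = cohort.genotypes.reindex(cohort.phenotypes["individual_id"])
    if snp_ids is None:
        snp_ids = cohort.snp_ids
    rows = []
    for snp in snp_ids:
        tokens = geno[snp].to_numpy()
        levels = ordered_levels(tokens)
        if len(levels) <= 1:
            rows.append((snp, 1.0, 0))
            continue
        G, _ = genotype_indicators(tokens, snp, levels=levels)
        X_ext = np.column_stack([X_base, G.to_numpy(float)])
        rss1, rank1 = _ols_rss(X_ext, y)
        q = rank1 - rank0
        if q <= 0 or n - rank1 <= 0:
            rows.append((snp, 1.0, 0))
            continue
        f_stat = max(0.0, (rss0 - rss1) / q) / (rss1 / (n - rank1))
        rows.append((snp, float(stats.f.sf(f_stat, q, n - rank1)), q))
    return pd.DataFrame(rows, columns=["snp_id", "p_value", "df"])


def allele_dose(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Minor-allele dose coding (0/1/2) of a genotype matrix; ``XX`` -> NaN.

    The minor allele is the less frequent of the two alleles over all
    non-missing calls at the SNP (tie broken toward the lexicographically
    smaller allele).
    """
    out = {}
    for snp in genotypes.columns:
        tokens = genotypes[snp].to_numpy()
        counts: dict[str, int] = {}
        for tok in tokens:
            if tok == MISSING_TOKEN:
                continue
            if len(tok) != 2:
                raise ValueError(f"genotype token {tok!r} for {snp!r} is not diploid")
            for ch in tok:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            out[snp] = np.full(len(tokens), np.nan)
            continue
        minor = min(counts, key=lambda a: (counts[a], a))
        dose = np.array(
            [np.nan if t == MISSING_TOKEN else float(t.count(minor)) for t in tokens]
        )
        out[snp] = dose
    return pd.DataFrame(out, index=genotypes.index)


def ld_prune(
    genotypes: pd.DataFrame,
    r_threshold: float,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy forward LD pruning on |Pearson r| of minor-allele dose.

    A SNP is kept iff its |r| with every previously kept SNP is below
    ``r_threshold``; with ``r_threshold = 1`` only exact duplicates
    (|r| = 1) are removed.  Zero-variance SNPs correlate with nothing and are
    always kept (logged).  Returns the kept SNP ids plus a per-SNP flag table
    (``pruned``, ``prune_reason`` in {perfect_ld, r_threshold, none}).
    """
    if genotypes.shape[1] < 2:
        raise ValueError("LD pruning needs at least two SNPs")
    if not (0.0 < r_threshold <= 1.0):
        raise ValueError("r_threshold must be in (0, 1]")
    dose = allele_dose(genotypes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pairwise-complete corr emits degenerate-slice noise
        corr = dose.corr(min_periods=2).abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr, nan=0.0)

    snp_ids = list(genotypes.columns)
    variances = dose.var(axis=0, ddof=0).to_numpy()
    kept_idx: list[int] = []
    pruned = np.zeros(len(snp_ids), dtype=bool)
    reason = np.array(["none"] * len(snp_ids), dtype=object)
    perfect_tol = 1.0 - 1e-12
    for j in range(len(snp_ids)):
        if not variances[j] > 0:
            logger.info("SNP %s has zero dose variance; kept", snp_ids[j])
            kept_idx.append(j)
            continue
        r_max = corr[j, kept_idx].max() if kept_idx else 0.0
        if r_max >= perfect_tol:
            pruned[j] = True
            reason[j] = "perfect_ld"
        elif r_threshold < 1.0 and r_max >= r_threshold:
            pruned[j] = True
            reason[j] = "r_threshold"
        else:
            kept_idx.append(j)

    flags = pd.DataFrame(
        {"pruned": pruned, "prune_reason": reason},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return [snp_ids[j] for j in kept_idx], flags
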