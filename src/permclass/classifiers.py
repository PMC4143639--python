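"""Comparison classifiers and shared feature construction.

Three predictors share one feature pipeline:

* **multi-SNP logistic regression** — the baseline covariates plus genotype
  indicators for the top-ranked SNPs, predicted with the >= 0.5 rule;
* **RBF-kernel maximal-margin classifier** — soft-margin SVM with kernel
  exp(-gamma ||x - x'||^2), (gamma, C) tuned by stratified 10-fold CV;
* **permanental classifier** — see :mod:`permclass.permanental`; (alpha, tau)
  tuned the same way.

Genotype features use *NS collapsing*: for each selected SNP the extended
logistic model with full genotype indicators is fitted on training data, and
every genotype level whose coefficient is not significant against the
reference (Wald p >= 0.05) is pooled into a single "Not Significant" (NS)
category.  Only the retained levels keep indicator columns, so collapsing
never increases a SNP's column count.  All encodings — genotype levels,
retained categories, pedigree contrasts, standardization constants — are
computed on training data once and frozen; genotype tokens unseen at test
time fall into the absorbing NS category.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .design import CovariateEncoder, genotype_indicators, ordered_levels
from .io_gaw import Cohort
from .scan import LogisticFit, fit_logistic

__all__ = [
    "NS_P_THRESHOLD",
    "SvmConfig",
    "DEFAULT_SVM_GRID",
    "DEFAULT_PERM_GRID",
    "NsCollapse",
    "ns_collapse",
    "FeatureBuilder",
    "logistic_predict",
    "svm_train",
    "tune_hyperparameters",
]

logger = logging.getLogger(__name__)

#: Wald p-value bound above which a genotype level is pooled into NS
NS_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class SvmConfig:
    """RBF-kernel SVM hyperparameters: kernel width gamma, error penalty C."""

    gamma: float
    cost: float

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.cost <= 0:
            raise ValueError("gamma and cost must be positive")


#: (gamma, C) grid, log-spaced over 10^-3..10^3; grid order breaks CV ties
DEFAULT_SVM_GRID: list[SvmConfig] = [
    SvmConfig(gamma=float(g), cost=float(c))
    for g in np.logspace(-3, 3, 7)
    for c in np.logspace(-3, 3, 7)
]

#: (alpha, tau) grid for the permanental classifier
DEFAULT_PERM_GRID: list[tuple[float, float]] = [
    (a, t) for a in (0.5, 1.0, 2.0, 4.0) for t in (0.5, 1.0, 2.0, 4.0, 8.0)
]


@dataclass
class NsCollapse:
    """Partition of one SNP's genotype tokens: retained singletons vs NS.

    Every token maps to exactly one category; the NS pool absorbs the
    reference genotype, the non-significant levels, and any token unseen in
    training.  A SNP with no retained level contributes no columns.
    """

    snp_id: str
    reference: str
    retained: list[str] = field(default_factory=list)
    pooled: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.retained)


def ns_collapse(
    snp_id: str,
    tokens: np.ndarray,
    X_base: pd.DataFrame,
    y: np.ndarray,
    p_threshold: float = NS_P_THRESHOLD,
) -> NsCollapse:
    """Fit the extended model for one SNP and pool its non-significant levels.

    Genotype levels are tested against the reference (most frequent genotype)
    with per-coefficient Wald tests from the extended logistic fit on the
    training rows; levels with p >= ``p_threshold`` join the NS pool.
    """
    levels = ordered_levels(tokens)
    if len(levels) <= 1:
        return NsCollapse(snp_id=snp_id, reference=levels[0] if levels else "", retained=[],
                          pooled=list(levels))
    G, reference = genotype_indicators(tokens, snp_id, levels=levels)
    G.index = X_base.index
    fit = fit_logistic(pd.concat([X_base, G], axis=1), y)
    wald = fit.wald_p_values()
    retained = []
    pooled = [reference]
    for tok in levels[1:]:
        col = f"{snp_id}[{tok}]"
        if col in wald.index and wald[col] < p_threshold:
            retained.append(tok)
        else:
            pooled.append(tok)
    if not retained:
        logger.warning("SNP %s: no significant genotype level; SNP dropped", snp_id)
    return NsCollapse(snp_id=snp_id, reference=reference, retained=retained, pooled=pooled)


class FeatureBuilder:
    """Training-frozen feature construction for all three classifiers.

    ``fit`` derives every encoding from the training cohort: the covariate
    design, NS-collapse maps for the selected SNPs, carrier indicators for
    the selected rare variants, and standardization constants.  ``transform``
    then applies the frozen maps to any cohort; ``state_hash`` fingerprints
    the maps so leakage (test-time mutation) is detectable by checksum.
    """

    def __init__(self, collapse: bool = True) -> None:
        self.collapse = collapse
        self.covariates_: CovariateEncoder | None = None
        self.snp_maps_: dict[str, NsCollapse] = {}
        self.snp_levels_: dict[str, list[str]] = {}
        self.rare_carriers_: dict[str, str] = {}
        self.mean_: pd.Series | None = None
        self.sd_: pd.Series | None = None

    def fit(
        self,
        cohort: Cohort,
        snp_ids: Sequence[str] = (),
        rare_carriers: dict[str, str] | None = None,
        X_base: pd.DataFrame | None = None,
    ) -> "FeatureBuilder":
        """Freeze encodings on a training cohort.

        ``rare_carriers`` maps SNP id -> carrier genotype token (from the
        rare-variant screen).  ``X_base`` may pass a precomputed baseline
        design to avoid refitting it per SNP.
        """
        self.covariates_ = CovariateEncoder().fit(cohort.phenotypes)
        if X_base is None:
            X_base = self.covariates_.transform(cohort.phenotypes)
        y = cohort.phenotypes["htn"].to_numpy(float)
        geno = cohort.genotypes.reindex(cohort.phenotypes["individual_id"])
        self.snp_maps_ = {}
        self.snp_levels_ = {}
        for snp in snp_ids:
            tokens = geno[snp].to_numpy()
            if self.collapse:
                cmap = ns_collapse(snp, tokens, X_base, y)
            else:
                levels = ordered_levels(tokens)
                cmap = NsCollapse(
                    snp_id=snp, reference=levels[0], retained=levels[1:], pooled=[levels[0]]
                )
            self.snp_maps_[snp] = cmap
        self.rare_carriers_ = dict(rare_carriers or {})

        raw = self._raw(cohort)
        self.mean_ = raw.mean(axis=0)
        sd = raw.std(axis=0, ddof=0)
        self.sd_ = sd.mask(sd == 0, 1.0)
        return self

    def _raw(self, cohort: Cohort) -> pd.DataFrame:
        assert self.covariates_ is not None, "FeatureBuilder is not fitted"
        parts = [self.covariates_.transform(cohort.phenotypes, include_const=False)]
        geno = cohort.genotypes.reindex(cohort.phenotypes["individual_id"])
        for snp, cmap in self.snp_maps_.items():
            tokens = geno[snp].to_numpy()
            for tok in cmap.retained:
                parts.append(
                    pd.Series((tokens == tok).astype(float), name=f"{snp}[{tok}]",
                              index=parts[0].index)
                )
        for snp, carrier_tok in self.rare_carriers_.items():
            if snp in self.snp_maps_:  # already encoded as a common-variant block
                continue
            tokens = geno[snp].to_numpy()
            parts.append(
                pd.Series((tokens == carrier_tok).astype(float),
                          name=f"{snp}[carrier:{carrier_tok}]", index=parts[0].index)
            )
        return pd.concat(parts, axis=1)

    @property
    def feature_names(self) -> list[str]:
        if self.mean_ is None:
            raise RuntimeError("FeatureBuilder is not fitted")
        return list(self.mean_.index)

    def transform(self, cohort: Cohort, standardize: bool = False) -> pd.DataFrame:
        """Features for a cohort using the frozen training maps.

        ``standardize=True`` applies the training mean/SD (for the kernel
        classifiers); the logistic model takes the raw indicators plus a
        constant column.
        """
        raw = self._raw(cohort)
        if standardize:
            return (raw - self.mean_) / self.sd_
        raw.insert(0, "const", 1.0)
        return raw

    def state_hash(self) -> str:
        """Checksum of every frozen map (leakage audit)."""
        h = hashlib.sha256()
        assert self.covariates_ is not None
        h.update(repr(self.covariates_.pedigree_levels_).encode())
        for snp in sorted(self.snp_maps_):
            m = self.snp_maps_[snp]
            h.update(repr((snp, m.reference, m.retained, m.pooled)).encode())
        h.update(repr(sorted(self.rare_carriers_.items())).encode())
        h.update(np.asarray(self.mean_, dtype=float).tobytes())
        h.update(np.asarray(self.sd_, dtype=float).tobytes())
        return h.hexdigest()


def logistic_predict(
    fit: LogisticFit,
    X: pd.DataFrame,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and >= 0.5-rule labels from a fitted logistic model."""
    prob = fit.predict_proba(X)
    return (prob >= threshold).astype(int), prob


def svm_train(X: np.ndarray, y: np.ndarray, config: SvmConfig) -> SVC:
    """Fit the soft-margin RBF-kernel classifier on (standardized) features."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("SVM training needs both classes present")
    model = SVC(kernel="rbf", gamma=config.gamma, C=config.cost)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def tune_hyperparameters(
    make_model: Callable[[object], object],
    grid: Sequence,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> tuple[object, pd.DataFrame]:
    """Grid search by stratified k-fold cross-validated misclassification.

    ``make_model(config)`` must return an object with ``fit``/``predict``.
    The winning config is the grid point with the smallest mean CV error,
    ties resolved toward the earlier grid entry.  Fold assignment is
    deterministic given ``seed``; a fold whose training part loses a class is
    refolded with a new sub-seed (max 5 attempts).
    """
    if len(grid) == 0:
        raise ValueError("hyperparameter grid is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_splits = min(folds, int(np.bincount(y.astype(int)).min()))
    if n_splits < 2:
        raise ValueError("too few examples of one class for cross-validation")

    splits = None
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed + attempt)
        candidate = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in candidate):
            splits = candidate
            break
    if splits is None:
        raise RuntimeError("could not build class-balanced folds in 5 attempts")

    rows = []
    for cfg in grid:
        errs = []
        for tr, va in splits:
            model = make_model(cfg)
            model.fit(X[tr], y[tr])
            errs.append(float(np.mean(model.predict(X[va]) != y[va])))
        rows.append((cfg, float(np.mean(errs))))
    table = pd.DataFrame(rows, columns=["config", "cv_error"])
    best_idx = int(table["cv_error"].idxmin())  # idxmin keeps the first minimum
    return table.loc[best_idx, "config"], table
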