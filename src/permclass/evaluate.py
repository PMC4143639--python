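"""Replicate-based train/test harness and error-rate accounting.

One training cohort is used for everything that involves choice — LD pruning,
the single-SNP scan and ranking, the rare-variant screen, NS collapsing,
standardization, and hyperparameter tuning — and the frozen models are then
scored on each testing replicate (same genotype matrix, independently
re-drawn phenotypes).  Errors are misclassification proportions over the
stacked individual x exam rows; the aggregate per method and feature-set
size is the arithmetic mean of the per-replicate testing errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import (
    DEFAULT_PERM_GRID,
    DEFAULT_SVM_GRID,
    FeatureBuilder,
    SvmConfig,
    logistic_predict,
    svm_train,
    tune_hyperparameters,
)
from .io_gaw import Cohort
from .permanental import PermanentalClassifier, PermanentalConfig
from .rare import rare_screen
from .scan import fit_baseline, fit_logistic, ld_prune, rank_snps, scan_snp

__all__ = ["ErrorReport", "error_rate", "run_comparison", "write_report", "read_report"]

logger = logging.getLogger(__name__)

METHODS = ("logistic", "svm", "permanental")

REPORT_COLUMNS = ["method", "k_common", "k_rare", "replicate", "split", "error"]


def error_rate(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Misclassification proportion of two equal-length binary vectors."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if not (np.isin(predicted, (0, 1)).all() and np.isin(truth, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return float(np.mean(predicted != truth))


@dataclass
class ErrorReport:
    """Long-format error records plus tuning provenance."""

    records: pd.DataFrame  # REPORT_COLUMNS
    tuned: pd.DataFrame  # method, k_common, k_rare, config

    def mean_testing_error(self, method: str, k_common: int, k_rare: int = 0) -> float:
        """Average testing error across testing replicates."""
        sub = self.records[
            (self.records["method"] == method)
            & (self.records["k_common"] == k_common)
            & (self.records["k_rare"] == k_rare)
            & (self.records["split"] == "testing")
        ]
        if sub.empty:
            raise KeyError(f"no testing records for {method} k=({k_common},{k_rare})")
        return float(sub["error"].mean())

    def summary(self) -> pd.DataFrame:
        """Wide table: one row per (method, split), one column per feature size.

        Testing rows average across replicates; column order follows the
        k-grid order of the run.
        """
        rec = self.records.copy()
        rec["k"] = list(zip(rec["k_common"], rec["k_rare"]))
        k_order = list(dict.fromkeys(rec["k"]))
        rows = {}
        for method in dict.fromkeys(rec["method"]):
            for split in ("training", "testing"):
                sub = rec[(rec["method"] == method) & (rec["split"] == split)]
                rows[(method, split)] = {
                    k: float(sub[sub["k"] == k]["error"].mean()) for k in k_order
                }
        out = pd.DataFrame(rows).T
        out = out[k_order]
        out.index = pd.MultiIndex.from_tuples(out.index, names=["method", "split"])
        out.columns = [f"k={c[0]}" if c[1] == 0 else f"k=({c[0]},{c[1]})" for c in k_order]
        return out


def _normalize_k_grid(k_grid: Sequence) -> list[tuple[int, int]]:
    pairs = []
    for k in k_grid:
        if isinstance(k, (tuple, list)):
            pairs.append((int(k[0]), int(k[1])))
        else:
            pairs.append((int(k), 0))
    return pairs


def run_comparison(
    train: Cohort,
    tests: Sequence[Cohort],
    methods: Sequence[str] = METHODS,
    k_grid: Sequence = (0, 5, 10, 15, 20),
    seed: int = 0,
    svm_grid: Sequence[SvmConfig] = DEFAULT_SVM_GRID,
    perm_grid: Sequence[tuple[float, float]] = DEFAULT_PERM_GRID,
    folds: int = 10,
    neighbor_budget: int = 10,
    collapse: bool = True,
) -> ErrorReport:
    """Train on one cohort, test on replicates, across methods and k sizes.

    ``k_grid`` entries are either ``k`` (top-k common SNPs) or ``(k_common,
    k_rare)`` pairs; rare carriers come from the rare-variant screen and are
    appended after the common-SNP indicators, with SNPs already selected as
    common variants dropped from the rare list.  Everything is reproducible
    from ``seed`` (the only randomness is CV fold assignment).
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    for t in tests:
        if list(t.genotypes.columns) != list(train.genotypes.columns):
            raise ValueError("testing cohorts must share the training genotype matrix")
    pairs = _normalize_k_grid(k_grid)

    # selection happens once, on training data only
    kept, flags = ld_prune(train.genotypes, 1.0)
    baseline, X_base, y_train, encoder = fit_baseline(train)
    geno = train.genotypes.reindex(train.phenotypes["individual_id"])
    scan = pd.DataFrame(
        {
            "snp_id": train.snp_ids,
            "p_value": np.nan,
            "df": 0,
        }
    )
    need_scan = any(k > 0 for k, _ in pairs)
    if need_scan:
        res = {
            snp: scan_snp(baseline, X_base, y_train, geno[snp].to_numpy(), snp)
            for snp in kept
        }
        scan["p_value"] = [res.get(s, (np.nan, 0))[0] for s in train.snp_ids]
        scan["df"] = [res.get(s, (np.nan, 0))[1] for s in train.snp_ids]
    ranked = rank_snps(scan, flags)
    ranked_ids = (
        ranked[ranked["rank"].notna()]
        .sort_values("rank")["snp_id"]
        .tolist()
    )
    rare_hits = None
    if any(kr > 0 for _, kr in pairs):
        rare_hits = rare_screen(train)

    y_tests = [t.phenotypes["htn"].to_numpy(int) for t in tests]
    records = []
    tuned_rows = []
    for k_common, k_rare in pairs:
        if k_common > len(ranked_ids):
            warnings.warn(
                f"k={k_common} exceeds the {len(ranked_ids)} retained SNPs; capped",
                stacklevel=2,
            )
            k_common = len(ranked_ids)
        selected = ranked_ids[:k_common]
        rare_carriers: dict[str, str] = {}
        if k_rare > 0:
            assert rare_hits is not None
            pool = rare_hits[~rare_hits["snp_id"].isin(selected)]
            if k_rare > len(pool):
                warnings.warn(
                    f"k_rare={k_rare} exceeds the {len(pool)} screened rare variants; capped",
                    stacklevel=2,
                )
            chosen = pool.head(k_rare)
            rare_carriers = dict(zip(chosen["snp_id"], chosen["rare_genotype"]))

        builder = FeatureBuilder(collapse=collapse).fit(
            train, snp_ids=selected, rare_carriers=rare_carriers, X_base=X_base
        )
        frozen = builder.state_hash()
        X_raw_train = builder.transform(train)
        X_std_train = builder.transform(train, standardize=True).to_numpy()
        raw_tests = [builder.transform(t) for t in tests]
        std_tests = [builder.transform(t, standardize=True).to_numpy() for t in tests]
        if builder.state_hash() != frozen:
            raise RuntimeError("feature maps changed between training and testing")
        y_int = y_train.astype(int)

        for method in methods:
            if method == "logistic":
                fit = fit_logistic(X_raw_train, y_train)
                preds_train, _ = logistic_predict(fit, X_raw_train)
                preds_tests = [logistic_predict(fit, Xt)[0] for Xt in raw_tests]
                tuned_rows.append((method, k_common, k_rare, None))
            elif method == "svm":
                best, _ = _tune_svm(X_std_train, y_int, svm_grid, folds, seed)
                model = svm_train(X_std_train, y_int, best)
                preds_train = model.predict(X_std_train)
                preds_tests = [model.predict(Xt) for Xt in std_tests]
                tuned_rows.append((method, k_common, k_rare, best))
            else:  # permanental
                best, _ = _tune_permanental(
                    X_std_train, y_int, perm_grid, folds, seed, neighbor_budget
                )
                model = PermanentalClassifier(
                    PermanentalConfig(alpha=best[0], tau=best[1],
                                      neighbor_budget=neighbor_budget)
                ).fit(X_std_train, y_int)
                preds_train = model.predict(X_std_train)
                preds_tests = [model.predict(Xt) for Xt in std_tests]
                tuned_rows.append((method, k_common, k_rare, best))

            records.append(
                (method, k_common, k_rare, 0, "training", error_rate(preds_train, y_int))
            )
            for r, (pred, yt) in enumerate(zip(preds_tests, y_tests), start=1):
                records.append(
                    (method, k_common, k_rare, r, "testing", error_rate(pred, yt))
                )
            logger.info(
                "%s k=(%d,%d): training %.4f",
                method, k_common, k_rare, records[-1 - len(tests)][5],
            )

    return ErrorReport(
        records=pd.DataFrame(records, columns=REPORT_COLUMNS),
        tuned=pd.DataFrame(tuned_rows, columns=["method", "k_common", "k_rare", "config"]),
    )


class _SvmWrap:
    def __init__(self, cfg: SvmConfig) -> None:
        self.cfg = cfg
        self.model: object | None = None

    def fit(self, X, y):
        self.model = svm_train(X, y, self.cfg)
        return self

    def predict(self, X):
        return self.model.predict(X)


def _tune_svm(X, y, grid, folds, seed):
    return tune_hyperparameters(_SvmWrap, grid, X, y, folds=folds, seed=seed)


def _tune_permanental(X, y, grid, folds, seed, neighbor_budget):
    def factory(cfg):
        alpha, tau = cfg
        return PermanentalClassifier(
            PermanentalConfig(alpha=alpha, tau=tau, neighbor_budget=neighbor_budget)
        )

    return tune_hyperparameters(factory, grid, X, y, folds=folds, seed=seed)


def write_report(report: ErrorReport, path: str) -> None:
    """Write the long-format records as CSV plus a summary table alongside.

    The summary (``<path>`` with a ``.summary.txt`` suffix) mirrors the
    method x split by feature-size layout of the published comparison
    tables.
    """
    report.records.to_csv(path, index=False)
    summary_path = f"{path}.summary.txt"
    with open(summary_path, "w") as fh:
        if report.records.empty:
            fh.write("(empty report)\n")
        else:
            fh.write(report.summary().to_string(float_format=lambda v: f"{v:.4f}"))
            fh.write("\n")


def read_report(path: str) -> ErrorReport:
    records = pd.read_csv(path)
    if list(records.columns) != REPORT_COLUMNS:
        raise ValueError("unexpected report columns")
    return ErrorReport(records=records, tuned=pd.DataFrame(columns=["method", "k_common", "k_rare", "config"]))
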