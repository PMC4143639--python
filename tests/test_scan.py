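"""Logistic core, likelihood-ratio scan, ranking and LD pruning."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from permclass.design import CovariateEncoder
from permclass.io_gaw import Cohort
from permclass.scan import (
    allele_dose,
    fit_baseline,
    fit_logistic,
    ld_prune,
    quantitative_scan,
    rank_snps,
    scan_cohort,
    scan_snp,
)
from permclass.simulate import SimulationConfig, simulate_cohort


def _two_by_two_design(n11, n10, n01, n00):
    """exposed cases / exposed controls / unexposed cases / unexposed controls"""
    x = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
    y = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    X = pd.DataFrame({"const": np.ones_like(x), "x": x})
    return X, y


def test_slope_matches_closed_form_log_odds_ratio():
    X, y = _two_by_two_design(10, 20, 20, 10)
    fit = fit_logistic(X, y)
    assert fit.converged and not fit.separation_flag
    assert fit.coef_series()["x"] == pytest.approx(np.log((10 * 10) / (20 * 20)), abs=1e-6)


def test_intercept_only_matches_prevalence_odds():
    y = np.r_[np.ones(30), np.zeros(70)]
    X = pd.DataFrame({"const": np.ones(100)})
    fit = fit_logistic(X, y)
    assert fit.coef_series()["const"] == pytest.approx(np.log(30 / 70), abs=1e-6)


def test_irls_agrees_with_statsmodels_glm():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
    X.insert(0, "const", 1.0)
    eta = 0.5 * X["a"] - 0.8 * X["c"]
    y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic(X, y)
    oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(fit.coef, oracle.params.to_numpy(), atol=1e-6)
    assert fit.log_likelihood == pytest.approx(oracle.llf, abs=1e-6)
    np.testing.assert_allclose(
        np.diag(fit.cov), np.diag(oracle.cov_params().to_numpy()), rtol=1e-4
    )


def test_perfect_separation_is_flagged():
    x = np.r_[np.linspace(-2, -0.5, 20), np.linspace(0.5, 2, 20)]
    y = (x > 0).astype(float)
    X = pd.DataFrame({"const": np.ones_like(x), "x": x})
    fit = fit_logistic(X, y)
    assert fit.separation_flag


def test_aliased_columns_dropped_with_warning(caplog):
    rng = np.random.default_rng(0)
    x = rng.normal(size=100)
    X = pd.DataFrame({"const": np.ones(100), "x": x, "x2": 2 * x})
    y = (rng.random(100) < 0.4).astype(float)
    with caplog.at_level("WARNING"):
        fit = fit_logistic(X, y)
    assert fit.dropped == ["x2"]
    assert "aliased" in caplog.text


def test_rank_zero_and_nonbinary_rejected():
    with pytest.raises(ValueError, match="rank zero"):
        fit_logistic(pd.DataFrame({"z": np.zeros(10)}), np.zeros(10))
    with pytest.raises(ValueError, match="binary"):
        fit_logistic(pd.DataFrame({"const": np.ones(4)}), np.array([0, 1, 2, 1]))


def test_monomorphic_snp_scores_one(small_cohort):
    cohort, _ = small_cohort
    baseline, X_base, y, _ = fit_baseline(cohort)
    tokens = np.array(["CC"] * len(y))
    assert scan_snp(baseline, X_base, y, tokens, "mono") == (1.0, 0)


def test_scan_invariant_to_token_relabeling(small_cohort):
    cohort, _ = small_cohort
    baseline, X_base, y, _ = fit_baseline(cohort)
    snp = cohort.snp_ids[0]
    tokens = cohort.genotypes[snp].reindex(cohort.phenotypes["individual_id"]).to_numpy()
    relabel = {t: n for t, n in zip(pd.unique(tokens), ["TT", "TC", "CC", "GG"])}
    renamed = np.array([relabel[t] for t in tokens])
    p1, df1 = scan_snp(baseline, X_base, y, tokens, snp)
    p2, df2 = scan_snp(baseline, X_base, y, renamed, snp)
    assert df1 == df2
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_baseline_is_cached_across_snps(small_cohort):
    cohort, _ = small_cohort
    baseline, X_base, y, _ = fit_baseline(cohort)
    ll = baseline.log_likelihood
    for snp in cohort.snp_ids[:3]:
        tokens = cohort.genotypes[snp].reindex(cohort.phenotypes["individual_id"]).to_numpy()
        scan_snp(baseline, X_base, y, tokens, snp)
    assert baseline.log_likelihood == ll  # refit-free baseline


def test_strong_causal_snp_detected():
    cfg = SimulationConfig(
        seed=1, n_individuals=400, n_snps=20, n_causal=1, causal_log_odds=1.0,
        causal_maf_range=(0.3, 0.3), n_rare_causal=0, n_ld_tagged=0,
        n_perfect_duplicates=0,
    )
    cohort, truth = simulate_cohort(cfg)
    res = scan_cohort(cohort)
    p = res.set_index("snp_id").loc[truth.causal_snp_ids[0], "p_value"]
    assert p < 1e-4


@pytest.mark.parametrize(
    "pvals, expected",
    [
        ([0.03, 0.001, 0.5], [2, 1, 3]),
        ([0.01, 0.01, 0.2], [1, 2, 3]),  # ties keep column order
    ],
)
def test_rank_snps_orders_by_p(pvals, expected):
    scan = pd.DataFrame({"snp_id": [f"s{i}" for i in range(len(pvals))],
                         "p_value": pvals, "df": 1})
    ranked = rank_snps(scan)
    assert list(ranked["rank"]) == expected


def test_rank_skips_pruned_snps():
    scan = pd.DataFrame({"snp_id": ["s0", "s1", "s2"], "p_value": [0.5, 0.001, 0.2], "df": 1})
    flags = pd.DataFrame(
        {"pruned": [False, True, False], "prune_reason": ["none", "perfect_ld", "none"]},
        index=pd.Index(["s0", "s1", "s2"], name="snp_id"),
    )
    ranked = rank_snps(scan, flags)
    assert ranked["rank"].tolist() == [2, pd.NA, 1]
    assert list(ranked["prune_reason"]) == ["none", "perfect_ld", "none"]


def _geno_from_doses(doses: dict) -> pd.DataFrame:
    lut = {0: "CC", 1: "TC", 2: "TT"}
    ids = [f"i{k}" for k in range(len(next(iter(doses.values()))))]
    return pd.DataFrame(
        {snp: [lut[d] for d in arr] for snp, arr in doses.items()},
        index=pd.Index(ids, name="individual_id"),
    )


def test_ld_prune_removes_exact_duplicates_only_at_threshold_one():
    rng = np.random.default_rng(4)
    x = rng.binomial(2, 0.4, size=100)
    y = x.copy()
    flip = rng.choice(100, size=4, replace=False)
    y[flip] = rng.binomial(2, 0.4, size=4)
    geno = _geno_from_doses({"a": x, "b": x, "c": y})
    r = abs(np.corrcoef(x, y)[0, 1])
    assert 0.8 < r < 1.0  # near- but not perfect-LD construction
    kept, flags = ld_prune(geno, 1.0)
    assert kept == ["a", "c"]
    assert flags.loc["b", "prune_reason"] == "perfect_ld"


def test_ld_prune_threshold_window():
    rng = np.random.default_rng(12)
    x = rng.binomial(2, 0.5, size=400)
    y = x.copy()
    flip = rng.choice(400, size=12, replace=False)
    y[flip] = rng.binomial(2, 0.5, size=12)
    r = abs(np.corrcoef(x, y)[0, 1])
    assert 0.95 < r < 0.99  # pins the construction between the two thresholds
    geno = _geno_from_doses({"a": x, "b": y})
    kept95, flags95 = ld_prune(geno, 0.95)
    assert kept95 == ["a"] and flags95.loc["b", "prune_reason"] == "r_threshold"
    kept99, _ = ld_prune(geno, 0.99)
    assert kept99 == ["a", "b"]


def test_ld_prune_is_idempotent(small_cohort):
    cohort, truth = small_cohort
    kept, flags = ld_prune(cohort.genotypes, 1.0)
    again, flags2 = ld_prune(cohort.genotypes[kept], 1.0)
    assert again == kept
    # the planted perfect duplicates are exactly the removed columns
    removed = set(flags.index[flags["pruned"]])
    assert removed == {dup for _, dup in truth.duplicate_groups}


def test_ld_prune_keeps_zero_variance_snp():
    geno = _geno_from_doses({"a": np.array([0, 1, 2, 1]), "b": np.array([0, 0, 0, 0])})
    kept, flags = ld_prune(geno, 1.0)
    assert "b" in kept and not flags.loc["b", "pruned"]


def test_allele_dose_counts_minor_allele():
    geno = _geno_from_doses({"a": np.array([0, 1, 2])})
    geno.loc["i2", "a"] = "XX"
    dose = allele_dose(geno)
    assert dose["a"].tolist()[:2] == [0.0, 1.0]
    assert np.isnan(dose["a"].iloc[2])


def test_quantitative_scan_monomorphic_snp_scores_one(small_cohort):
    cohort, _ = small_cohort
    geno = cohort.genotypes.copy()
    geno["mono"] = "CC"
    qs = quantitative_scan(Cohort(cohort.phenotypes, geno), "sbp").set_index("snp_id")
    assert qs.loc["mono", "p_value"] == 1.0 and qs.loc["mono", "df"] == 0
    with pytest.raises(ValueError, match="sbp"):
        quantitative_scan(cohort, "htn")


def test_quantitative_scan_detects_strong_bp_snp():
    cfg = SimulationConfig(
        seed=1, n_individuals=400, n_snps=20, n_causal=1, causal_log_odds=2.5,
        causal_maf_range=(0.3, 0.3), n_rare_causal=0, n_ld_tagged=0,
        n_perfect_duplicates=0,
    )
    cohort, truth = simulate_cohort(cfg)
    qs = quantitative_scan(cohort, "sbp").set_index("snp_id")
    assert qs.loc[truth.causal_snp_ids[0], "p_value"] < 1e-6


def test_top_htn_snp_ranks_high_in_sbp_scan():
    cohort, _ = simulate_cohort(SimulationConfig(seed=1))
    htn_res = scan_cohort(cohort, prune_r=1.0)
    top = htn_res[htn_res["rank"].notna()].sort_values("rank")["snp_id"].iloc[0]
    sbp = quantitative_scan(cohort, "sbp").sort_values("p_value")
    assert top in sbp["snp_id"].head(10).tolist()
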