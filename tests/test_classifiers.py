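"""NS collapsing, frozen feature maps, SVM training and CV tuning."""

import numpy as np
import pandas as pd
import pytest
from sklearn.datasets import make_moons

from permclass.classifiers import (
    FeatureBuilder,
    SvmConfig,
    logistic_predict,
    ns_collapse,
    svm_train,
    tune_hyperparameters,
)
from permclass.io_gaw import Cohort
from permclass.scan import fit_logistic
from permclass.simulate import SimulationConfig, simulate_cohort


def _const_design(n):
    return pd.DataFrame({"const": np.ones(n)})


def test_ns_collapse_keeps_only_significant_levels():
    """A planted recessive effect: only the rare homozygote is associated, so
    the het (and XX) pool into NS while 'TT' keeps its own indicator."""
    rng = np.random.default_rng(1)
    n = 400
    tokens = np.array(["CC"] * 280 + ["TC"] * 80 + ["TT"] * 30 + ["XX"] * 10)
    risk = np.where(tokens == "TT", 0.9, 0.25)
    y = (rng.random(n) < risk).astype(float)
    cmap = ns_collapse("s", tokens, _const_design(n), y)
    assert cmap.retained == ["TT"]
    assert set(cmap.pooled) == {"CC", "TC", "XX"}
    assert cmap.n_columns == 1


def test_ns_collapse_drops_snp_without_signal(caplog):
    rng = np.random.default_rng(5)
    n = 300
    tokens = np.array(["CC"] * 200 + ["TC"] * 100)
    y = (rng.random(n) < 0.3).astype(float)
    with caplog.at_level("WARNING"):
        cmap = ns_collapse("s", tokens, _const_design(n), y)
    assert cmap.retained == [] and "dropped" in caplog.text


def test_ns_collapse_never_adds_columns(small_cohort):
    cohort, _ = small_cohort
    from permclass.scan import fit_baseline

    _, X_base, y, _ = fit_baseline(cohort)
    geno = cohort.genotypes.reindex(cohort.phenotypes["individual_id"])
    for snp in cohort.snp_ids[:10]:
        tokens = geno[snp].to_numpy()
        cmap = ns_collapse(snp, tokens, X_base, y)
        assert cmap.n_columns <= len(np.unique(tokens)) - 1
        assert sorted(cmap.retained + cmap.pooled) == sorted(np.unique(tokens))


def test_logistic_predict_threshold_rule():
    y = np.r_[np.ones(50), np.zeros(50)]
    X = pd.DataFrame({"const": np.ones(100)})
    fit = fit_logistic(X, y)  # balanced -> linear predictor 0 -> p = 0.5
    labels, prob = logistic_predict(fit, X)
    assert np.allclose(prob, 0.5)
    assert (labels == 1).all()  # >= 0.5 rule labels the boundary as 1
    y2 = np.r_[np.ones(5), np.zeros(95)]
    fit2 = fit_logistic(pd.DataFrame({"const": np.ones(100)}), y2)
    labels2, _ = logistic_predict(fit2, X)
    assert (labels2 == 0).all()


def test_svm_separable_and_label_flip():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(5, 0.3, (10, 2))])
    y = np.r_[np.zeros(10, int), np.ones(10, int)]
    model = svm_train(X, y, SvmConfig(gamma=0.5, cost=10.0))
    assert (model.predict(X) == y).all()
    flipped = svm_train(X, 1 - y, SvmConfig(gamma=0.5, cost=10.0))
    assert (flipped.predict(X) == 1 - y).all()
    with pytest.raises(ValueError, match="both classes"):
        svm_train(X, np.zeros(20, int), SvmConfig(gamma=0.5, cost=10.0))


def test_svm_solves_xor_pattern_with_rbf_kernel():
    rng = np.random.default_rng(2)
    centers = [(0, 0), (4, 4), (0, 4), (4, 0)]
    labels = [0, 0, 1, 1]
    X = np.vstack([rng.normal(c, 0.3, (10, 2)) for c in centers])
    y = np.repeat(labels, 10)
    model = svm_train(X, y, SvmConfig(gamma=1.0, cost=10.0))
    assert (model.predict(X) == y).all()


class _Wrap:
    def __init__(self, cfg):
        self.cfg = cfg

    def fit(self, X, y):
        self.model = svm_train(X, y, self.cfg)
        return self

    def predict(self, X):
        return self.model.predict(X)


def test_tuning_single_point_and_determinism():
    X, y = make_moons(n_samples=120, noise=0.25, random_state=1)
    only = SvmConfig(gamma=1.0, cost=1.0)
    best, _ = tune_hyperparameters(_Wrap, [only], X, y, folds=5, seed=3)
    assert best == only
    grid = [SvmConfig(gamma=g, cost=1.0) for g in (0.1, 1.0, 10.0)]
    b1, t1 = tune_hyperparameters(_Wrap, grid, X, y, folds=5, seed=3)
    b2, t2 = tune_hyperparameters(_Wrap, grid, X, y, folds=5, seed=3)
    assert b1 == b2
    assert t1["cv_error"].tolist() == t2["cv_error"].tolist()


def test_tuning_prefers_well_scaled_gamma():
    X, y = make_moons(n_samples=200, noise=0.2, random_state=1)
    good = SvmConfig(gamma=1.0, cost=1.0)
    bad = SvmConfig(gamma=100.0, cost=1.0)  # 100x mis-scaled kernel width
    _, table = tune_hyperparameters(_Wrap, [good, bad], X, y, folds=10, seed=0)
    errs = dict(zip(table["config"], table["cv_error"]))
    assert errs[good] <= errs[bad]


def test_tuning_empty_grid_rejected():
    with pytest.raises(ValueError, match="empty"):
        tune_hyperparameters(_Wrap, [], np.zeros((10, 2)), np.r_[np.zeros(5), np.ones(5)])


def _builder_fixture():
    cfg = SimulationConfig(
        seed=13, n_individuals=120, n_pedigrees=6, n_snps=20, n_causal=2,
        causal_log_odds=1.5, n_rare_causal=0, n_ld_tagged=0, n_perfect_duplicates=0,
    )
    cohorts = __import__("permclass.simulate", fromlist=["simulate_replicates"]).simulate_replicates(cfg, 2)
    return cohorts


def test_feature_builder_freeze_and_no_leakage():
    train, test = _builder_fixture()
    builder = FeatureBuilder().fit(train, snp_ids=train.snp_ids[:4])
    frozen = builder.state_hash()
    X_train = builder.transform(train)
    X_test = builder.transform(test, standardize=True)
    assert builder.state_hash() == frozen  # transforming never mutates the maps
    assert list(X_test.columns) == builder.feature_names
    assert "const" in X_train.columns
    # standardization constants come from training data
    X_train_std = builder.transform(train, standardize=True)
    np.testing.assert_allclose(X_train_std.mean(axis=0), 0.0, atol=1e-12)


def test_feature_builder_covariates_only_at_k_zero():
    train, _ = _builder_fixture()
    builder = FeatureBuilder().fit(train, snp_ids=[])
    names = builder.feature_names
    assert all(not n.startswith("snp") for n in names)
    assert {"smoke", "age", "sex", "age_sex"} <= set(names)


def test_unseen_genotype_token_maps_to_ns():
    train, test = _builder_fixture()
    snp = train.snp_ids[0]
    builder = FeatureBuilder(collapse=False).fit(train, snp_ids=[snp])
    mutated = test.genotypes.copy()
    mutated.loc[mutated.index[0], snp] = "GG"  # token absent from training
    cohort = Cohort(phenotypes=test.phenotypes, genotypes=mutated)
    X = builder.transform(cohort)
    ind = mutated.index[0]
    rows = cohort.phenotypes["individual_id"] == ind
    snp_cols = [c for c in X.columns if c.startswith(f"{snp}[")]
    assert X.loc[rows.to_numpy(), snp_cols].to_numpy().sum() == 0.0


def test_rare_carrier_indicator_column():
    train, _ = _builder_fixture()
    snp = train.snp_ids[1]
    tokens = train.genotypes[snp]
    carrier_tok = tokens.value_counts().index[-1]
    builder = FeatureBuilder().fit(train, snp_ids=[], rare_carriers={snp: carrier_tok})
    X = builder.transform(train)
    col = f"{snp}[carrier:{carrier_tok}]"
    expected = (
        train.genotypes[snp].reindex(train.phenotypes["individual_id"]) == carrier_tok
    ).sum()
    assert X[col].sum() == expected
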