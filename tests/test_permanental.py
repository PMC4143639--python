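"""Alpha-permanent engine and permanental membership scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from permclass.permanental import (
    MAX_EXACT_N,
    MembershipScores,
    PermanentalClassifier,
    PermanentalConfig,
    alpha_permanent,
    alpha_permanent_bruteforce,
    kernel_matrix,
    membership_scores,
    permanental_predict,
)


def rising_factorial(alpha: float, n: int) -> float:
    out = 1.0
    for i in range(n):
        out *= alpha + i
    return out


@pytest.mark.parametrize("n", range(1, 9))
@pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 3.3])
def test_all_ones_matrix_matches_rising_factorial(n, alpha):
    value = alpha_permanent(np.ones((n, n)), alpha)
    assert value == pytest.approx(rising_factorial(alpha, n), rel=1e-12)


@pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
def test_diagonal_matrix_closed_form(alpha):
    d = np.array([2.0, 3.0, 0.5, 4.0])
    assert alpha_permanent(np.diag(d), alpha) == pytest.approx(
        alpha ** len(d) * np.prod(d), rel=1e-12
    )


@given(st.integers(2, 7), st.floats(0.3, 4.0), st.integers(0, 10_000))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_engine_equals_permutation_oracle(n, alpha, seed):
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.01, 1.0, size=(n, n))
    exact = alpha_permanent(A, alpha)
    oracle = alpha_permanent_bruteforce(A, alpha)
    assert exact == pytest.approx(oracle, rel=1e-10)


def test_engine_input_validation():
    with pytest.raises(ValueError, match="square"):
        alpha_permanent(np.ones((2, 3)), 1.0)
    with pytest.raises(ValueError, match="positive"):
        alpha_permanent(np.ones((2, 2)), 0.0)
    with pytest.raises(ValueError, match="subset approximation"):
        alpha_permanent(np.ones((MAX_EXACT_N + 1, MAX_EXACT_N + 1)), 1.0)


def test_kernel_matrix_properties():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
    K = kernel_matrix(pts, tau=1.0)
    assert np.allclose(np.diag(K), 1.0)
    assert np.allclose(K, K.T)
    assert K[0, 1] == pytest.approx(np.exp(-1.0))  # distance tau -> e^-1
    # tau -> infinity limit: all entries -> 1
    assert np.allclose(kernel_matrix(pts, tau=1e8), 1.0, atol=1e-10)
    with pytest.raises(ValueError, match="tau"):
        kernel_matrix(pts, tau=0.0)


def test_config_validation():
    with pytest.raises(ValueError):
        PermanentalConfig(alpha=-1.0)
    with pytest.raises(ValueError):
        PermanentalConfig(neighbor_budget=0)
    with pytest.raises(ValueError):
        PermanentalConfig(prior="empirical")


def test_mirror_classes_split_even_and_threshold_is_inclusive():
    """Two classes mirror-symmetric through the query share identical kernel
    geometry, so membership must be exactly 0.5/0.5 and the >= rule labels 1."""
    a = np.array([[1.0, 0.0], [2.0, 1.0], [3.0, -1.0]])
    classes = {0: -a, 1: a}  # mirror through the origin
    cfg = PermanentalConfig(alpha=1.0, tau=2.0, neighbor_budget=5)
    scores = membership_scores(np.zeros(2), classes, cfg)
    assert scores.probabilities[0] == pytest.approx(0.5, abs=1e-14)
    assert scores.probabilities[1] == pytest.approx(0.5, abs=1e-14)
    labels = permanental_predict(np.zeros((1, 2)), classes, cfg)
    assert labels.tolist() == [1]  # probability exactly 0.5 -> class 1


def test_query_on_top_of_one_class():
    """Closed form: a class of n points coincident with the query has
    predictive-intensity ratio per_a(1_{n+1}) / per_a(1_n) = a + n, while a
    class far beyond the kernel range contributes its base intensity a; with
    equal class sizes P(near) = (a + n) / (2a + n)."""
    near = np.zeros((5, 2))
    far = near + 50.0  # >> 10 tau away
    for alpha, expected in ((1.0, 6.0 / 7.0), (0.1, 5.1 / 5.2)):
        cfg = PermanentalConfig(alpha=alpha, tau=1.0, neighbor_budget=5)
        scores = membership_scores(np.zeros(2), {"A": near, "B": far}, cfg)
        assert scores.probabilities["A"] == pytest.approx(expected, rel=1e-9)
    assert scores.probabilities["A"] > 0.98  # small alpha: near-certainty


def test_single_class_gets_probability_one():
    cfg = PermanentalConfig()
    scores = membership_scores(
        np.zeros(2), {"only": np.array([[1.0, 1.0], [2.0, 0.0]])}, cfg
    )
    assert scores.probabilities["only"] == pytest.approx(1.0)
    assert isinstance(scores, MembershipScores) and scores.neighbor_budget == 10


def test_membership_invariant_to_point_order_and_label_swap():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(6, 3))
    b = rng.normal(size=(5, 3)) + 1.0
    q = rng.normal(size=3)
    cfg = PermanentalConfig(alpha=2.0, tau=1.5, neighbor_budget=6)
    base = membership_scores(q, {0: a, 1: b}, cfg).probabilities
    shuffled = membership_scores(q, {0: a[::-1], 1: b[[3, 1, 4, 0, 2]]}, cfg).probabilities
    assert shuffled[0] == pytest.approx(base[0], rel=1e-10)
    swapped = membership_scores(q, {0: b, 1: a}, cfg).probabilities
    assert swapped[1] == pytest.approx(base[0], rel=1e-10)


def test_probability_monotone_as_query_approaches_class():
    """Moving the query toward a class (its kernel values all nondecreasing,
    the other class fixed far away) never decreases that class's probability."""
    a = np.array([[0.0], [0.3], [-0.3]])
    b = np.array([[30.0], [30.5], [29.5]])
    cfg = PermanentalConfig(alpha=1.0, tau=1.0, neighbor_budget=5)
    probs = [
        membership_scores(np.array([x]), {0: a, 1: b}, cfg).probabilities[0]
        for x in (10.0, 6.0, 3.0, 1.0, 0.0)
    ]
    assert all(q >= p - 1e-12 for p, q in zip(probs, probs[1:]))


def test_validation_errors():
    cfg = PermanentalConfig()
    with pytest.raises(ValueError, match="class"):
        membership_scores(np.zeros(2), {}, cfg)
    with pytest.raises(ValueError, match="no training points"):
        membership_scores(np.zeros(2), {0: np.empty((0, 2))}, cfg)
    with pytest.raises(ValueError, match="dimension"):
        membership_scores(np.zeros(3), {0: np.zeros((2, 2)), 1: np.ones((2, 2))}, cfg)
    with pytest.raises(ValueError, match="budget"):
        membership_scores(
            np.zeros(1),
            {0: np.zeros((20, 1)), 1: np.ones((20, 1))},
            PermanentalConfig(neighbor_budget=16),
        )


def test_classifier_separates_two_gaussian_clusters():
    rng = np.random.default_rng(1)
    x0 = rng.normal(0.0, 1.0, size=(100, 2))
    x1 = rng.normal(3.0, 1.0, size=(100, 2))  # 3-sigma separation
    X = np.vstack([x0, x1])
    y = np.r_[np.zeros(100, int), np.ones(100, int)]
    model = PermanentalClassifier(PermanentalConfig(alpha=1.0, tau=1.0)).fit(X, y)
    training_error = np.mean(model.predict(X) != y)
    assert training_error < 0.15
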