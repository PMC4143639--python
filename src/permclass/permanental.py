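"""Permanental-process classification and the alpha-permanent engine.

The classifier treats the training points of each class as one realization of
a permanental point process with Gaussian covariance

    K(x, x') = exp(-||x - x'||^2 / tau^2),

and scores how naturally a query point x* joins each class's configuration
through the ratio of alpha-permanents

    affinity(class) = per_a(K[S u {x*}]) / per_a(K[S]),

where S is the class's point set and

    per_a(A) = sum over permutations sigma of a^cyc(sigma) * prod_i A[i, sigma(i)]

is the alpha-permanent (cyc = number of cycles; a = 1 recovers the ordinary
matrix permanent).  Class-membership probabilities are the prior-weighted,
normalized affinities.

Computing per_a exactly is #P-hard, so two engines are provided:

* :func:`alpha_permanent` — exact, via a cycle-expansion dynamic program over
  vertex subsets (numba-compiled bitmask DP, O(3^n); n <= 14);
* :func:`alpha_permanent_bruteforce` — the all-permutations cycle-counting
  oracle, kept deliberately naive as an independent correctness reference
  for small n.

For prediction, each query restricts every class to its ``neighbor_budget``
most similar training points (largest kernel value, ties by training index),
which keeps the exact engine feasible per query.  With kernel entries in
(0, 1] and unit diagonal, per_a is bounded between a^n and the rising
factorial a(a+1)...(a+n-1), so the ratio is computed safely in linear space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from numba import njit

__all__ = [
    "MAX_EXACT_N",
    "PermanentalConfig",
    "MembershipScores",
    "kernel_matrix",
    "alpha_permanent",
    "alpha_permanent_bruteforce",
    "membership_scores",
    "permanental_predict",
    "PermanentalClassifier",
]

#: largest matrix size the exact subset DP accepts
MAX_EXACT_N = 14


@dataclass(frozen=True)
class PermanentalConfig:
    """Hyperparameters of the permanental classifier.

    alpha
        Process parameter a > 0 (cycle weight of the alpha-permanent).
    tau
        Length scale of the Gaussian covariance, in units of the
        (standardized) feature space.
    neighbor_budget
        Max training points per class entering the per-query permanent; the
        exact engine bounds the usable budget at ``MAX_EXACT_N - 1``.
    prior
        "proportional" (class prior ~ class size, the default) or "uniform".
    """

    alpha: float = 1.0
    tau: float = 1.0
    neighbor_budget: int = 10
    prior: str = "proportional"

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not 1 <= self.neighbor_budget <= 20:
            raise ValueError("neighbor_budget must be in 1..20")
        if self.prior not in ("proportional", "uniform"):
            raise ValueError("prior must be 'proportional' or 'uniform'")


@dataclass
class MembershipScores:
    """Per-class membership probabilities with the provenance that made them."""

    probabilities: dict
    alpha: float
    tau: float
    neighbor_budget: int


def kernel_matrix(points: np.ndarray, tau: float) -> np.ndarray:
    """Gaussian covariance matrix K[i, j] = exp(-||x_i - x_j||^2 / tau^2)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    sq = np.sum(pts**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * pts @ pts.T, 0.0)
    return np.exp(-d2 / tau**2)


def _cross_kernel(query: np.ndarray, points: np.ndarray, tau: float) -> np.ndarray:
    d2 = np.sum((points - query[None, :]) ** 2, axis=1)
    return np.exp(-d2 / tau**2)


@njit(cache=True)
def _subset_permanents(A: np.ndarray, alpha: float) -> np.ndarray:  # pragma: no cover
    """f[S] = per_alpha(A restricted to vertex subset S), for every bitmask S.

    Cycle expansion: peeling the cycle through the lowest vertex of S gives
        f[S] = sum over V (lowest vertex of S in V, V subset of S)
               alpha * C[V] * f[S \\ V],
    where C[V] is the total weight of simple cycles with support exactly V.
    C is filled first by a path DP anchored at each subset's lowest vertex.
    """
    n = A.shape[0]
    full = 1 << n
    C = np.zeros(full)
    for m in range(n):
        C[1 << m] = A[m, m]
        r = n - m - 1  # vertices above the anchor, relabeled 0..r-1
        if r == 0:
            continue
        g = np.zeros(((1 << r), r))
        for t in range(r):
            g[1 << t, t] = A[m, m + 1 + t]
        for U in range(1, 1 << r):
            s = 0.0
            for t in range(r):
                if U >> t & 1:
                    w = g[U, t]
                    if w != 0.0:
                        s += w * A[m + 1 + t, m]
                        for t2 in range(r):
                            if not (U >> t2 & 1):
                                g[U | (1 << t2), t2] += w * A[m + 1 + t, m + 1 + t2]
            C[(U << (m + 1)) | (1 << m)] = s

    f = np.zeros(full)
    f[0] = 1.0
    for S in range(1, full):
        m = 0
        while not (S >> m & 1):
            m += 1
        mbit = 1 << m
        rem = S ^ mbit
        total = 0.0
        W = rem
        while True:
            V = W | mbit
            c = C[V]
            if c != 0.0:
                total += alpha * c * f[S ^ V]
            if W == 0:
                break
            W = (W - 1) & rem
        f[S] = total
    return f


def alpha_permanent(matrix: np.ndarray, alpha: float) -> float:
    """Exact alpha-permanent of a square matrix (n <= 14).

    Bit-reproducible subset-DP evaluation of
    ``per_a(A) = sum_sigma a^cyc(sigma) prod_i A[i, sigma(i)]``.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("alpha_permanent needs a square matrix")
    if A.shape[0] < 1:
        raise ValueError("matrix must have size >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if A.shape[0] > MAX_EXACT_N:
        raise ValueError(
            f"exact engine limited to n <= {MAX_EXACT_N}; use the neighbor-budget "
            "subset approximation (membership_scores) for larger point sets"
        )
    return float(_subset_permanents(A, float(alpha))[-1])


def alpha_permanent_bruteforce(matrix: np.ndarray, alpha: float) -> float:
    """All-permutations cycle-counting oracle (independent of the DP engine)."""
    A = np.asarray(matrix, dtype=float)
    n = A.shape[0]
    if n > 9:
        raise ValueError("brute-force oracle limited to n <= 9")
    total = 0.0
    for sigma in itertools.permutations(range(n)):
        prod = 1.0
        for i in range(n):
            prod *= A[i, sigma[i]]
        seen = [False] * n
        cycles = 0
        for i in range(n):
            if not seen[i]:
                cycles += 1
                j = i
                while not seen[j]:
                    seen[j] = True
                    j = sigma[j]
        total += alpha**cycles * prod
    return total


def _class_affinity(
    query: np.ndarray,
    points: np.ndarray,
    config: PermanentalConfig,
) -> float:
    """per_a(K over nearest subset + query) / per_a(K over nearest subset)."""
    k = _cross_kernel(query, points, config.tau)
    m = min(config.neighbor_budget, len(points))
    order = np.argsort(-k, kind="stable")[:m]  # ties broken by training index
    sel = points[order]
    n = m + 1
    if n > MAX_EXACT_N:
        raise ValueError(
            f"neighbor_budget {config.neighbor_budget} exceeds the exact engine "
            f"limit (budget <= {MAX_EXACT_N - 1})"
        )
    B = np.empty((n, n))
    B[:m, :m] = kernel_matrix(sel, config.tau)
    B[m, :m] = B[:m, m] = k[order]
    B[m, m] = 1.0
    f = _subset_permanents(B, float(config.alpha))
    with_query = f[(1 << n) - 1]
    without_query = f[(1 << m) - 1]
    return with_query / without_query


def membership_scores(
    query: np.ndarray,
    classes: Mapping,
    config: PermanentalConfig,
) -> MembershipScores:
    """Class-membership probabilities for one query point.

    ``classes`` maps class label -> (n_points x dim) training array.  Every
    class must be nonempty and share the query's dimension.  Probabilities
    are prior-weighted normalized affinities and sum to one.
    """
    query = np.asarray(query, dtype=float).ravel()
    labels = list(classes)
    if not labels:
        raise ValueError("need at least one class")
    sizes = {}
    affinities = {}
    for label in labels:
        pts = np.atleast_2d(np.asarray(classes[label], dtype=float))
        if pts.shape[0] == 0:
            raise ValueError(f"class {label!r} has no training points")
        if pts.shape[1] != query.shape[0]:
            raise ValueError("dimension mismatch between query and class points")
        sizes[label] = pts.shape[0]
        affinities[label] = _class_affinity(query, pts, config)
    total_size = sum(sizes.values())
    if config.prior == "proportional":
        priors = {lab: sizes[lab] / total_size for lab in labels}
    else:
        priors = {lab: 1.0 / len(labels) for lab in labels}
    weighted = {lab: priors[lab] * affinities[lab] for lab in labels}
    norm = sum(weighted.values())
    probs = {lab: weighted[lab] / norm for lab in labels}
    return MembershipScores(
        probabilities=probs,
        alpha=config.alpha,
        tau=config.tau,
        neighbor_budget=config.neighbor_budget,
    )


def permanental_predict(
    queries: np.ndarray,
    classes: Mapping,
    config: PermanentalConfig,
    threshold: float = 0.5,
) -> np.ndarray:
    """Binary labels for queries: 1 iff P(class 1) >= threshold."""
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    out = np.empty(len(queries), dtype=int)
    for i, q in enumerate(queries):
        probs = membership_scores(q, classes, config).probabilities
        out[i] = 1 if probs.get(1, 0.0) >= threshold else 0
    return out


class PermanentalClassifier:
    """Sklearn-style wrapper: fit stores per-class point sets, predict scores
    each query with :func:`membership_scores`."""

    def __init__(self, config: PermanentalConfig | None = None, **kw) -> None:
        self.config = config if config is not None else PermanentalConfig(**kw)
        self.classes_: dict | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PermanentalClassifier":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        labels = np.unique(y)
        if len(labels) < 2:
            raise ValueError("need at least two classes to fit")
        self.classes_ = {int(lab): X[y == lab] for lab in labels}
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(class 1) per query (binary use)."""
        if self.classes_ is None:
            raise RuntimeError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array(
            [
                membership_scores(q, self.classes_, self.config).probabilities[1]
                for q in X
            ]
        )

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)
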