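"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from guttmap import ResponseMatrix


def h_pair_covariance_oracle(x_a, x_b, w=None):
    """Loevinger h for a dichotomous item pair via cov/cov_max.

    Independent of the Guttman-error counting path: computes the
    (weighted) covariance of the two indicators from the joint table and
    divides by its maximum given the margins, cov_max = p_hard(1 - p_easy).
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    w = np.ones(len(x_a)) if w is None else np.asarray(w, dtype=float)
    W = w.sum()
    pa = w @ x_a / W
    pb = w @ x_b / W
    cov = w @ (x_a * x_b) / W - pa * pb
    p_easy, p_hard = (pa, pb) if pa >= pb else (pb, pa)
    cov_max = p_hard * (1.0 - p_easy)
    return cov / cov_max


def h_pair_polytomous_oracle(x_a, x_b, m_a, m_b, w=None):
    """cov/cov_max oracle for polytomous scores with steps 1..m."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    w = np.ones(len(x_a)) if w is None else np.asarray(w, dtype=float)
    W = w.sum()
    cov = w @ (x_a * x_b) / W - (w @ x_a / W) * (w @ x_b / W)
    cov_max = 0.0
    for s in range(1, m_a + 1):
        ps = w @ (x_a >= s) / W
        for t in range(1, m_b + 1):
            pt = w @ (x_b >= t) / W
            p_easy, p_hard = (ps, pt) if ps >= pt else (pt, ps)
            cov_max += p_hard * (1.0 - p_easy)
    return cov / cov_max


def random_dichotomous_matrix(rng, n=200, k=5, p_range=(0.2, 0.8)):
    """Bernoulli response matrix with non-degenerate columns."""
    p = rng.uniform(*p_range, size=k)
    values = (rng.uniform(size=(n, k)) < p).astype(np.int64)
    # regenerate any constant column so every pair is defined
    for j in range(k):
        while values[:, j].min() == values[:, j].max():
            values[:, j] = (rng.uniform(size=n) < p[j]).astype(np.int64)
    return ResponseMatrix(values, [f"i{j + 1}" for j in range(k)])


@pytest.fixture
def pair_example():
    """10 respondents, 2 items: (1,1)x3, (1,0)x4, (0,1)x1, (0,0)x2.

    Hand enumeration of the four cells gives F = 1 (the single (0,1)
    pattern), E = 10 * 0.3 * 0.4 = 1.2, hence e = 83.333% and
    h = 1 - 1/1.2 = 1/6.
    """
    values = np.array([[1, 1]] * 3 + [[1, 0]] * 4 + [[0, 1]] + [[0, 0]] * 2)
    return ResponseMatrix(values, ["A", "B"])


@pytest.fixture
def perfect_guttman():
    """Deterministic scalogram: (1,1)x4, (1,0)x3, (0,0)x3 — no errors."""
    values = np.array([[1, 1]] * 4 + [[1, 0]] * 3 + [[0, 0]] * 3)
    return ResponseMatrix(values, ["A", "B"])


@pytest.fixture
def independent_items():
    """Exactly independent pair: all four patterns 25 times each."""
    values = np.array(
        [[1, 1]] * 25 + [[1, 0]] * 25 + [[0, 1]] * 25 + [[0, 0]] * 25
    )
    return ResponseMatrix(values, ["A", "B"])
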