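import numpy as np
import pytest

from dcbiclust import Bicluster, ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 conditions with simple integer values."""
    values = np.arange(12, dtype=float).reshape(3, 4)
    return ExpressionMatrix(values, ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"])


@pytest.fixture
def small_bicluster() -> Bicluster:
    return Bicluster(frozenset({"g1", "g2"}), frozenset({"c1", "c2"}), "algA", 1)


def lstsq_additive_fit(X: np.ndarray):
    """Independent oracle: least-squares fit of the additive two-way model.

    Builds the full design matrix for mu, tau_i, beta_j with sum-to-zero
    constraints imposed by dropping the last level and back-substituting,
    and solves with a generic dense solver.  Returns (mu, tau, beta,
    residuals).
    """
    I, J = X.shape
    n = I * J
    # columns: mu, tau_1..tau_{I-1}, beta_1..beta_{J-1}; last levels are
    # minus the sum of the others (sum-to-zero coding)
    D = np.zeros((n, 1 + (I - 1) + (J - 1)))
    y = X.ravel()
    for i in range(I):
        for j in range(J):
            r = i * J + j
            D[r, 0] = 1.0
            if i < I - 1:
                D[r, 1 + i] = 1.0
            else:
                D[r, 1 : I] = -1.0
            if j < J - 1:
                D[r, I + j] = 1.0
            else:
                D[r, I : I + J - 1] = -1.0
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    mu = coef[0]
    tau = np.append(coef[1:I], -coef[1:I].sum())
    beta = np.append(coef[I:], -coef[I:].sum())
    resid = X - mu - tau[:, None] - beta[None, :]
    return mu, tau, beta, resid
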