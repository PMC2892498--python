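"""Two-way additive decomposition of an expression submatrix.

For one condition group the log-expression of gene i in condition j is
modelled additively as

    X_ij = mu + tau_i + beta_j + eps_ij,   eps_ij ~ iid N(0, sigma^2),

with the usual identifiability constraints sum_i tau_i = 0 and
sum_j beta_j = 0.  Under these constraints the least-squares estimates are
closed-form: mu_hat is the grand mean, tau_hat_i the row-mean deviation,
beta_hat_j the column-mean deviation, and the residuals are the doubly
centred matrix.  The residual score

    E = sum_ij r_ij^2 / ((I-1)(J-1))

uses the residual degrees of freedom so that E is an unbiased estimator of
sigma^2 — the premise the bias-corrected co-expression components rest on.
A plain-mean denominator I*J (the Cheng-Church mean squared residue
convention) is available via ``denominator="n"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DegenerateFitError

__all__ = ["TwoWayFit", "fit_two_way_model", "impute_additive"]


@dataclass(frozen=True)
class TwoWayFit:
    """Least-squares fit of the additive two-way model to one I x J submatrix."""

    mu_hat: float
    tau_hat: np.ndarray  # length I, sums to 0
    beta_hat: np.ndarray  # length J, sums to 0
    residuals: np.ndarray  # I x J, rows and columns each sum to 0
    E: float  # residual variance estimate, >= 0
    I: int
    J: int

    def reconstruct(self) -> np.ndarray:
        """mu_hat + tau_hat_i + beta_hat_j + residual_ij, equal to the input."""
        return (
            self.mu_hat
            + self.tau_hat[:, None]
            + self.beta_hat[None, :]
            + self.residuals
        )


def fit_two_way_model(submatrix, denominator: str = "df") -> TwoWayFit:
    """Fit the additive two-way model to a submatrix of one condition group.

    Parameters
    ----------
    submatrix : array-like, shape (I, J)
        Log-expression of the bicluster genes over the group's conditions.
        Requires I >= 2 and J >= 2 so the residual degrees of freedom
        (I-1)(J-1) are at least 1.
    denominator : {"df", "n"}
        ``"df"`` (default) divides the residual sum of squares by
        (I-1)(J-1), making E unbiased for the noise variance.  ``"n"``
        divides by I*J (mean squared residue).

    Returns
    -------
    TwoWayFit

    Raises
    ------
    DegenerateFitError
        If I < 2 or J < 2.
    DataError
        If the submatrix contains non-finite values.
    """
    X = np.asarray(submatrix, dtype=float)
    if X.ndim != 2:
        raise DataError(f"submatrix must be 2-D, got shape {X.shape}")
    I, J = X.shape
    if I < 2 or J < 2:
        raise DegenerateFitError(
            f"two-way fit needs at least 2 genes and 2 conditions, got {I} x {J}"
        )
    if not np.all(np.isfinite(X)):
        raise DataError("submatrix contains non-finite values")
    if denominator not in ("df", "n"):
        raise ValueError(f"denominator must be 'df' or 'n', got {denominator!r}")

    grand = X.mean()
    tau = X.mean(axis=1) - grand
    beta = X.mean(axis=0) - grand
    resid = X - grand - tau[:, None] - beta[None, :]
    ss = float(np.sum(resid * resid))
    denom = (I - 1) * (J - 1) if denominator == "df" else I * J
    return TwoWayFit(
        mu_hat=float(grand),
        tau_hat=tau,
        beta_hat=beta,
        residuals=resid,
        E=ss / denom,
        I=I,
        J=J,
    )


def impute_additive(values: np.ndarray) -> np.ndarray:
    """Fill NaN cells with row mean + column mean - grand mean over observed cells.

    The additive fill is deliberately the model's own prediction, so imputed
    cells contribute no residual of their own and cannot inflate apparent
    co-expression.  Rows or columns with no observed value at all are an error.
    """
    X = np.array(values, dtype=float)
    mask = np.isfinite(X)
    if mask.all():
        return X
    if not mask.any():
        raise DataError("cannot impute: no observed values")
    row_ok = mask.any(axis=1)
    col_ok = mask.any(axis=0)
    if not row_ok.all() or not col_ok.all():
        raise DataError("cannot impute: a row or column has no observed values")
    grand = X[mask].mean()
    with np.errstate(invalid="ignore"):
        row_means = np.nanmean(X, axis=1)
        col_means = np.nanmean(X, axis=0)
    fill = row_means[:, None] + col_means[None, :] - grand
    X[~mask] = fill[~mask]
    return X
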