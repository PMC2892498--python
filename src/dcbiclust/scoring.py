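"""Differential co-expression scoring and stratification of biclusters.

From a two-way fit of each condition group (G1 = bicluster conditions,
G2 = the rest) we derive two co-expression components:

    T_k = (1/I) sum_i tau_hat_ik^2  -  E_k (I-1)/(I J_k)     (gene effects)
    B_k = (1/J_k) sum_j beta_hat_jk^2 - E_k (J_k-1)/(I J_k)  (condition effects)

The subtracted terms remove the noise contribution of the effect estimates,
so that under iid N(0, sigma^2) noise T_k and B_k are unbiased for the mean
squared true gene and condition effects (and have expectation 0 when no
effects are present).  Negative values therefore signal an effect estimate
below the noise floor and are clipped at 0 wherever a component enters a
ratio.

The goodness score compares the two groups,

    SB(b) = ln( (T1+ + B1+ + a) / (T2+ + B2+ + a) ),   x+ = max(x, 0),

with a small fudge factor a > 0 damping ratios of near-zero co-expression.
Strongly positive SB means co-expression confined to the bicluster
conditions; near-zero SB means comparable (global) co-expression in both
groups, which disqualifies the gene set as a bicluster.  Within the group
declared co-expressed (k = 1 if SB > 0, else 2), the stratification score

    TS_k(b) = ln( (T_k+ + a) / (B_k+ + a) )

separates T-type (TS > phi: gene effects only), B-type (TS < -phi:
condition effects only) and mu-type (|TS| <= phi: strong gene and
condition effects together) co-expression.  The printed default is phi = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import NotScorableError, ParameterError
from .matrix import Bicluster, ExpressionMatrix, partition_matrix
from .model import TwoWayFit, fit_two_way_model

__all__ = [
    "CoexpressionComponents",
    "BiclusterAssessment",
    "coexpression_components",
    "differential_coexpression_score",
    "stratification_score",
    "classify_bicluster",
    "kostka_spang_score",
    "assess_bicluster",
    "DEFAULT_FUDGE",
    "DEFAULT_PHI",
]

DEFAULT_FUDGE = 0.01
DEFAULT_PHI = 1.0

_E_FLOOR = 1e-12  # guards the error-ratio score on perfectly additive submatrices


@dataclass(frozen=True)
class CoexpressionComponents:
    """Bias-corrected gene-effect (T) and condition-effect (B) co-expression.

    T and B may be negative: they estimate nonnegative population mean
    squared effects, and negativity indicates the estimate fell below the
    noise level.
    """

    T: float
    B: float
    E: float
    I: int
    J: int


def coexpression_components(fit: TwoWayFit) -> CoexpressionComponents:
    """Compute T and B from a two-way fit, with the noise bias removed."""
    I, J = fit.I, fit.J
    T = float(np.mean(fit.tau_hat**2)) - fit.E * (I - 1) / (I * J)
    B = float(np.mean(fit.beta_hat**2)) - fit.E * (J - 1) / (I * J)
    return CoexpressionComponents(T=T, B=B, E=fit.E, I=I, J=J)


def _check_fudge(a: float) -> None:
    if not (a > 0):
        raise ParameterError(f"fudge factor a must be > 0, got {a}")


def differential_coexpression_score(
    c1: CoexpressionComponents, c2: CoexpressionComponents, a: float = DEFAULT_FUDGE
) -> float:
    """Goodness score SB: log-ratio of total co-expression in G1 vs G2."""
    _check_fudge(a)
    num = max(c1.T, 0.0) + max(c1.B, 0.0) + a
    den = max(c2.T, 0.0) + max(c2.B, 0.0) + a
    # log difference (not log of the quotient) so group exchange negates
    # the score bit-exactly
    return math.log(num) - math.log(den)


def stratification_score(c: CoexpressionComponents, a: float = DEFAULT_FUDGE) -> float:
    """Stratification score TS: log-ratio of gene-effect to condition-effect strength."""
    _check_fudge(a)
    return math.log((max(c.T, 0.0) + a) / (max(c.B, 0.0) + a))


def classify_bicluster(TS: float, phi: float = DEFAULT_PHI) -> str:
    """Map a stratification score to a co-expression type.

    Returns ``"T"`` if TS > phi, ``"B"`` if TS < -phi, else ``"mu"``
    (ties at |TS| == phi fall in the closed mu band, for determinism).
    """
    if not (phi > 0):
        raise ParameterError(f"phi must be > 0, got {phi}")
    if TS > phi:
        return "T"
    if TS < -phi:
        return "B"
    return "mu"


def kostka_spang_score(E1: float, E2: float) -> float:
    """Error-variance ratio score ln(E2/E1), an optional alternative ranking.

    Oriented so that a larger score means a tighter additive fit in the
    bicluster conditions.  Errors are floored at 1e-12 to keep perfectly
    additive submatrices scorable.
    """
    if E1 < 0 or E2 < 0:
        raise NotScorableError("error variances must be nonnegative")
    return math.log(max(E2, _E_FLOOR) / max(E1, _E_FLOOR))


@dataclass(frozen=True)
class BiclusterAssessment:
    """Full differential co-expression assessment of one bicluster."""

    bicluster: Bicluster
    components_g1: CoexpressionComponents
    components_g2: CoexpressionComponents
    SB: float
    TS: float
    group_used: int  # 1 if SB > 0, 2 if SB < 0; 1 with type "unclassified" at SB == 0
    coexpression_type: str  # "T" | "B" | "mu" | "unclassified"
    fudge_a: float
    phi: float

    @property
    def kostka_spang(self) -> float:
        return kostka_spang_score(self.components_g1.E, self.components_g2.E)


def assess_bicluster(
    matrix: ExpressionMatrix,
    bicluster: Bicluster,
    a: float = DEFAULT_FUDGE,
    phi: float = DEFAULT_PHI,
    denominator: str = "df",
) -> BiclusterAssessment:
    """Partition, fit both groups, and score one bicluster end to end.

    Raises
    ------
    NotScorableError
        If the bicluster spans fewer than 2 genes or conditions, or leaves
        fewer than 2 non-bicluster conditions (J2 < 2) — in the latter case
        the gene set's co-expression is a global effect and cannot be
        tested differentially.
    """
    _check_fudge(a)
    if not (phi > 0):
        raise ParameterError(f"phi must be > 0, got {phi}")
    part = partition_matrix(matrix, bicluster)
    ident = f"bicluster {bicluster.label!r}"
    if part.X1.shape[0] < 2:
        raise NotScorableError(f"{ident}: fewer than 2 genes")
    if part.X1.shape[1] < 2:
        raise NotScorableError(f"{ident}: fewer than 2 bicluster conditions")
    if part.degenerate_g2:
        raise NotScorableError(
            f"{ident}: fewer than 2 non-bicluster conditions; "
            "co-expression of the gene set is a global effect and cannot be tested"
        )
    c1 = coexpression_components(fit_two_way_model(part.X1, denominator=denominator))
    c2 = coexpression_components(fit_two_way_model(part.X2, denominator=denominator))
    SB = differential_coexpression_score(c1, c2, a)
    if SB > 0:
        group, comp = 1, c1
    elif SB < 0:
        group, comp = 2, c2
    else:  # exact tie: report G1's stratification but leave the type open
        group, comp = 1, c1
    TS = stratification_score(comp, a)
    ctype = classify_bicluster(TS, phi) if SB != 0 else "unclassified"
    return BiclusterAssessment(
        bicluster=bicluster,
        components_g1=c1,
        components_g2=c2,
        SB=SB,
        TS=TS,
        group_used=group,
        coexpression_type=ctype,
        fudge_a=a,
        phi=phi,
    )
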