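"""Expression-matrix and bicluster containers.

An :class:`ExpressionMatrix` holds log-scale expression values for genes
(rows) over conditions (columns); it is the universe from which biclusters
draw their gene and condition subsets.  A :class:`Bicluster` is a gene
subset plus a condition subset with provenance (which algorithm produced it
and at what rank).  :func:`partition_matrix` splits the matrix columns into
the bicluster conditions (group G1) and the complementary, non-bicluster
conditions (group G2), keeping the bicluster's genes as rows of both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, IdentifierError

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "Bicluster", "BiclusterPartition", "partition_matrix"]


class ExpressionMatrix:
    """Log-expression values with gene and condition identifiers.

    Parameters
    ----------
    values : array-like, shape (n_genes, n_conditions)
        Log-scale expression values.  All entries must be finite unless
        ``allow_nonfinite=True`` (used internally by the imputing reader).
    gene_ids, condition_ids : sequences of str
        Unique row and column identifiers, matched case-sensitively.
    """

    def __init__(
        self,
        values,
        gene_ids: Sequence[str],
        condition_ids: Sequence[str],
        *,
        allow_nonfinite: bool = False,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise DataError(f"expression values must be 2-D, got shape {values.shape}")
        gene_ids = [str(g) for g in gene_ids]
        condition_ids = [str(c) for c in condition_ids]
        if values.shape != (len(gene_ids), len(condition_ids)):
            raise DataError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(gene_ids)} gene ids x {len(condition_ids)} condition ids"
            )
        for label, ids in (("gene", gene_ids), ("condition", condition_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise DataError(f"duplicate {label} id: {dup!r}")
        if not allow_nonfinite and not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite value at gene {gene_ids[i]!r}, condition "
                f"{condition_ids[j]!r}; use the impute policy to fill missing cells"
            )
        self.values = values
        self.gene_ids = gene_ids
        self.condition_ids = condition_ids
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}
        self._condition_index = {c: j for j, c in enumerate(condition_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_indices(self, ids: Iterable[str]) -> list[int]:
        """Row indices of ``ids`` in matrix order; unknown id raises IdentifierError."""
        missing = [g for g in ids if g not in self._gene_index]
        if missing:
            raise IdentifierError(f"unknown gene id(s): {', '.join(sorted(missing))}")
        idx = sorted(self._gene_index[g] for g in set(ids))
        return idx

    def condition_indices(self, ids: Iterable[str]) -> list[int]:
        missing = [c for c in ids if c not in self._condition_index]
        if missing:
            raise IdentifierError(f"unknown condition id(s): {', '.join(sorted(missing))}")
        return sorted(self._condition_index[c] for c in set(ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=self.gene_ids, columns=self.condition_ids)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_conditions} conditions)"


@dataclass(frozen=True)
class Bicluster:
    """A gene subset co-expressed over a condition subset, with provenance.

    ``source_rank`` is the rank the producing algorithm itself assigned
    (1-based); it is preserved through ranking so per-algorithm rank
    distributions can be reported.
    """

    gene_ids: frozenset[str]
    condition_ids: frozenset[str]
    source_algorithm: str = "unknown"
    source_rank: Optional[int] = None
    id: Optional[str] = None

    def __post_init__(self):
        genes = list(self.gene_ids)
        conds = list(self.condition_ids)
        if len(set(genes)) != len(genes):
            logger.warning("bicluster %s: duplicate gene ids deduplicated", self.id)
        if len(set(conds)) != len(conds):
            logger.warning("bicluster %s: duplicate condition ids deduplicated", self.id)
        object.__setattr__(self, "gene_ids", frozenset(str(g) for g in genes))
        object.__setattr__(self, "condition_ids", frozenset(str(c) for c in conds))
        if not self.gene_ids:
            raise DataError(f"bicluster {self.id!r}: empty gene set")
        if not self.condition_ids:
            raise DataError(f"bicluster {self.id!r}: empty condition set")
        if self.source_rank is not None and self.source_rank < 1:
            raise DataError(f"bicluster {self.id!r}: source_rank must be >= 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    @property
    def label(self) -> str:
        """Stable display id: explicit id, else source_algorithm:source_rank."""
        if self.id is not None:
            return self.id
        if self.source_rank is not None:
            return f"{self.source_algorithm}:{self.source_rank}"
        return f"{self.source_algorithm}:?"


@dataclass
class BiclusterPartition:
    """The two submatrices a bicluster induces on the study matrix.

    ``X1`` holds the bicluster genes over the J1 bicluster conditions
    (group G1); ``X2`` holds the same genes, in the same row order, over
    the J2 = M - J1 remaining conditions (group G2).  ``degenerate_g2``
    flags J2 < 2: the partition is still returned for inspection, but
    differential scoring refuses it.
    """

    X1: np.ndarray
    X2: np.ndarray
    gene_ids: list[str]
    g1_condition_ids: list[str]
    g2_condition_ids: list[str]
    degenerate_g2: bool = field(init=False)

    def __post_init__(self):
        if self.X1.shape[0] != self.X2.shape[0]:
            raise DataError("X1 and X2 must share gene rows")
        self.degenerate_g2 = self.X2.shape[1] < 2


def partition_matrix(matrix: ExpressionMatrix, bicluster: Bicluster) -> BiclusterPartition:
    """Split ``matrix`` into the bicluster-conditions and complement submatrices.

    Rows are the bicluster's genes and columns of each part follow the
    parent matrix order, so the output is deterministic for a given matrix.

    Raises
    ------
    IdentifierError
        If the bicluster references a gene or condition absent from the matrix.
    """
    rows = matrix.gene_indices(bicluster.gene_ids)
    g1_cols = matrix.condition_indices(bicluster.condition_ids)
    g1_set = set(g1_cols)
    g2_cols = [j for j in range(matrix.n_conditions) if j not in g1_set]
    return BiclusterPartition(
        X1=matrix.values[np.ix_(rows, g1_cols)],
        X2=matrix.values[np.ix_(rows, g2_cols)] if g2_cols
        else np.empty((len(rows), 0)),
        gene_ids=[matrix.gene_ids[i] for i in rows],
        g1_condition_ids=[matrix.condition_ids[j] for j in g1_cols],
        g2_condition_ids=[matrix.condition_ids[j] for j in g2_cols],
    )
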