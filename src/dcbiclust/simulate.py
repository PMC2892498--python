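"""Synthetic expression matrices with implanted, ground-truth biclusters.

The generator runs the additive model forward: a background of iid
N(0, noise_sd^2) log-expression, plus rectangular implants that add

    mu_shift + tau_i + beta_j

to a gene-block x condition-block region, with tau_i ~ N(0, tau_sd^2) and
beta_j ~ N(0, beta_sd^2) drawn once per implant.  Implant types map onto
the three co-expression types plus two controls:

- ``T``      gene effects only (tau_sd > 0, beta_sd = 0, mu_shift = 0)
- ``B``      condition effects only (beta_sd > 0, tau_sd = 0, mu_shift = 0)
- ``mu``     gene + condition + overall effects (all three nonzero)
- ``global`` the same gene effects extended to ALL conditions (with fresh
             condition effects outside G1): co-expression everywhere, which
             a good bicluster score must NOT reward
- ``null``   a labelled region with no effects at all (pure noise control)

Every draw is deterministic per seed; a dataset's per-implant seeds are
split from the master seed with ``numpy.random.SeedSequence``, so adding an
implant never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import LayoutError, ParameterError
from .matrix import Bicluster, ExpressionMatrix

__all__ = [
    "ImplantSpec",
    "SyntheticDataset",
    "generate_background",
    "implant_bicluster",
    "simulate_dataset",
    "default_spec",
]

IMPLANT_TYPES = ("T", "B", "mu", "global", "null")


@dataclass(frozen=True)
class ImplantSpec:
    """Ground-truth description of one synthetic bicluster.

    ``effect_pattern`` selects how gene effects are drawn: ``"gaussian"``
    (tau_i ~ N(0, tau_sd^2), the default, matching the linear-model
    framework) or ``"signed"`` (tau_i = +/- tau_sd, half the genes induced
    and half repressed — the heatmap-style two-block pattern).

    ``normalize_effects`` recentres each realized effect vector and rescales
    it so its root mean square equals the nominal sd exactly.  This pins the
    realized gene-to-condition effect balance, which the mu-type default
    relies on: with free Gaussian draws the realized ratio of mean squared
    effects fluctuates enough (only J1 condition effects are drawn) that a
    genuinely balanced implant would spill over the |TS| <= phi band in a
    non-negligible fraction of replicates.
    """

    implant_type: str
    n_genes: int
    n_conditions_g1: int
    tau_sd: float = 0.0
    beta_sd: float = 0.0
    mu_shift: float = 0.0
    noise_sd: float = 1.0
    seed: Optional[int] = None
    effect_pattern: str = "gaussian"
    normalize_effects: bool = False

    def __post_init__(self):
        if self.implant_type not in IMPLANT_TYPES:
            raise ParameterError(
                f"implant_type must be one of {IMPLANT_TYPES}, got {self.implant_type!r}"
            )
        if self.n_genes < 1 or self.n_conditions_g1 < 1:
            raise ParameterError("implant block must have at least 1 gene and 1 condition")
        if self.tau_sd < 0 or self.beta_sd < 0 or self.noise_sd <= 0:
            raise ParameterError("tau_sd/beta_sd must be >= 0 and noise_sd > 0")
        if self.effect_pattern not in ("gaussian", "signed"):
            raise ParameterError(f"unknown effect_pattern {self.effect_pattern!r}")
        t = self.implant_type
        if t == "T" and (self.beta_sd != 0 or self.mu_shift != 0):
            raise ParameterError("T-type implant requires beta_sd == 0 and mu_shift == 0")
        if t == "B" and (self.tau_sd != 0 or self.mu_shift != 0):
            raise ParameterError("B-type implant requires tau_sd == 0 and mu_shift == 0")
        if t == "mu" and self.mu_shift == 0:
            raise ParameterError("mu-type implant requires a nonzero mu_shift")
        if t == "null" and (self.tau_sd != 0 or self.beta_sd != 0 or self.mu_shift != 0):
            raise ParameterError("null implant requires all effect magnitudes 0")


def default_spec(
    implant_type: str,
    n_genes: int = 20,
    n_conditions_g1: int = 10,
    effect_sd: float = 2.0,
    noise_sd: float = 1.0,
    seed: Optional[int] = None,
) -> ImplantSpec:
    """Convenience constructor with per-type effect defaults.

    Effect magnitudes default to twice the noise sd — a clearly detectable
    but not overwhelming signal.  The mu-type implant combines gene,
    condition and overall effects of equal magnitude so its stratification
    score sits near zero.
    """
    kw = dict(
        implant_type=implant_type,
        n_genes=n_genes,
        n_conditions_g1=n_conditions_g1,
        noise_sd=noise_sd,
        seed=seed,
    )
    if implant_type == "T":
        return ImplantSpec(tau_sd=effect_sd, **kw)
    if implant_type == "B":
        return ImplantSpec(beta_sd=effect_sd, **kw)
    if implant_type == "mu":
        return ImplantSpec(
            tau_sd=effect_sd,
            beta_sd=effect_sd,
            mu_shift=effect_sd,
            normalize_effects=True,
            **kw,
        )
    if implant_type == "global":
        return ImplantSpec(tau_sd=effect_sd, **kw)
    if implant_type == "null":
        return ImplantSpec(**kw)
    raise ParameterError(f"unknown implant type {implant_type!r}")


@dataclass
class SyntheticDataset:
    """A simulated matrix plus the ground-truth biclusters implanted in it."""

    matrix: ExpressionMatrix
    truth: list[tuple[Bicluster, ImplantSpec]] = field(default_factory=list)


def generate_background(
    n_genes: int, n_conditions: int, noise_sd: float = 1.0, seed: int = 0
) -> ExpressionMatrix:
    """Pure-noise matrix: iid N(0, noise_sd^2), deterministic per seed."""
    if n_genes < 1 or n_conditions < 1:
        raise ParameterError(
            f"matrix must have at least 1 gene and 1 condition, got {n_genes} x {n_conditions}"
        )
    if noise_sd <= 0:
        raise ParameterError(f"noise_sd must be > 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd, size=(n_genes, n_conditions))
    gene_ids = [f"g{i+1}" for i in range(n_genes)]
    condition_ids = [f"c{j+1}" for j in range(n_conditions)]
    return ExpressionMatrix(values, gene_ids, condition_ids)


def implant_bicluster(
    matrix: ExpressionMatrix,
    spec: ImplantSpec,
    gene_offset: int = 0,
    condition_offset: int = 0,
) -> tuple[ExpressionMatrix, Bicluster]:
    """Add one implant block to a copy of ``matrix``; return it with the truth bicluster.

    The block occupies rows ``gene_offset : gene_offset + n_genes`` and
    columns ``condition_offset : condition_offset + n_conditions_g1``.  For
    a ``global`` implant the same gene effects (plus freshly drawn condition
    effects) are additionally applied to every column outside the block, so
    the gene set is co-expressed across all conditions.
    """
    I, J1 = spec.n_genes, spec.n_conditions_g1
    if gene_offset < 0 or condition_offset < 0:
        raise LayoutError("offsets must be nonnegative")
    if gene_offset + I > matrix.n_genes or condition_offset + J1 > matrix.n_conditions:
        raise LayoutError(
            f"implant block {I} x {J1} at ({gene_offset}, {condition_offset}) "
            f"exceeds matrix {matrix.n_genes} x {matrix.n_conditions}"
        )
    rng = np.random.default_rng(spec.seed)

    def _draw(sd: float, size: int) -> np.ndarray:
        if sd == 0:
            return np.zeros(size)
        v = rng.normal(0.0, sd, size=size)
        if spec.normalize_effects:
            v = v - v.mean()
            rms = float(np.sqrt(np.mean(v**2)))
            if rms > 0:
                v *= sd / rms
        return v

    if spec.effect_pattern == "signed" and spec.tau_sd > 0:
        tau = spec.tau_sd * np.where(np.arange(I) < I // 2, 1.0, -1.0)
        if I % 2:  # odd gene count: recentre so the implanted gene effects sum to 0
            tau -= tau.mean()
    else:
        tau = _draw(spec.tau_sd, I)
    beta = _draw(spec.beta_sd, J1)

    values = matrix.values.copy()
    rows = slice(gene_offset, gene_offset + I)
    cols = slice(condition_offset, condition_offset + J1)
    values[rows, cols] += spec.mu_shift + tau[:, None] + beta[None, :]
    if spec.implant_type == "global":
        other = np.ones(matrix.n_conditions, dtype=bool)
        other[cols] = False
        J2 = int(other.sum())
        beta2 = _draw(spec.beta_sd, J2)
        values[rows, other] += spec.mu_shift + tau[:, None] + beta2[None, :]

    truth = Bicluster(
        gene_ids=frozenset(matrix.gene_ids[gene_offset : gene_offset + I]),
        condition_ids=frozenset(matrix.condition_ids[condition_offset : condition_offset + J1]),
        source_algorithm=f"truth-{spec.implant_type}",
    )
    return (
        ExpressionMatrix(values, matrix.gene_ids, matrix.condition_ids),
        truth,
    )


def simulate_dataset(
    n_genes: int,
    n_conditions: int,
    specs: Sequence[ImplantSpec] = (),
    master_seed: int = 0,
) -> SyntheticDataset:
    """Background plus all implants in disjoint diagonal blocks.

    Implants are laid out left-to-right / top-to-bottom in spec order, so
    gene blocks and condition blocks are mutually disjoint by construction.
    Per-implant seeds not set on the spec are split from ``master_seed``
    (SeedSequence child states, masked to 31 bits); the realised specs are
    recorded on the truth list so the dataset regenerates bit-identically.
    """
    need_genes = sum(s.n_genes for s in specs)
    need_conds = sum(s.n_conditions_g1 for s in specs)
    if need_genes > n_genes or need_conds > n_conditions:
        raise LayoutError(
            f"implants need {need_genes} genes x {need_conds} conditions, "
            f"matrix provides {n_genes} x {n_conditions}"
        )
    children = np.random.SeedSequence(master_seed).generate_state(len(specs) + 1) & 0x7FFFFFFF
    noise_sd = specs[0].noise_sd if specs else 1.0
    matrix = generate_background(n_genes, n_conditions, noise_sd, seed=int(children[0]))
    truth: list[tuple[Bicluster, ImplantSpec]] = []
    g_off = c_off = 0
    for k, spec in enumerate(specs):
        if spec.seed is None:
            spec = replace(spec, seed=int(children[k + 1]))
        matrix, bic = implant_bicluster(matrix, spec, g_off, c_off)
        truth.append((bic, spec))
        g_off += spec.n_genes
        c_off += spec.n_conditions_g1
    return SyntheticDataset(matrix=matrix, truth=truth)
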