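# Methods

## Model and estimators

For a bicluster b with gene set I over condition group Gk (k = 1: the J1
bicluster conditions; k = 2: the J2 = M − J1 remaining conditions), the
log-expression is modelled additively,

    X_ijk = mu_k + tau_ik + beta_jk + eps_ijk,  eps_ijk ~ iid N(0, sigma^2),

with the identifiability constraints Σ_i tau_ik = 0 and Σ_j beta_jk = 0.
Under these constraints the least-squares fit is closed-form: mû is the
grand mean, taû_i the row-mean deviations, betâ_j the column-mean
deviations, and the residuals the doubly centred matrix. The fit is
computed independently for G1 and G2 on the same gene rows.

**Residual variance.** E_k divides the residual sum of squares by the
residual degrees of freedom (I−1)(J_k−1), so E[E_k] = sigma² exactly. The
historical mean-squared-residue convention (divide by I·J_k) is available
via `fit_two_way_model(..., denominator="n")`; it is biased low by the
factor (I−1)(J−1)/(IJ) and is provided only for comparability with scores
defined that way.

**Bias-corrected components.** The raw mean squared effect estimates are
inflated by estimation noise: Var(taû_i − tau_i) = sigma²(I−1)/(I·J) and
symmetrically for betâ. Subtracting the plug-in noise terms gives

    T_k = (1/I) Σ taû² − E_k (I−1)/(I·J_k),
    B_k = (1/J_k) Σ betâ² − E_k (J_k−1)/(I·J_k),

which are unbiased for the mean squared centred gene and condition effects
(zero expectation under pure noise). Per-element averaging (1/I, 1/J_k)
keeps the components comparable across bicluster sizes. The overall effect
mû is estimated but deliberately enters no score: only the gene and
condition coefficients carry co-expression information. Both properties are
validated by Monte Carlo in the test suite rather than by re-deriving the
underlying non-central chi-square algebra.

T_k and B_k can come out negative (estimate below the noise floor); since
they estimate sums of squares, they are clipped at zero before entering any
ratio.

## Scores

    SB(b)   = ln(T1⁺ + B1⁺ + a) − ln(T2⁺ + B2⁺ + a)
    TS_k(b) = ln(T_k⁺ + a) − ln(B_k⁺ + a),  k = 1 if SB > 0 else 2

computed as log differences so that exchanging G1 and G2 negates SB
bit-exactly. Classification: T-type if TS > phi, B-type if TS < −phi,
mu-type otherwise; ties at |TS| = phi fall in the closed mu band for
determinism. At SB = 0 exactly (e.g. a constant matrix) no group is
declared co-expressed; the assessment reports group 1's TS with type
`unclassified`.

The optional error-ratio score `kostka_spang_score(E1, E2) = ln(E2/E1)` is
oriented so larger means a tighter additive fit inside the bicluster
conditions; errors are floored at 1e-12 so perfectly additive submatrices
remain scorable.

### Parameters

| parameter | default | meaning |
|---|---|---|
| a (fudge factor) | 0.01 | additive stabiliser in both log-ratios, on the scale of squared log-expression. Keeps near-zero/near-zero ratios finite and damped; any 0 < a ≪ 1 on unit-variance data behaves similarly. |
| phi | 1 | half-width of the mu band on the TS scale (natural log). TS > 1 means gene-effect co-expression e-fold stronger than condition-effect. |
| min_conditions | 5 | biclusters spanning fewer conditions are filtered before ranking; few columns are too easy to fit and look spuriously strong. |
| denominator | "df" | E divisor; `"n"` gives the mean-squared-residue convention. |

Natural logarithms are used throughout; phi is interpreted on the same
scale.

### Known properties of SB

- Antisymmetry under group exchange is exact.
- With a → 0, SB is invariant to rescaling all expression values by c > 0
  *provided both groups' clipped components are positive*; if one group is
  pure noise its clipped components vanish, the fudge factor dominates that
  side, and rescaling shifts SB by ln c². This is inherent to fudge-
  stabilised log-ratios.
- Under pure noise SB is symmetric about 0 only for J1 = J2. For J1 < J2
  the clipping inflates the noisier G1 components more, so the null SB mean
  is mildly positive (≈ 0.45 at I = 20, J1 = 10, J2 = 50). Null biclusters
  still rank far below genuine implants (separation is validated at the
  default effect sizes), but SB values of small-J1 biclusters should not be
  compared against an assumed zero null.

## Meta-ranking

All biclusters from all lists are assessed identically and sorted by SB
descending; ties break on larger gene count, then lexicographic id, making
the ranking a deterministic permutation of the scorable input. Biclusters
that cannot be scored (fewer than 2 genes, fewer than 2 bicluster
conditions, or fewer than 2 complement conditions) are reported separately,
never silently dropped. Overlapping or duplicated biclusters from different
algorithms are retained — an optional Jaccard overlap report surfaces them.
Summaries: per-source counts and median sizes (median of an even count is
the mean of the two middle values), unified-rank distributions and
quantiles, top-n composition percentages (summing to 100 at every prefix),
and per-source type compositions with sorted TS values (the cumulative TS
distribution).

## Synthetic data generator

The generator runs the additive model forward: background iid
N(0, noise_sd²) plus disjoint rectangular implants adding
mu_shift + tau_i + beta_j, with tau ~ N(0, tau_sd²) and beta ~ N(0,
beta_sd²) drawn once per implant. Defaults model a detectable but not
overwhelming signal on unit-variance log-expression: noise_sd = 1, effect
sd = 2 (twice the noise), blocks of 20 genes × 10 conditions.

Implant types: `T` (gene effects only), `B` (condition effects only), `mu`
(gene + condition + overall effects of equal magnitude), `global` (the same
gene effects extended to every condition, with fresh condition effects
outside the block — the control a differential score must *not* reward) and
`null` (a labelled region with no effects).

Two generator options depart from free Gaussian draws:

- `effect_pattern="signed"` sets tau_i = ±tau_sd with half the genes
  induced and half repressed, for heatmap-style two-block fixtures.
- `normalize_effects=True` recentres each realized effect vector and
  rescales it to its nominal root mean square. The mu-type default uses
  this: with free draws the realized gene-to-condition effect ratio
  fluctuates (only J1 condition effects are drawn, so ln of the ratio has
  sd ≈ √(2/I + 2/J1) ≈ 0.55 at the default sizes) and a genuinely balanced
  implant would leave the |TS| ≤ phi band in roughly 10% of replicates.
  Pinning the realized magnitudes makes the implanted type unambiguous.

Seeding: each dataset derives one child seed per implant (plus one for the
background) from the master seed via `numpy.random.SeedSequence` state,
masked to 31 bits. Appending an implant therefore never perturbs earlier
draws, and a dataset regenerates bit-identically from its recorded specs.
The background noise sd follows the first implant's spec (or 1.0 with no
implants); implants with heterogeneous noise sds share that background.

What the generator does **not** emulate: probe effects,
intensity-dependent variance, missingness patterns, correlated noise, or
overlapping biclusters. Passing the recovery tests shows the scores behave
correctly under the additive Gaussian model they assume — not that any
particular real dataset satisfies those assumptions.

## Numerical and degenerate-input choices

- Missing values are a hard error by default; the opt-in imputation fills a
  cell with row mean + column mean − grand mean over observed cells (the
  additive model's own prediction, so imputation cannot manufacture
  co-expression). Rows or columns with no observed value are an error.
- Identifiers are matched case-sensitively by exact string equality;
  duplicate ids inside a bicluster are deduplicated with a logged warning.
- Submatrix rows/columns always follow parent-matrix order, and all file
  writers use fixed column order with 6-significant-digit floats, so every
  output is byte-deterministic.
- Fits require I ≥ 2 and J ≥ 2; scoring additionally requires J2 ≥ 2,
  otherwise the bicluster is reported not-scorable (its co-expression would
  be a global effect, untestable differentially).

## Validation problem sizes

The test suite validates the decomposition against an independent
least-squares solver (1,000 random matrices up to 6×6, tolerance 1e-8),
component unbiasedness by Monte Carlo (20,000 replicates at (I,J) ∈
{(10,8), (20,10), (50,30)} × sigma ∈ {0.5, 1, 2}, 3-standard-error bands),
type recovery (500 seeded replicates per type at effect sd = 2× noise,
I = 20, J1 = 10, J2 = 50, ≥ 95% required), and ranking separation of true
implants from global/null controls (200 seeded 500×120 simulations, ≥ 95%).
`scripts/acceptance.py` recomputes the same quantities at the same sizes.
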