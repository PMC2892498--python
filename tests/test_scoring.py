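"""Co-expression components, goodness score SB, stratification TS and typing."""

import math

import numpy as np
import pytest

from dcbiclust import (
    Bicluster,
    CoexpressionComponents,
    ExpressionMatrix,
    NotScorableError,
    ParameterError,
    assess_bicluster,
    classify_bicluster,
    coexpression_components,
    default_spec,
    differential_coexpression_score,
    fit_two_way_model,
    kostka_spang_score,
    simulate_dataset,
    stratification_score,
)


def components_of(X):
    return coexpression_components(fit_two_way_model(np.asarray(X, dtype=float)))


class TestComponents:
    def test_2x2_exact(self):
        c = components_of([[1, 2], [3, 4]])
        # perfect additive fit: E = 0, so the bias correction vanishes
        assert c.E == 0.0
        assert c.T == pytest.approx(1.0)
        assert c.B == pytest.approx(0.25)

    def test_constant_matrix_zero_components(self):
        c = components_of(np.full((3, 4), 2.0))
        assert c.T == pytest.approx(0.0)
        assert c.B == pytest.approx(0.0)

    def test_null_monte_carlo_mean_zero(self):
        """Bias correction centres T and B at 0 under pure noise."""
        rng = np.random.default_rng(11)
        n, I, J = 5000, 10, 8
        Ts, Bs = np.empty(n), np.empty(n)
        for r in range(n):
            c = components_of(rng.normal(0, 1, size=(I, J)))
            Ts[r], Bs[r] = c.T, c.B
        for vals in (Ts, Bs):
            se = vals.std(ddof=1) / np.sqrt(n)
            assert abs(vals.mean()) < 3 * se

    def test_unbiased_for_implanted_effects(self):
        """T and B recover the mean squared fixed effects under noise."""
        rng = np.random.default_rng(12)
        I, J, sigma = 12, 9, 1.5
        tau = rng.normal(0, 2, size=I)
        tau -= tau.mean()
        beta = rng.normal(0, 1, size=J)
        beta -= beta.mean()
        true_T, true_B = np.mean(tau**2), np.mean(beta**2)
        n = 8000
        Ts, Bs = np.empty(n), np.empty(n)
        for r in range(n):
            X = tau[:, None] + beta[None, :] + rng.normal(0, sigma, size=(I, J))
            c = components_of(X)
            Ts[r], Bs[r] = c.T, c.B
        assert abs(Ts.mean() - true_T) < 3 * Ts.std(ddof=1) / np.sqrt(n)
        assert abs(Bs.mean() - true_B) < 3 * Bs.std(ddof=1) / np.sqrt(n)


def cc(T, B, E=0.0, I=2, J=2):
    return CoexpressionComponents(T=T, B=B, E=E, I=I, J=J)


class TestGoodnessScore:
    def test_direct_evaluation(self):
        sb = differential_coexpression_score(cc(1.0, 0.25), cc(0.0, 0.0), a=0.01)
        assert sb == pytest.approx(math.log(1.26 / 0.01), abs=1e-9)
        assert sb == pytest.approx(4.836, abs=1e-3)

    def test_equal_components_score_zero(self):
        c = cc(0.4, 0.7)
        assert differential_coexpression_score(c, c, a=0.05) == 0.0

    def test_antisymmetric_under_group_swap(self):
        c1, c2 = cc(1.2, 0.1), cc(0.3, 0.8)
        assert differential_coexpression_score(
            c1, c2, 0.01
        ) == -differential_coexpression_score(c2, c1, 0.01)

    def test_negative_components_clipped(self):
        # negative T/B mean below-noise estimates; they must not reduce the ratio
        sb = differential_coexpression_score(cc(-0.5, -0.5), cc(-0.1, -0.2), a=0.01)
        assert sb == 0.0

    @pytest.mark.parametrize("a", [0.0, -0.3])
    def test_nonpositive_fudge_rejected(self, a):
        with pytest.raises(ParameterError):
            differential_coexpression_score(cc(1, 1), cc(1, 1), a)


class TestStratificationScore:
    def test_gene_effect_dominance_is_T_type(self):
        ts = stratification_score(cc(1.0, 0.25), a=0.01)
        assert ts == pytest.approx(math.log(1.01 / 0.26), abs=1e-9)
        assert ts == pytest.approx(1.357, abs=1e-3)
        assert classify_bicluster(ts, phi=1.0) == "T"

    def test_balanced_effects_are_mu_type(self):
        assert stratification_score(cc(0.8, 0.8), a=0.01) == 0.0
        assert classify_bicluster(0.0, phi=1.0) == "mu"

    def test_condition_effect_dominance_is_B_type(self):
        ts = stratification_score(cc(0.0, 5.0), a=0.01)
        assert ts == pytest.approx(math.log(0.01 / 5.01), abs=1e-9)
        assert ts == pytest.approx(-6.217, abs=1e-3)
        assert classify_bicluster(ts, phi=1.0) == "B"

    def test_nonpositive_fudge_rejected(self):
        with pytest.raises(ParameterError):
            stratification_score(cc(1, 1), a=0.0)


class TestClassify:
    @pytest.mark.parametrize(
        "ts,phi,expected",
        [
            (1.5, 1.0, "T"),
            (-1.5, 1.0, "B"),
            (0.0, 1.0, "mu"),
            (1.0, 1.0, "mu"),  # boundary ties fall in the closed mu band
            (-1.0, 1.0, "mu"),
            (0.31, 0.3, "T"),
        ],
    )
    def test_threshold_bands(self, ts, phi, expected):
        assert classify_bicluster(ts, phi) == expected

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ParameterError):
            classify_bicluster(0.5, phi=0.0)


class TestKostkaSpang:
    def test_equal_errors_score_zero(self):
        assert kostka_spang_score(0.7, 0.7) == 0.0

    def test_tight_g1_fit_scores_positive(self):
        assert kostka_spang_score(0.5, 2.0) == pytest.approx(math.log(4.0))
        assert kostka_spang_score(2.0, 0.5) == pytest.approx(-math.log(4.0))

    def test_zero_error_floored(self):
        assert math.isfinite(kostka_spang_score(0.0, 1.0))

    def test_negative_error_rejected(self):
        with pytest.raises(NotScorableError):
            kostka_spang_score(-1.0, 1.0)


class TestAssessBicluster:
    def test_t_implant_recovered(self):
        ds = simulate_dataset(20, 60, [default_spec("T", seed=123)], master_seed=5)
        bic, _ = ds.truth[0]
        asmt = assess_bicluster(ds.matrix, bic)
        assert asmt.SB > 0
        assert asmt.group_used == 1
        assert asmt.coexpression_type == "T"

    def test_global_coexpression_scores_near_zero(self):
        hits = 0
        n = 100
        for s in range(n):
            ds = simulate_dataset(20, 60, [default_spec("global")], master_seed=s)
            bic, _ = ds.truth[0]
            if abs(assess_bicluster(ds.matrix, bic).SB) < math.log(2):
                hits += 1
        assert hits >= 0.95 * n

    def test_pure_noise_sb_centred_at_zero(self):
        # equal group sizes: the SB distribution under pure noise is then
        # symmetric about 0 (with J1 != J2 the component clipping inflates
        # the noisier small group and shifts the null mean positive)
        sbs = []
        for s in range(300):
            ds = simulate_dataset(20, 20, [default_spec("null")], master_seed=s)
            bic, _ = ds.truth[0]
            sbs.append(assess_bicluster(ds.matrix, bic).SB)
        sbs = np.asarray(sbs)
        se = sbs.std(ddof=1) / np.sqrt(len(sbs))
        assert abs(sbs.mean()) < 3 * se

    def test_group_used_follows_sb_sign(self):
        # co-expression implanted OUTSIDE the declared bicluster conditions
        ds = simulate_dataset(20, 60, [default_spec("T", seed=9)], master_seed=2)
        bic, _ = ds.truth[0]
        flipped = Bicluster(
            bic.gene_ids,
            frozenset(ds.matrix.condition_ids) - bic.condition_ids,
            "flipped",
            1,
        )
        asmt = assess_bicluster(ds.matrix, flipped)
        assert asmt.SB < 0
        assert asmt.group_used == 2

    def test_exact_tie_unclassified(self):
        # a constant matrix gives identical (zero) components in both groups
        m = ExpressionMatrix(np.zeros((4, 6)), [f"g{i}" for i in range(4)], [f"c{j}" for j in range(6)])
        b = Bicluster(frozenset({"g0", "g1"}), frozenset({"c0", "c1", "c2"}))
        asmt = assess_bicluster(m, b)
        assert asmt.SB == 0.0
        assert asmt.group_used == 1
        assert asmt.coexpression_type == "unclassified"

    def test_degenerate_g2_not_scorable(self, small_matrix):
        b = Bicluster(frozenset({"g1", "g2"}), frozenset(small_matrix.condition_ids))
        with pytest.raises(NotScorableError, match="global effect"):
            assess_bicluster(small_matrix, b)

    def test_single_gene_not_scorable(self, small_matrix):
        b = Bicluster(frozenset({"g1"}), frozenset({"c1", "c2"}))
        with pytest.raises(NotScorableError, match="genes"):
            assess_bicluster(small_matrix, b)

    def test_error_names_offending_bicluster(self, small_matrix):
        b = Bicluster(frozenset({"g1", "g2"}), frozenset({"c1"}), "algA", 7)
        with pytest.raises(NotScorableError, match="algA:7"):
            assess_bicluster(small_matrix, b)


class TestScaleBehaviour:
    def test_components_scale_quadratically(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, size=(8, 6))
        c1 = components_of(X)
        c4 = components_of(2.0 * X)
        assert c4.T == pytest.approx(4 * c1.T, rel=1e-10)
        assert c4.B == pytest.approx(4 * c1.B, rel=1e-10)
        assert c4.E == pytest.approx(4 * c1.E, rel=1e-10)

    def test_sb_scale_invariant_as_fudge_vanishes(self):
        # a global implant keeps both groups' components positive, so the
        # vanishing fudge factor never dominates either side of the ratio
        ds = simulate_dataset(20, 60, [default_spec("global", seed=77)], master_seed=8)
        bic, _ = ds.truth[0]
        a = 1e-12
        sb1 = assess_bicluster(ds.matrix, bic, a=a).SB
        scaled = ExpressionMatrix(
            3.0 * ds.matrix.values, ds.matrix.gene_ids, ds.matrix.condition_ids
        )
        sb3 = assess_bicluster(scaled, bic, a=a).SB
        assert sb3 == pytest.approx(sb1, abs=1e-6)
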