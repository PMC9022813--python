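import itertools
import math
from collections import Counter

import numpy as np
import pytest

from rsdna import (
    DefectVector,
    SolutionSpec,
    classify_alignment,
    counterfactual_theta_perfect,
    defect_fractions_ensemble,
    defect_fractions_fcg,
    delta_g_parametrized,
    partition_sum,
    rank_motifs,
    total_error_fractions,
)
from rsdna.constants import R_KCAL

T_LOW = 273.15  # the "lowest temperature" operating point


class TestNormalization:
    def test_class_fractions_sum_to_theta_e_per_composition(self, params, pool_12n):
        for T in (273.15, 303.15, 333.15):
            d = defect_fractions_fcg(pool_12n, 0.5, T, params)
            assert d.theta.sum() == pytest.approx(d.theta_e, rel=1e-12)

    def test_class_fractions_sum_to_theta_e_ensemble(self, params, pool_12n):
        for T in (273.15, 313.15):
            d = defect_fractions_ensemble(pool_12n, T, params)
            assert d.theta.sum() == pytest.approx(d.theta_e, rel=1e-12)

    def test_error_count_bins_conserve_total(self, params, pool_12n):
        d = defect_fractions_ensemble(pool_12n, 283.15, params)
        assert sum(d.by_total.values()) == pytest.approx(d.theta_e, rel=1e-12)


class TestClassRatios:
    def test_fraction_ratio_equals_weight_ratio(self, params, pool_12n):
        T = 293.15
        d = defect_fractions_fcg(pool_12n, 0.5, T, params)
        table = partition_sum(12, 0.5, T, pool_12n.c_molar, params)
        w = dict(zip(table.alphas, table.weight))
        a, b = DefectVector(0, 0, 0, 0), DefectVector(1, 0, 0, 0)
        got = d.at_T[a] / d.at_T[b]
        assert got == pytest.approx(w[a] / w[b], rel=1e-9)

    def test_distribution_drifts_toward_degeneracy_at_high_t(self, params, pool_12n):
        # total-variation distance to the pure-degeneracy distribution shrinks
        def tv_to_g(T):
            d = defect_fractions_fcg(pool_12n, 0.5, T, params)
            table = partition_sum(12, 0.5, T, pool_12n.c_molar, params)
            p = d.theta / d.theta.sum()
            q = table.g / table.g.sum()
            return 0.5 * np.abs(p - q).sum()

        assert tv_to_g(400.0) < tv_to_g(273.15)


class TestReportedFractions:
    def test_perfect_fraction_exceeds_ten_percent_at_low_t(self, params, pool_12n):
        d = defect_fractions_ensemble(pool_12n, T_LOW, params)
        assert d.theta_perfect > 0.10

    def test_perfect_fraction_ceiling_near_fourteen_percent(self, params, pool_12n):
        best = max(
            defect_fractions_ensemble(pool_12n, T_LOW + t, params).theta_perfect
            for t in np.arange(0.0, 60.0, 5.0)
        )
        assert best == pytest.approx(0.14, abs=0.02)

    def test_single_error_bin_dominates_at_low_t(self, params, pool_12n):
        bins = total_error_fractions(defect_fractions_ensemble(pool_12n, T_LOW, params))
        assert bins[1] == max(bins.values())
        # many-error duplexes are jointly the minority at low T
        many = sum(v for k, v in bins.items() if k > 2)
        assert many < bins[0] + bins[1] + bins[2]

    def test_error_bins_converge_across_lengths_at_low_t(self, params):
        # g is L-independent without internal mismatches, so at fixed
        # composition the low-T error-count bins are length-invariant
        def fixed_composition_bins(L):
            spec = SolutionSpec(L=L, c_mass=25.0)
            d = defect_fractions_fcg(spec, 0.5, T_LOW, params)
            out = {}
            for a, th in zip(d.alphas, d.theta):
                if a.alpha_i == 0:
                    out[a.total] = out.get(a.total, 0.0) + th
            return out

        bins = {L: fixed_composition_bins(L) for L in (8, 12, 20)}
        for k in range(4):
            vals = [bins[L][k] for L in (8, 12, 20)]
            assert max(vals) - min(vals) < 0.002

    def test_ensemble_error_bins_drift_slowly_with_length(self, params):
        # composition averaging adds a weak L dependence: adjacent lengths
        # stay within one percentage point per bin
        bins = {}
        for L in (8, 12, 20):
            spec = SolutionSpec(L=L, c_mass=25.0)
            bins[L] = total_error_fractions(
                defect_fractions_ensemble(spec, T_LOW, params)
            )
        for k in range(4):
            assert abs(bins[8][k] - bins[12][k]) < 0.01
            assert abs(bins[12][k] - bins[20][k]) < 0.01


class TestRankMotifs:
    def test_top_motif_is_terminal_defect_at_low_t(self, params, pool_12n):
        d = defect_fractions_ensemble(pool_12n, T_LOW, params)
        (alpha, frac), = rank_motifs(d, 1)
        assert alpha.alpha_i == 0
        assert frac > 0

    def test_full_ranking_is_a_permutation(self, params, pool_12n):
        d = defect_fractions_ensemble(pool_12n, 300.0, params)
        ranked = rank_motifs(d, len(d.alphas))
        assert sorted(a.astuple() for a, _ in ranked) == sorted(
            a.astuple() for a in d.alphas
        )

    def test_fractions_non_increasing(self, params, pool_12n):
        d = defect_fractions_ensemble(pool_12n, 290.0, params)
        fracs = [f for _, f in rank_motifs(d, 10)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestExhaustiveFractionOracle:
    def test_closed_formula_matches_partner_enumeration_L4(self, params):
        # explicit enumeration of all partners and shifts with parametrized
        # energies reproduces the per-class fractions
        L, T = 4, 290.0
        spec = SolutionSpec(L=L, c_mass=25.0)
        ref = "ACGT"[:L]
        f_cg = 0.5
        counts = Counter()
        for partner in ("".join(p) for p in itertools.product("ACGT", repeat=L)):
            for shift in range(-(L - 1), L):
                a = classify_alignment(ref, partner, shift)
                if a is not None:
                    counts[a] += 1
        weights = {
            a: n
            * spec.c_molar
            * math.exp(-delta_g_parametrized(L, a, f_cg, params).dG(T) / (R_KCAL * T))
            for a, n in counts.items()
        }
        total = sum(weights.values())
        d = defect_fractions_fcg(spec, f_cg, T, params)
        for a, w in weights.items():
            assert d.at_T[a] / d.theta_e == pytest.approx(w / total, rel=1e-9)


class TestCounterfactuals:
    def test_all_cg_raises_perfect_fraction(self, params):
        spec = SolutionSpec(L=8, c_mass=25.0)
        base = defect_fractions_ensemble(spec, T_LOW, params).theta_perfect
        cg = counterfactual_theta_perfect(spec, np.array([T_LOW]), "all_CG", params)
        assert cg.theta[0] > base

    def test_two_base_alphabet_stays_under_point_four(self, params, pool_12n):
        c = counterfactual_theta_perfect(pool_12n, np.array([T_LOW]), 2, params)
        assert c.theta[0] < 0.4
        base = defect_fractions_ensemble(pool_12n, T_LOW, params).theta_perfect
        assert c.theta[0] > base  # reduced degeneracy favors perfect pairing

    def test_more_bases_reduce_perfect_fraction(self, params, pool_12n):
        th = {
            n_b: counterfactual_theta_perfect(pool_12n, np.array([T_LOW]), n_b,
                                              params).theta[0]
            for n_b in (4, 6, 8)
        }
        assert th[6] < th[4]
        assert th[8] < th[6]

    def test_unknown_variant_rejected(self, params, pool_12n):
        from rsdna import InvalidInputError

        with pytest.raises(InvalidInputError):
            counterfactual_theta_perfect(pool_12n, np.array([T_LOW]), "weird", params)


class TestTwoClassToy:
    def test_equal_weights_split_theta_evenly(self, params):
        # hand-restricted two-class system: identical g * zeta means each
        # class carries exactly half of the bound fraction
        spec = SolutionSpec(L=12, c_mass=25.0)
        T = 290.0
        d = defect_fractions_fcg(spec, 0.5, T, params)
        a, b = DefectVector(1, 0, 0, 0), DefectVector(-1, 0, 0, 0)
        # the two shift-mirror classes have equal g and equal energy
        assert d.at_T[a] == pytest.approx(d.at_T[b], rel=1e-12)
        pair_sum = d.at_T[a] + d.at_T[b]
        assert d.at_T[a] == pytest.approx(pair_sum / 2, rel=1e-12)
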