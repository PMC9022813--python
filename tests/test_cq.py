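import dataclasses

import numpy as np
import pytest

from rsdna import (
    CQSpec,
    FreeEnergy,
    InvalidInputError,
    SolutionSpec,
    melting_temperature,
    salt_sensitivity_ab,
    stoichiometric_ratio,
    theta_ab,
    theta_e_cq,
    theta_ensemble,
)
from rsdna.cq import pair_reference_curve
from rsdna.thermo import default_t_grid

SEQ_A, SEQ_B = "ACAGTCCT", "AGGACTGT"  # the tagged 8-mer probe pair

#: characterized fluorophore terminal stabilization and its uncertainty
STABILIZATION = FreeEnergy(-1.2, 0.0)
DG_AB_UNCERTAINTY = 0.75


@pytest.fixture
def cq_phi1():
    """phi = 1 contact-quenching conditions: 16 g/l pool, 100 nM probes, 0.15 M."""
    pool = SolutionSpec(L=8, c_mass=16.0, na_molar=0.15)
    return CQSpec(seq_a=SEQ_A, seq_b=SEQ_B, c_fluo=100e-9, pool=pool,
                  dg_ab_offset=STABILIZATION, dg_ab_uncertainty=DG_AB_UNCERTAINTY)


class TestStoichiometricRatio:
    def test_phi_one_near_sixteen_grams_per_liter(self):
        # 100 nM probes in an 8N pool reach phi = 1 close to 16 g/l
        assert stoichiometric_ratio(100e-9, 16.0, 8) == pytest.approx(1.0, rel=0.05)

    def test_doubling_pool_halves_phi(self):
        assert stoichiometric_ratio(100e-9, 32.0, 8) == pytest.approx(
            stoichiometric_ratio(100e-9, 16.0, 8) / 2
        )

    def test_12mer_pool_value(self):
        # 100 nM probes in 12N at 25 g/l: phi = c_fluo * 4^12 * MW(12) / 25;
        # each species is present at only ~0.4 nM, so the probes are in
        # roughly 250-fold excess over their untagged twins
        expected = 100e-9 * 4**12 * (303.7 * 12 + 79) / 25.0
        assert stoichiometric_ratio(100e-9, 25.0, 12) == pytest.approx(expected)
        assert expected == pytest.approx(250.0, rel=0.01)

    def test_spec_invariant(self, cq_phi1):
        assert cq_phi1.phi == pytest.approx(
            cq_phi1.c_fluo / (cq_phi1.pool.c_molar / 4**8)
        )


class TestThetaAB:
    def test_phi_infinity_converges_to_pair_curve(self, cq_phi1, params):
        grid = default_t_grid(0, 95, 5.0)
        dilute_pool = SolutionSpec.from_molar(8, 100e-9 * 4**8 / 1e6, na_molar=0.15)
        big_phi = dataclasses.replace(cq_phi1, pool=dilute_pool,
                                      dg_ab_uncertainty=0.0)
        assert big_phi.phi == pytest.approx(1e6)
        ab = theta_ab(big_phi, grid, params)
        cq_curve = theta_e_cq(big_phi, grid, params)
        ref = pair_reference_curve(big_phi, grid, params)
        assert np.max(np.abs(ab.theta - ref.theta)) < 1e-3
        assert np.max(np.abs(cq_curve.theta - ref.theta)) < 1e-3

    def test_small_phi_suppresses_specific_pairing(self, cq_phi1, params):
        grid = np.array([273.15])
        crowded = dataclasses.replace(
            cq_phi1, pool=SolutionSpec.from_molar(8, 100e-9 * 4**8 / 1e-4,
                                                  na_molar=0.15))
        assert crowded.phi == pytest.approx(1e-4)
        assert theta_ab(crowded, grid, params).theta[0] < 0.01

    def test_monotone_increasing_in_phi(self, cq_phi1, params):
        grid = np.array([283.15])
        thetas = []
        for phi in (0.1, 1.0, 10.0, 100.0):
            pool = SolutionSpec.from_molar(8, 100e-9 * 4**8 / phi, na_molar=0.15)
            c = dataclasses.replace(cq_phi1, pool=pool)
            thetas.append(theta_ab(c, grid, params).theta[0])
        assert np.all(np.diff(thetas) > 0)

    def test_phi1_low_t_fraction_near_thirty_percent(self, cq_phi1, params):
        # with the fluorophore stabilization the phi = 1 specific-pairing
        # plateau sits near 0.3 at low temperature
        curve = theta_ab(cq_phi1, np.array([273.15]), params)
        assert curve.theta_lo[0] < 0.30 < curve.theta_hi[0]
        assert curve.theta[0] == pytest.approx(0.30, abs=0.08)

    def test_band_brackets_central_curve(self, cq_phi1, params):
        grid = default_t_grid(0, 60, 10.0)
        curve = theta_ab(cq_phi1, grid, params)
        assert np.all(curve.theta_lo <= curve.theta + 1e-12)
        assert np.all(curve.theta_hi >= curve.theta - 1e-12)


class TestThetaECQ:
    def test_phi_zero_limit_reduces_to_pool_class_curve(self, cq_phi1, params):
        # vanishing probe concentration: the CQ total reduces to the pool
        # melting of the probes' composition class
        from rsdna import theta_fcg

        grid = default_t_grid(0, 95, 10.0)
        tiny = dataclasses.replace(cq_phi1, c_fluo=1e-30)
        cq_curve = theta_e_cq(tiny, grid, params)
        pool_curve = theta_fcg(tiny.pool, 0.5, grid, params)
        np.testing.assert_allclose(cq_curve.theta, pool_curve.theta, atol=1e-9)

    def test_total_dominates_specific(self, cq_phi1, params):
        grid = default_t_grid(0, 95, 10.0)
        ab = theta_ab(cq_phi1, grid, params)
        tot = theta_e_cq(cq_phi1, grid, params)
        assert np.all(tot.theta >= ab.theta - 1e-12)

    def test_share_consistency(self, cq_phi1, params):
        # theta_AB / theta_e_CQ equals the weight share of the tagged pair
        from rsdna.cq import _cq_logs

        T = 288.15
        p = params.with_na(cq_phi1.pool.na_molar)
        log_ab, log_pool = _cq_logs(cq_phi1, T, p)
        share = 1.0 / (1.0 + np.exp(log_pool - log_ab))
        ab = theta_ab(cq_phi1, np.array([T]), params).theta[0]
        tot = theta_e_cq(cq_phi1, np.array([T]), params).theta[0]
        assert ab / tot == pytest.approx(share, rel=1e-9)


class TestSaltCancellation:
    def test_theta_ab_profiles_agree_within_band(self, cq_phi1, params):
        # 15 C, experimentally covered phi range: the 0.15 M and 1 M profiles
        # differ by less than the combined dG_AB uncertainty bands
        phis = np.logspace(np.log10(0.3), np.log10(400), 9)
        ss = salt_sensitivity_ab(cq_phi1, 288.15, [0.15, 1.0], phis, params)
        diff = np.abs(ss.theta[0] - ss.theta[1])
        band = ss.band[0] + ss.band[1]
        assert np.all(diff <= band)

    def test_alpha_dependent_salt_term_breaks_cancellation(self, cq_phi1, params):
        # negative control: making the salt exponent defect-dependent by a
        # fictitious factor inflates the cross-salt spread
        import dataclasses as dc

        strong_salt = dc.replace(params, salt_coeff=params.salt_coeff * 4,
                                 _cache={})
        phis = np.logspace(np.log10(0.3), np.log10(400), 5)
        base = salt_sensitivity_ab(cq_phi1, 288.15, [0.15, 1.0], phis, params)
        broken = salt_sensitivity_ab(cq_phi1, 288.15, [0.15, 1.0], phis,
                                     strong_salt)
        assert broken.max_abs_diff > base.max_abs_diff

    def test_pool_tm_remains_salt_sensitive(self, params, coarse_grid):
        # contrast: the ensemble melting temperature still moves with salt
        lo = SolutionSpec(L=12, c_mass=0.04, na_molar=0.15)
        hi = SolutionSpec(L=12, c_mass=0.04, na_molar=1.0)
        tm_lo = melting_temperature(theta_ensemble(lo, coarse_grid, params))
        tm_hi = melting_temperature(theta_ensemble(hi, coarse_grid, params))
        assert tm_hi - tm_lo > 3.0


class TestCQSpecValidation:
    def test_non_complementary_probes_rejected(self):
        pool = SolutionSpec(L=8, c_mass=16.0)
        with pytest.raises(InvalidInputError):
            CQSpec(seq_a=SEQ_A, seq_b=SEQ_A, c_fluo=1e-7, pool=pool)

    def test_length_mismatch_rejected(self):
        pool = SolutionSpec(L=12, c_mass=16.0)
        with pytest.raises(InvalidInputError):
            CQSpec(seq_a=SEQ_A, seq_b=SEQ_B, c_fluo=1e-7, pool=pool)
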