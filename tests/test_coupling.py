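"""Nonlinear coupling estimators: exact cases, symmetries, Gaussian limits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gausscoup import (
    SegmentedSpectra,
    coupling_matrix,
    model_opec,
    model_pec,
    model_pli,
    model_plv,
    model_wpli,
    opec_global,
    opec_local,
    pec,
    pli,
    plv,
    wpli,
)
from gausscoup.simulate import GaussianPairSpec, random_mixing_matrix, simulate_gaussian_pairs

from conftest import circular_gaussian_pair


@pytest.fixture()
def random_pair(rng):
    z1 = rng.standard_normal(256) + 1j * rng.standard_normal(256)
    z2 = rng.standard_normal(256) + 1j * rng.standard_normal(256)
    return z1, z2


class TestExactCases:
    def test_wpli_saturates_at_quarter_cycle_lag(self, random_pair):
        z1, _ = random_pair
        assert wpli(z1, 1j * z1) == -1.0
        assert wpli(z1, -1j * z1) == 1.0

    def test_wpli_undefined_for_real_cross_terms(self, rng):
        # real coefficients (e.g., DC/Nyquist bins) make Im(z1 z2*) exactly 0
        z1 = rng.standard_normal(64).astype(complex)
        z2 = rng.standard_normal(64).astype(complex)
        with pytest.raises(ValueError, match="undefined"):
            wpli(z1, z2)

    def test_pli_saturates_and_zero_convention(self, random_pair, rng):
        z1, _ = random_pair
        assert pli(z1, 1j * z1) == -1.0
        # exactly real cross-terms contribute sign(0) = 0
        r1 = rng.standard_normal(64).astype(complex)
        r2 = rng.standard_normal(64).astype(complex)
        assert pli(r1, r2) == 0.0

    def test_plv_constant_phase_lag(self, random_pair):
        z1, _ = random_pair
        assert plv(z1, z1) == pytest.approx(1.0)
        phi = 0.8
        val = plv(z1, np.exp(1j * phi) * z1)
        assert abs(val) == pytest.approx(1.0)
        assert np.angle(val) == pytest.approx(-phi)

    def test_pec_perfect_correlation_for_identical_channels(self, random_pair):
        z1, _ = random_pair
        for variant in ("power", "amplitude", "log"):
            assert pec(z1, z1, variant) == pytest.approx(1.0)

    def test_opec_degenerate_real_collinearity_errors(self, random_pair):
        z1, _ = random_pair
        with pytest.raises(ValueError):
            opec_global(z1, 2.5 * z1)
        with pytest.raises(ValueError):
            opec_local(z1, z1)  # orthogonalized envelope identically zero


class TestSymmetriesAndInvariances:
    def test_swap_antisymmetry_of_phase_measures(self, random_pair):
        z1, z2 = random_pair
        assert wpli(z2, z1) == pytest.approx(-wpli(z1, z2))
        assert pli(z2, z1) == pytest.approx(-pli(z1, z2))
        assert plv(z2, z1).imag == pytest.approx(-plv(z1, z2).imag)
        assert abs(plv(z2, z1)) == pytest.approx(abs(plv(z1, z2)))
        assert pec(z2, z1) == pytest.approx(pec(z1, z2))

    @given(a1=st.floats(0.01, 100.0), a2=st.floats(0.01, 100.0))
    def test_scale_invariance(self, a1, a2):
        rng = np.random.default_rng(5)
        z1 = rng.standard_normal(128) + 1j * rng.standard_normal(128)
        z2 = rng.standard_normal(128) + 1j * rng.standard_normal(128)
        for f in (wpli, pli, lambda a, b: abs(plv(a, b)), pec, opec_global, opec_local):
            assert f(a1 * z1, a2 * z2) == pytest.approx(f(z1, z2), abs=1e-9)

    def test_two_source_real_mixing_invariance_of_wpli_pli(self):
        A = random_mixing_matrix(21)
        n = 300_000
        z1, z2 = simulate_gaussian_pairs(GaussianPairSpec(A, n, seed=6))
        M = np.array([[1.2, 0.5], [-0.3, 0.8]])
        w = M @ np.stack([z1, z2])
        assert abs(wpli(w[0], w[1])) == pytest.approx(abs(wpli(z1, z2)), abs=0.02)
        assert abs(pli(w[0], w[1])) == pytest.approx(abs(pli(z1, z2)), abs=0.02)

    def test_log_amplitude_equals_log_power_correlation(self, random_pair):
        z1, z2 = random_pair
        lp1, lp2 = np.log(np.abs(z1) ** 2), np.log(np.abs(z2) ** 2)
        expected = np.corrcoef(lp1, lp2)[0, 1]
        assert pec(z1, z2, "log") == pytest.approx(expected, abs=1e-12)


class TestGaussianLimits:
    """Each estimator converges to its model function of coherency."""

    N = 200_000
    # 3 x standard-error tolerances at N = 2e5; SE ~ 1/sqrt(N) up to an
    # O(1) measure-dependent factor
    TOL = 5 / np.sqrt(N) * 3

    @pytest.mark.parametrize("c", [0.3 + 0.4j, -0.2 + 0.55j, 0.6j])
    def test_phase_measures_match_models(self, c):
        z1, z2 = circular_gaussian_pair(c, self.N, np.random.default_rng(abs(hash(c)) % 2**31))
        assert wpli(z1, z2) == pytest.approx(model_wpli(c), abs=self.TOL)
        assert pli(z1, z2) == pytest.approx(model_pli(c), abs=self.TOL)
        mp = model_plv(c)
        est = plv(z1, z2)
        assert abs(est - mp) < self.TOL + 0.012  # model uses the approximate f

    def test_pec_power_matches_squared_coherence(self):
        z1, z2 = circular_gaussian_pair(0.6 + 0j, self.N, np.random.default_rng(1))
        assert pec(z1, z2) == pytest.approx(0.36, abs=self.TOL)

    def test_pec_power_vanishes_for_independent_channels(self):
        z1, z2 = circular_gaussian_pair(0.0, self.N, np.random.default_rng(2))
        assert pec(z1, z2) == pytest.approx(0.0, abs=self.TOL)

    def test_opec_global_matches_squared_lagged_coherence(self):
        c = 0.3 + 0.4j
        z1, z2 = circular_gaussian_pair(c, self.N, np.random.default_rng(3))
        assert opec_global(z1, z2) == pytest.approx(model_opec(c), abs=self.TOL)

    def test_opec_local_vanishes_for_independent_channels(self):
        z1, z2 = circular_gaussian_pair(0.0, self.N, np.random.default_rng(4))
        assert opec_local(z1, z2) == pytest.approx(0.0, abs=self.TOL)

    def test_power_pec_non_negative_in_gaussian_limit(self):
        # powers cannot be negatively correlated for linear dynamics
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(20):
            A = random_mixing_matrix(rng)
            z1, z2 = simulate_gaussian_pairs(
                GaussianPairSpec(A, 20_000, seed=int(rng.integers(2**31 - 1)))
            )
            vals.append(pec(z1, z2))
        se = np.std(vals) / np.sqrt(len(vals))
        assert np.mean(vals) >= -3 * se


class TestZeroAmplitudeHandling:
    def test_few_zero_segments_dropped_with_warning(self):
        rng = np.random.default_rng(8)
        z1 = rng.standard_normal(1000) + 1j * rng.standard_normal(1000)
        z2 = rng.standard_normal(1000) + 1j * rng.standard_normal(1000)
        z1[3] = 0.0
        with pytest.warns(RuntimeWarning, match="dropping"):
            val = plv(z1, z2)
        assert np.isfinite(abs(val))

    def test_many_zero_segments_error(self):
        z1 = np.zeros(100, dtype=complex)
        z2 = np.ones(100, dtype=complex)
        with pytest.raises(ValueError, match="zero amplitude"):
            plv(z1, z2)


class TestCouplingMatrix:
    def make_spectra(self, n_ch=3, n_seg=400, seed=0):
        rng = np.random.default_rng(seed)
        mix = rng.standard_normal((n_ch, n_ch)) + 1j * rng.standard_normal((n_ch, n_ch))
        z = mix @ (rng.standard_normal((n_ch, n_seg)) + 1j * rng.standard_normal((n_ch, n_seg)))
        return SegmentedSpectra(z[:, None, :], np.array([10.0]), 100, 0.5)

    def test_two_channel_matrix_matches_scalar_call(self):
        sp = self.make_spectra(n_ch=2)
        z = sp.at_frequency(10.0)
        M = coupling_matrix(sp, "wpli", 10.0)
        assert M.values[0, 1] == pytest.approx(wpli(z[0], z[1]))
        assert M.values[1, 0] == pytest.approx(-wpli(z[0], z[1]))

    def test_channel_permutation_equivariance(self):
        sp = self.make_spectra(n_ch=4, seed=3)
        M = coupling_matrix(sp, "pli", 10.0).values
        perm = [2, 0, 3, 1]
        sp_perm = SegmentedSpectra(
            sp.coefficients[perm], sp.frequencies, sp.segment_length, sp.overlap_fraction
        )
        M_perm = coupling_matrix(sp_perm, "pli", 10.0).values
        assert np.allclose(M_perm, M[np.ix_(perm, perm)])

    def test_wpli_matrix_antisymmetric_on_many_channels(self):
        sp = self.make_spectra(n_ch=8, n_seg=300, seed=7)
        M = coupling_matrix(sp, "wpli", 10.0).values
        assert np.allclose(M, -M.T, atol=1e-12)

    def test_plv_matrix_hermitian(self):
        sp = self.make_spectra(n_ch=4, seed=9)
        M = coupling_matrix(sp, "plv", 10.0).values
        assert np.allclose(M, M.conj().T)

    def test_unknown_measure_rejected(self):
        sp = self.make_spectra()
        with pytest.raises(ValueError, match="unknown measure"):
            coupling_matrix(sp, "nonsense", 10.0)

    def test_pair_errors_identify_the_pair(self):
        coeff = np.ones((2, 1, 10), dtype=complex)  # real cross-terms everywhere
        sp = SegmentedSpectra(coeff, np.array([10.0]), 100, 0.0,
                              channel_labels=["Fz", "Cz"])
        with pytest.raises(ValueError, match=r"\(Fz, Cz\)"):
            coupling_matrix(sp, "wpli", 10.0)
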