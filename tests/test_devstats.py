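"""Model error, bootstrap noise floor, time-resolved and permutation stats."""

import numpy as np
import pytest

from gausscoup import (
    SegmentedSpectra,
    bootstrap_statistical_error,
    model_error,
    paired_permutation_test,
    relative_frobenius,
    time_resolved_model_error,
)
def gaussian_spectra(n_ch: int, n_seg: int, seed: int) -> SegmentedSpectra:
    rng = np.random.default_rng(seed)
    mix = rng.standard_normal((n_ch, n_ch)) + 1j * rng.standard_normal((n_ch, n_ch))
    z = mix @ (rng.standard_normal((n_ch, n_seg)) + 1j * rng.standard_normal((n_ch, n_seg)))
    return SegmentedSpectra(z[:, None, :], np.array([10.0]), 100, 0.5)


class TestModelError:
    def test_perfect_model_gives_zero(self):
        D = np.array([[0, 0.4], [0.4, 0]])
        assert model_error([D, D], [D.copy(), D.copy()]) == 0.0

    def test_zero_model_gives_one(self):
        D = np.array([[0, 0.4], [0.4, 0]])
        assert model_error([D], [np.zeros_like(D)]) == 1.0

    def test_hand_frobenius_ratio(self):
        D = np.array([[0, 1.0], [1.0, 0]])
        DM = np.array([[0, 0.5], [0.5, 0]])
        assert model_error([D], [DM]) == pytest.approx(0.5)

    def test_zero_norm_matrix_names_subject(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValueError, match="subject 0"):
            model_error([D], [D])

    def test_orthonormal_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        D = rng.standard_normal((5, 5))
        DM = rng.standard_normal((5, 5))
        perm = rng.permutation(5)
        # include_diagonal so the Frobenius property is exact
        a = relative_frobenius(D, DM, include_diagonal=True)
        b = relative_frobenius(D[np.ix_(perm, perm)], DM[np.ix_(perm, perm)],
                               include_diagonal=True)
        assert a == pytest.approx(b, abs=1e-12)

    def test_mismatched_stacks_rejected(self):
        D = np.eye(2)
        with pytest.raises(ValueError):
            model_error([D, D], [D])


class TestBootstrapError:
    def test_invalid_n_boot(self):
        sp = gaussian_spectra(2, 50, 0)
        with pytest.raises(ValueError):
            bootstrap_statistical_error([sp], "wpli", 10.0, n_boot=0)

    def test_error_shrinks_with_segment_count(self):
        sizes = [200, 800, 3200]
        errs = [
            bootstrap_statistical_error(
                [gaussian_spectra(2, n, 1)], "pec_power", 10.0, n_boot=20, seed=2
            )
            for n in sizes
        ]
        # ~ 1/sqrt(n): quadrupling n should roughly halve the error
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[2] > 2.0

    def test_replicates_have_variance(self):
        sp = gaussian_spectra(2, 300, 4)
        rng = np.random.default_rng(5)
        vals = [
            bootstrap_statistical_error([sp], "wpli", 10.0, n_boot=1, seed=rng)
            for _ in range(10)
        ]
        assert np.std(vals) > 0

    def test_gaussian_subjects_model_error_within_noise_floor(self):
        """On Gaussian data E_M stays at or below the statistical error scale."""
        from gausscoup import coherency, coupling_matrix, cross_spectrum, model_matrix

        subjects = [gaussian_spectra(3, 400, 10 + s) for s in range(5)]
        for measure in ("wpli", "pli"):
            D = [coupling_matrix(sp, measure, 10.0) for sp in subjects]
            DM = [
                model_matrix(coherency(cross_spectrum(sp, 10.0)), measure)
                for sp in subjects
            ]
            e_m = model_error(D, DM)
            e_s = bootstrap_statistical_error(subjects, measure, 10.0, n_boot=20, seed=6)
            assert e_m <= e_s * 2.5 + 0.02


class TestTimeResolved:
    def test_1200ms_trials_at_200ms_180ms_give_51_time_points(self):
        rng = np.random.default_rng(0)
        fs = 500.0
        trials = [rng.standard_normal((20, 2, int(1.2 * fs)))]
        curve = time_resolved_model_error(trials, fs, "pec_power", 0.2, 0.18,
                                          frequencies=[10.0])
        assert curve.model_error.shape == (1, 51)
        assert len(curve.times) == 51

    @staticmethod
    def coupled_gaussian_trials(rng, n_tr, n_ch, n_samp):
        """Trials sharing a common source (half the channels lagged by one
        sample), so coupling matrices are well away from zero."""
        shared = rng.standard_normal((n_tr, n_samp + 1))
        noise = rng.standard_normal((n_tr, n_ch, n_samp))
        chans = [
            (shared[:, 1:] if k % 2 == 0 else 0.9 * shared[:, :-1]) + 0.8 * noise[:, k]
            for k in range(n_ch)
        ]
        return np.stack(chans, axis=1)

    def test_stationary_coupled_trials_give_flat_error_curve(self):
        rng = np.random.default_rng(1)
        fs = 250.0
        n_samp = int(1.2 * fs)
        trials = [self.coupled_gaussian_trials(rng, 120, 4, n_samp) for _ in range(4)]
        curve = time_resolved_model_error(trials, fs, "pec_power", 0.2, 0.18,
                                          frequencies=[10.0])
        e = curve.model_error[0]
        assert e.std() / e.mean() < 0.5  # flat within statistical-scale noise

    def test_mid_trial_gaussianization_dips(self):
        """A constructed mid-trial switch to coupled Gaussian data lowers E_M."""
        rng = np.random.default_rng(2)
        fs = 250.0
        n_samp = int(1.2 * fs)
        n_tr, n_ch = 120, 4
        # strongly non-Gaussian edges: common random amplitude per trial with
        # independent phases -> PEC ~ 1 while coherency ~ 0 (model fails)
        t = np.arange(n_samp) / fs
        trials = np.empty((n_tr, n_ch, n_samp))
        for k in range(n_tr):
            amp = 1.0 + 2.0 * rng.random()
            ph = rng.uniform(0, 2 * np.pi, size=n_ch)
            trials[k] = amp * np.sin(2 * np.pi * 10 * t[None, :] + ph[:, None])
        trials += 0.05 * rng.standard_normal(trials.shape)
        # replace the middle third by coupled Gaussian trials (model succeeds)
        third = n_samp // 3
        trials[:, :, third : 2 * third] = self.coupled_gaussian_trials(
            rng, n_tr, n_ch, third
        )
        curve = time_resolved_model_error(
            [trials], fs, "pec_power", 0.2, 0.18, frequencies=[10.0],
            subtract_erp=False,
        )
        e = curve.model_error[0]
        mid = slice(len(e) // 3 + 3, 2 * len(e) // 3 - 3)
        edges = np.r_[e[: len(e) // 4], e[-len(e) // 4 :]]
        assert e[mid].mean() < 0.7 * edges.mean()

    def test_trials_shorter_than_segment_error(self):
        with pytest.raises(ValueError, match="shorter"):
            time_resolved_model_error(
                [np.zeros((5, 2, 30))], 500.0, "pec_power", 0.2, 0.18
            )


class TestPairedPermutation:
    def test_identical_baseline_gives_large_p(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((10, 3))
        values = np.repeat(base[:, None, :], 4, axis=1)  # every time == baseline
        res = paired_permutation_test(values, base, n_perm=200, seed=0)
        assert np.all(res.p_values == 1.0)
        assert not res.significant_mask.any()

    def test_constant_shift_is_maximally_significant(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((12, 2))
        values = np.repeat(base[:, None, :], 3, axis=1)
        values[:, 1, :] += 50.0
        res = paired_permutation_test(values, base, n_perm=2000, seed=1)
        assert res.p_values[1].max() <= 1.0 / 2000 * 2  # smallest attainable scale
        assert res.significant_mask[1].all()
        assert not res.significant_mask[0].any()

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            paired_permutation_test(np.zeros((1, 3, 2)), np.zeros((1, 2)), n_perm=10)

    def test_bonferroni_threshold(self):
        rng = np.random.default_rng(5)
        values = rng.standard_normal((8, 51, 9))
        res = paired_permutation_test(values, n_perm=50, seed=2)
        assert res.alpha_bonferroni == pytest.approx(0.05 / (51 * 9))

    def test_null_p_values_super_uniform(self):
        """Repeated exchangeable-null runs give ~uniform p-values."""
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(300):
            vals = rng.standard_normal((10, 2, 1))
            res = paired_permutation_test(vals, n_perm=99, seed=rng)
            ps.append(res.p_values[1, 0])
        ps = np.sort(ps)
        # Kolmogorov distance to uniform (allowing permutation granularity)
        grid = (np.arange(len(ps)) + 1) / len(ps)
        assert np.max(np.abs(ps - grid)) < 0.12
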