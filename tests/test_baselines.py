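import numpy as np
import pytest
from scipy.signal import sawtooth

from tfdenoise import baselines as bl

FS = 250.0


class TestEmd:
    def test_monotone_signal_gives_no_imfs(self):
        ramp = np.linspace(0, 1, 100)
        st = bl.emd(ramp)
        assert st.n_imfs == 0
        assert np.array_equal(st.residue, ramp)

    @pytest.mark.parametrize("seed", range(3))
    def test_completeness_exact(self, seed):
        x = np.random.default_rng(seed).normal(size=300)
        st = bl.emd(x)
        recon = st.imfs.sum(axis=0) + st.residue
        assert np.abs(recon - x).max() < 1e-8

    def test_fast_tone_lands_in_first_imf(self):
        t = np.arange(250) / FS
        x = np.sin(2 * np.pi * 25 * t) + np.sin(2 * np.pi * 3 * t)
        st = bl.emd(x)
        r = np.corrcoef(st.imfs[0], np.sin(2 * np.pi * 25 * t))[0, 1]
        assert abs(r) > 0.9


class TestEemd:
    def _signal(self):
        t = np.arange(250) / FS
        return np.sin(2 * np.pi * 25 * t) + np.sin(2 * np.pi * 3 * t)

    def test_zero_noise_degenerates_to_emd(self):
        x = self._signal()
        e = bl.eemd(x, bl.EemdConfig(noise_std=0.0, n_ensembles=3))
        p = bl.emd(x, bl.EemdConfig().sift_sd_threshold,
                   bl.EemdConfig().max_imfs, bl.EemdConfig().max_sift_iters)
        assert np.abs(e.imfs - p.imfs).max() < 1e-12

    def test_deterministic_under_seed(self):
        x = self._signal()
        a = bl.eemd(x, bl.EemdConfig(seed=7, n_ensembles=10))
        b = bl.eemd(x, bl.EemdConfig(seed=7, n_ensembles=10))
        assert np.array_equal(a.imfs, b.imfs)
        assert np.array_equal(a.residue, b.residue)

    def test_reconstruction_error_shrinks_with_ensemble_size(self):
        x = self._signal()

        def err(l):
            e = bl.eemd(x, bl.EemdConfig(n_ensembles=l, seed=0))
            recon = e.imfs.sum(axis=0) + e.residue
            return np.linalg.norm(recon - x) / np.linalg.norm(x)

        assert err(100) < err(10)


class TestFastica:
    def _two_sources(self, n=1000):
        t = np.arange(n) / n
        s1 = sawtooth(2 * np.pi * 7 * t)
        s2 = np.sin(2 * np.pi * 11 * t)
        return np.vstack([s1, s2])

    @pytest.mark.parametrize("seed", range(5))
    def test_two_source_recovery(self, seed):
        S = self._two_sources()
        X = np.array([[1.0, 0.5], [0.5, 1.0]]) @ S
        Sp, _ = bl.fastica(X, seed=seed)
        C = np.abs(np.corrcoef(np.vstack([Sp, S]))[:2, 2:])
        # each true source matched by some output row, sign/permutation free
        assert C.max(axis=0).min() > 0.95

    def test_output_rows_unit_variance(self):
        S = self._two_sources()
        X = np.array([[1.0, 0.5], [0.5, 1.0]]) @ S
        Sp, _ = bl.fastica(X, seed=0)
        assert np.abs(Sp.var(axis=1) - 1.0).max() < 1e-6

    def test_rank_deficiency_rejected(self):
        s = self._two_sources()[0]
        X = np.vstack([s, 2 * s])  # one source in two channels
        with pytest.raises(ValueError, match="rank"):
            bl.fastica(X, n_components=2)

    def test_matches_sklearn_on_separable_mixture(self):
        """Independent cross-check against scikit-learn's FastICA."""
        sklearn_ica = pytest.importorskip(
            "sklearn.decomposition").FastICA
        S = self._two_sources()
        X = np.array([[1.0, 0.4], [0.6, 1.0]]) @ S
        ours, _ = bl.fastica(X, seed=0)
        theirs = sklearn_ica(whiten="unit-variance",
                             random_state=0).fit_transform(X.T).T
        C = np.abs(np.corrcoef(np.vstack([ours, theirs]))[:2, 2:])
        assert C.max(axis=0).min() > 0.99


class TestCca:
    def test_self_correlation_is_one(self, rng):
        X = rng.normal(size=(4, 300))
        _, rho = bl.cca_first_variate(X, X)
        # the regularising ridge (1e-8 * trace) keeps rho just below 1
        assert abs(rho - 1.0) < 1e-6

    def test_rho_equals_pearson_of_variates(self, rng):
        X1 = rng.normal(size=(4, 300))
        X2 = rng.normal(size=(4, 300))
        variates, rhos, W1, W2 = bl.cca(X1, X2)
        v2 = W2[:, 0] @ (X2 - X2.mean(axis=1, keepdims=True))
        assert abs(rhos[0] - np.corrcoef(variates[0], v2)[0, 1]) < 1e-8

    def test_rhos_ordered_descending(self, rng):
        X1 = rng.normal(size=(5, 400))
        X2 = rng.normal(size=(5, 400))
        _, rhos, _, _ = bl.cca(X1, X2)
        assert np.all(np.diff(rhos) <= 1e-12)

    def test_eigen_solution_beats_random_projections(self, rng):
        """Stochastic lower-bound oracle: no random projection pair should
        correlate better than the first canonical pair."""
        X1 = rng.normal(size=(3, 500))
        X2 = np.vstack([X1[0] + 0.5 * rng.normal(size=500),
                        rng.normal(size=(2, 500))])
        _, rho = bl.cca_first_variate(X1, X2)
        best = 0.0
        for _ in range(100_000 // 100):  # 1000 draws is ample at p=3
            w1 = rng.normal(size=3)
            w2 = rng.normal(size=3)
            r = abs(np.corrcoef(w1 @ X1, w2 @ X2)[0, 1])
            best = max(best, r)
        assert rho >= best - 1e-3

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            bl.cca(rng.normal(size=(3, 100)), rng.normal(size=(3, 99)))


class TestEemdIcaDenoise:
    def test_argmax_selection_and_determinism(self, sim_seed1):
        trial = sim_seed1.trials[0]
        ref = sim_seed1.trials.mean(axis=0)
        cfg = bl.EemdConfig(seed=3, n_ensembles=20)
        a = bl.eemd_ica_denoise(trial, ref, cfg)
        b = bl.eemd_ica_denoise(trial, ref, cfg)
        assert np.array_equal(a, b)
        # output is positively correlated with the reference by construction
        assert np.corrcoef(a, ref)[0, 1] > 0

    def test_reference_length_checked(self, rng):
        with pytest.raises(ValueError):
            bl.eemd_ica_denoise(rng.normal(size=250), rng.normal(size=100))


class TestEemdCcaDenoise:
    def test_output_length_and_determinism(self, sim_seed1):
        trial = sim_seed1.trials[0]
        cfg = bl.EemdConfig(seed=3, n_ensembles=20)
        a = bl.eemd_cca_denoise(trial, cfg)
        b = bl.eemd_cca_denoise(trial, cfg)
        assert a.shape == trial.shape
        assert np.array_equal(a, b)

    def test_too_short_trial_rejected(self):
        with pytest.raises(ValueError):
            bl.eemd_cca_denoise(np.zeros(2))


class TestWaveletThreshold:
    def test_zero_in_zero_out(self):
        assert np.abs(bl.wavelet_threshold_denoise(np.zeros(64))).max() == 0

    def test_pure_noise_mostly_removed(self):
        noise = np.random.default_rng(1).normal(size=256)
        out = bl.wavelet_threshold_denoise(noise)
        assert np.sum(out ** 2) < 0.2 * np.sum(noise ** 2)

    def test_slow_sinusoid_passes_through(self):
        x = np.sin(2 * np.pi * 3 * np.arange(256) / FS)
        out = bl.wavelet_threshold_denoise(x)
        assert np.corrcoef(out, x)[0, 1] > 0.99

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bl.wavelet_threshold_denoise(np.zeros(4))
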