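import numpy as np
import pytest

from ssvepkit import rca
from ssvepkit.spectral import HarmonicResponse


def make_input(n_trials=40, epochs=5, n_channels=32, sources=(), noise=0.3,
               seed=0, jitter=0.0):
    """Observations = sum of phase-locked sources + iid complex noise.

    ``sources`` is a list of (topography, per-trial complex coefficient
    array) pairs; coefficients are constant within a trial.
    """
    rng = np.random.default_rng(seed)
    rows, tids = [], []
    for t in range(n_trials):
        z_clean = np.zeros(n_channels, dtype=complex)
        for topo, coeffs in sources:
            z_clean = z_clean + coeffs[t] * (1 + jitter * rng.uniform(-1, 1)) * topo
        for _ in range(epochs):
            z = z_clean + noise * (rng.standard_normal(n_channels)
                                   + 1j * rng.standard_normal(n_channels))
            rows += [z.real, z.imag]
            tids += [t, t]
    return rca.RCInput(np.array(rows), np.array(tids), harmonic=1, task="letter")


def random_topo(n_channels, lo, hi, seed):
    rng = np.random.default_rng(seed)
    t = np.zeros(n_channels)
    t[lo:hi] = rng.uniform(0.5, 1.0, hi - lo)
    return t / np.linalg.norm(t)


class TestCovariances:
    def test_identical_observation_vectors_make_between_equal_within(self):
        # perfect reliability: every trial contributes the same epoch vector
        rng = np.random.default_rng(1)
        epoch = rng.standard_normal((2, 8))  # one (re, im) pair
        obs = np.tile(epoch, (5, 1))
        inp = rca.RCInput(obs, np.repeat(np.arange(5), 2), 1, "letter")
        rb, rw = rca.cross_trial_covariances(inp)
        np.testing.assert_allclose(rb, rw, atol=1e-12)

    def test_independent_noise_has_vanishing_reliability(self):
        inp = make_input(n_trials=200, epochs=2, n_channels=8, noise=1.0, seed=2)
        rb, rw = rca.cross_trial_covariances(inp)
        assert np.linalg.norm(rb) / np.linalg.norm(rw) < 0.1

    def test_matches_bruteforce_pair_sum_for_three_trials(self):
        inp = make_input(n_trials=3, epochs=2, n_channels=5, noise=1.0, seed=3)
        rb, _ = rca.cross_trial_covariances(inp)
        T = inp.by_trial()  # 3 trials of 4 rows; rows alternate re, im
        acc = np.zeros((5, 5))
        n_pairs = 0
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                for kind in (0, 1):  # re rows, im rows
                    Xi, Xj = T[i][kind::2], T[j][kind::2]
                    for a in range(Xi.shape[0]):
                        for b in range(Xj.shape[0]):
                            acc += np.outer(Xi[a], Xj[b])
                            n_pairs += 1
        expected = 0.5 * (acc + acc.T) / n_pairs
        np.testing.assert_allclose(rb, expected, atol=1e-12)

    def test_single_trial_rejected(self):
        inp = make_input(n_trials=2, epochs=1, n_channels=4)
        solo = rca.RCInput(inp.observations[:2], inp.trial_ids[:2], 1, "letter")
        with pytest.raises(ValueError):
            rca.cross_trial_covariances(solo)

    def test_unequal_epoch_counts_pool_with_pair_weights(self):
        # artifact rejection leaves trials with different epoch counts;
        # dropping one epoch from one trial must not change expectations
        rng = np.random.default_rng(4)
        epoch = rng.standard_normal((2, 6))
        obs = np.tile(epoch, (6, 1))                   # 3 trials x 2 epochs
        tids = np.repeat(np.arange(3), 4)
        full = rca.RCInput(obs, tids, 1, "letter")
        pruned = rca.RCInput(obs[:-2], tids[:-2], 1, "letter")
        rb_f, _ = rca.cross_trial_covariances(full)
        rb_p, _ = rca.cross_trial_covariances(pruned)
        np.testing.assert_allclose(rb_f, rb_p, atol=1e-12)

    def test_dangling_half_epoch_rejected(self):
        obs = np.zeros((6, 4))
        with pytest.raises(ValueError):
            rca.RCInput(obs, np.array([0, 0, 0, 1, 1, 1]), 1, "letter")


def phases(vals_deg, n_trials, seed=None):
    per_cond = np.repeat(np.exp(1j * np.deg2rad(vals_deg)),
                         n_trials // len(vals_deg))
    return per_cond


class TestFit:
    def test_single_source_recovery(self):
        topo = random_topo(32, 5, 15, seed=4)
        coeffs = 2.0 * phases([0, 20, 40, 60, 80], 40)
        inp = make_input(sources=[(topo, coeffs)], noise=0.3, seed=5, jitter=0.1)
        model = rca.fit_rca(inp, n_components=1)
        _, r = rca.match_topographies(model.A, topo[:, None])
        assert r[0] >= 0.99

    def test_two_source_recovery_with_distinct_reliability(self):
        t1 = random_topo(32, 2, 12, seed=6)
        t2 = random_topo(32, 18, 28, seed=7)
        c1 = 2.0 * np.linspace(0.5, 1.5, 40) * phases([10] * 5, 40)
        c2 = 0.8 * np.linspace(1.5, 0.5, 40) * phases([100] * 5, 40)
        inp = make_input(sources=[(t1, c1), (t2, c2)], noise=0.4, seed=8,
                         jitter=0.1)
        model = rca.fit_rca(inp, n_components=2)
        assign, r = rca.match_topographies(model.A, np.column_stack([t1, t2]))
        assert sorted(assign) == [0, 1]
        assert np.all(r >= 0.95)

    def test_generalized_eigen_identity_on_reduced_subspace(self):
        inp = make_input(n_trials=30, n_channels=16,
                         sources=[(random_topo(16, 3, 9, 9),
                                   phases([0, 45, 90, 135, 180], 30))],
                         noise=0.5, seed=10)
        model = rca.fit_rca(inp, n_components=2)
        rb, rw = rca.cross_trial_covariances(inp)
        lhs = rb @ model.W
        rhs = rw @ model.W @ np.diag(model.eigvals[:2])
        np.testing.assert_allclose(lhs, rhs, atol=1e-8 * np.abs(lhs).max())

    def test_channel_permutation_equivariance(self):
        inp = make_input(n_trials=20, n_channels=12, noise=1.0, seed=11)
        rng = np.random.default_rng(12)
        perm = rng.permutation(12)
        inp_p = rca.RCInput(inp.observations[:, perm], inp.trial_ids, 1, "letter")
        w = rca.fit_rca(inp, n_components=1).W[:, 0]
        w_p = rca.fit_rca(inp_p, n_components=1).W[:, 0]
        sign = np.sign(np.dot(w[perm], w_p))
        np.testing.assert_allclose(w[perm] * sign, w_p, atol=1e-6)

    def test_scale_invariance(self):
        inp = make_input(n_trials=20, n_channels=12,
                         sources=[(random_topo(12, 2, 8, 13),
                                   phases([0, 90, 180, 270, 45], 20))],
                         noise=0.4, seed=13)
        scaled = rca.RCInput(7.5 * inp.observations, inp.trial_ids, 1, "letter")
        m1, m2 = rca.fit_rca(inp), rca.fit_rca(scaled)
        np.testing.assert_allclose(m1.A, m2.A, atol=1e-8)
        np.testing.assert_allclose(m1.reliability_fraction,
                                   m2.reliability_fraction, atol=1e-8)

    def test_deterministic(self):
        inp = make_input(n_trials=15, n_channels=10, noise=1.0, seed=14)
        np.testing.assert_array_equal(rca.fit_rca(inp).W, rca.fit_rca(inp).W)


class TestReliabilityExplained:
    def test_all_components_explain_everything(self):
        inp = make_input(n_trials=20, n_channels=10, noise=1.0, seed=15)
        model = rca.fit_rca(inp)
        assert rca.reliability_explained(model, k=len(model.eigvals)) == \
            pytest.approx(1.0)

    def test_rank_one_structure_explained_by_first(self):
        topo = random_topo(16, 4, 10, seed=16)
        inp = make_input(n_trials=40, n_channels=16,
                         sources=[(topo, 3.0 * phases([30] * 5, 40))],
                         noise=0.2, seed=17)
        assert rca.reliability_explained(rca.fit_rca(inp), k=1) >= 0.95


def response_from(vec, noise_vecs, condition=1):
    noise_vecs = np.asarray(noise_vecs)
    return HarmonicResponse(harmonic=1, freq_hz=3.0, condition=condition,
                            mean_coeff=np.asarray(vec),
                            noise_coeffs=noise_vecs,
                            noise_amp=np.abs(noise_vecs).mean(axis=0),
                            n_epochs=10)


class TestProject:
    def _selector_model(self, n_channels, idx):
        W = np.zeros((n_channels, 1))
        W[idx, 0] = 1.0
        return rca.RCModel(W=W, A=W.copy(), eigvals=np.array([1.0]),
                           reliability_fraction=np.array([1.0]),
                           n_components=1, rank=1)

    def test_selector_filter_reads_single_channel(self):
        rng = np.random.default_rng(18)
        z = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        nz = rng.standard_normal((2, 8)) * 0.1
        out = rca.project(self._selector_model(8, 5), [response_from(z, nz)])
        assert out.loc[0, "amplitude"] == pytest.approx(abs(z[5]))
        assert out.loc[0, "phase_deg"] == pytest.approx(
            np.degrees(np.angle(z[5])) % 360)

    def test_amplitude_invariant_to_global_phase(self):
        rng = np.random.default_rng(19)
        z = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        nz = rng.standard_normal((2, 8)) * 0.1
        model = self._selector_model(8, 2)
        a1 = rca.project(model, [response_from(z, nz)])["amplitude"]
        a2 = rca.project(model, [response_from(z * np.exp(1j * 0.7), nz)])["amplitude"]
        np.testing.assert_allclose(a1, a2)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rca.project(self._selector_model(8, 0),
                        [response_from(np.ones(6, complex), np.ones((2, 6)))])

    def test_learned_filter_beats_best_single_channel_snr(self):
        # matched-filter property: with spatially uniform noise the learned
        # weighting of coherent channels outperforms any single electrode
        # (|w'sig|/||w|| >= max |sig_ch| when w aligns with the topography)
        for seed in range(20):
            topo = random_topo(24, 4, 16, seed=100 + seed)
            coeffs = 1.5 * phases([15] * 5, 30)
            inp = make_input(n_trials=30, n_channels=24,
                             sources=[(topo, coeffs)], noise=0.5,
                             seed=200 + seed, jitter=0.1)
            w = rca.fit_rca(inp, n_components=1).W[:, 0]
            sig = 1.5 * np.exp(1j * np.deg2rad(15)) * topo
            snr_proj = abs(w @ sig) / np.linalg.norm(w)
            assert snr_proj >= 0.98 * np.abs(sig).max()


class TestNullCalibration:
    def test_phase_randomization_kills_reliability(self):
        topo = random_topo(16, 4, 10, seed=20)
        inp = make_input(n_trials=40, n_channels=16,
                         sources=[(topo, 2.0 * phases([45] * 5, 40))],
                         noise=0.4, seed=21)
        lam_obs = rca.fit_rca(inp).eigvals[0]
        lam_null = rca.fit_rca(rca.phase_randomize(inp, seed=22)).eigvals[0]
        assert lam_null < 0.25 * lam_obs

    def test_permutation_null_bounds_randomized_input(self):
        inp = make_input(n_trials=30, n_channels=12, noise=1.0, seed=23)
        null_input = rca.phase_randomize(inp, seed=24)
        observed, null = rca.permutation_null_top_eig(null_input, n_perm=100,
                                                      seed=25)
        assert observed <= np.quantile(null, 0.95)
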