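import numpy as np
import pytest

import ssvepkit as sk
from ssvepkit.simulate import DEG_PER_MS
from ssvepkit.spectral import coherent_average, compute_spectra


@pytest.fixture(scope="module")
def letter_gt(montage):
    return sk.default_ground_truth("letter", montage)


@pytest.fixture(scope="module")
def vernier_gt(montage):
    return sk.default_ground_truth("vernier", montage)


class TestGroundTruth:
    def test_letter_second_source_peaks_at_0p6_logmar(self, letter_gt):
        levels = sk.build_series("letter", 0.15, 1.06).logmar_levels
        peak = levels[int(np.argmax(letter_gt.source2.tuning_amp_1f))]
        assert peak == pytest.approx(0.6, abs=0.01)

    def test_letter_first_source_saturates_at_top_sizes(self, letter_gt):
        amp = letter_gt.source1.tuning_amp_1f
        assert np.all(np.diff(amp) >= 0)
        assert amp[3] / amp[4] > 0.9  # plateau over the two largest sizes

    def test_letter_lag_decreases_100_to_40(self, letter_gt):
        assert letter_gt.latency_lag_ms[0] == pytest.approx(100.0)
        assert letter_gt.latency_lag_ms[-1] == pytest.approx(40.0)
        assert np.all(np.diff(letter_gt.latency_lag_ms) < 0)

    def test_vernier_lag_constant_90ms(self, vernier_gt):
        np.testing.assert_allclose(vernier_gt.latency_lag_ms, 90.0)

    def test_topographies_unit_norm(self, letter_gt, vernier_gt):
        for gt in (letter_gt, vernier_gt):
            for src in (gt.source1, gt.source2):
                assert np.linalg.norm(src.topography) == pytest.approx(1.0)

    def test_topographies_peak_at_named_sensors(self, letter_gt, vernier_gt):
        assert int(np.argmax(letter_gt.source1.topography)) + 1 in (65, 66)
        assert int(np.argmax(letter_gt.source2.topography)) + 1 in (75, 83)
        assert int(np.argmax(vernier_gt.source1.topography)) + 1 == 75
        assert int(np.argmax(vernier_gt.source2.topography)) + 1 in (90, 91)

    def test_lag_phase_consistency_enforced(self, letter_gt):
        import dataclasses
        with pytest.raises(ValueError):
            dataclasses.replace(letter_gt, latency_lag_ms=np.full(5, 10.0))

    def test_phase_lag_arithmetic(self, vernier_gt):
        dphi = (vernier_gt.source2.phase_1f_deg
                - vernier_gt.source1.phase_1f_deg) % 360
        np.testing.assert_allclose(dphi / DEG_PER_MS, 90.0)

    def test_unknown_task_rejected(self, montage):
        with pytest.raises(ValueError):
            sk.default_ground_truth("grating", montage)


def small_schedule(conds, n_blocks=1, trial_s=12.0, seed=0):
    return sk.build_schedule(n_blocks=n_blocks, per_block_per_cond=1,
                             conditions=conds, trial_s=trial_s, seed=seed)


class TestSimulateSession:
    def test_same_seed_bit_identical(self, montage, letter_gt, condition_table):
        sched = small_schedule([6, 7], trial_s=3.0)
        kw = dict(noise=sk.NoiseSpec(noise_rms_uv=2.0), seed=5, montage=montage,
                  condition_table=condition_table)
        a = sk.simulate_session(sched, letter_gt, **kw)
        b = sk.simulate_session(sched, letter_gt, **kw)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noiseless_signal_confined_to_harmonics(self, montage, letter_gt,
                                                    condition_table):
        sched = small_schedule([10], trial_s=3.0)
        sess = sk.simulate_session(
            sched, letter_gt, sk.NoiseSpec(noise_rms_uv=0.0, blink_rate_hz=0.0),
            seed=0, montage=montage, condition_table=condition_table,
            amp_jitter=0.0)
        spectra, _ = compute_spectra(sess, reject=False)
        mag = np.abs(spectra.coeffs[0, np.argmax(letter_gt.source1.topography)])
        k1 = spectra.bin_index(3.0)
        harmonics = {k1, spectra.bin_index(6.0)}
        others = [m for i, m in enumerate(mag) if i not in harmonics]
        assert 20 * np.log10(max(others) / mag[k1]) < -100

    def test_noiseless_spectral_inversion_is_exact(self, montage, letter_gt,
                                                   condition_table):
        # analysis convention inverts the generative model: amplitudes and
        # phases at 1F/2F come back exactly (float32 data tolerance)
        sched = small_schedule([8], trial_s=12.0)
        sess = sk.simulate_session(
            sched, letter_gt, sk.NoiseSpec(noise_rms_uv=0.0, blink_rate_hz=0.0),
            seed=0, montage=montage, condition_table=condition_table,
            amp_jitter=0.0)
        spectra, _ = compute_spectra(sess, reject=False)
        resp = {r.harmonic: r for r in coherent_average(spectra)
                if r.condition == 8}
        lvl = 2  # condition 8 = letter level 3 (0.605 logMAR)
        for harm, amps, phases in (
                (1, "tuning_amp_1f", "phase_1f_deg"),
                (2, "tuning_amp_2f", "phase_2f_deg")):
            expected = sum(
                getattr(src, amps)[lvl]
                * np.exp(1j * np.deg2rad(getattr(src, phases)[lvl]))
                * src.topography
                for src in (letter_gt.source1, letter_gt.source2))
            np.testing.assert_allclose(resp[harm].mean_coeff, expected, atol=1e-5)

    def test_pink_noise_spectral_slope(self, montage, condition_table):
        sched = small_schedule(list(range(1, 11)), trial_s=12.0)
        ns = sk.NoiseSpec(noise_rms_uv=10.0, blink_rate_hz=0.0)
        sess = sk.simulate_session(sched, [], ns, seed=3, montage=montage,
                                   condition_table=condition_table)
        f, p = None, None
        from scipy import signal as sps
        f, p = sps.welch(sess.data[::8].astype(float), fs=sess.fs, nperseg=4096)
        band = (f >= 1.0) & (f <= 40.0)
        slope = np.polyfit(np.log10(f[band]), np.log10(p[:, band].mean(axis=0)), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_noise_amplitude_estimate_scales_linearly(self, montage,
                                                      condition_table):
        means = []
        for rms in (5.0, 10.0):
            vals = []
            for seed in range(8):
                sched = small_schedule([1, 6], trial_s=3.0, seed=seed)
                ns = sk.NoiseSpec(noise_rms_uv=rms, blink_rate_hz=0.0)
                sess = sk.simulate_session(sched, [], ns, seed=seed,
                                           montage=montage,
                                           condition_table=condition_table)
                spectra, _ = compute_spectra(sess, reject=False)
                resp = coherent_average(spectra)
                vals.append(np.mean([r.noise_amp.mean() for r in resp]))
            means.append(np.mean(vals))
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.15)

    def test_blinks_are_frontal_and_transient(self, montage, condition_table):
        sched = small_schedule(list(range(1, 11)), trial_s=12.0)
        ns = sk.NoiseSpec(noise_rms_uv=0.0, blink_rate_hz=0.3, blink_amp_uv=150.0)
        sess = sk.simulate_session(sched, [], ns, seed=7, montage=montage,
                                   condition_table=condition_table)
        assert len(sess.meta["blinks_s"]) > 0
        frontal = montage.positions[:, 1] > 0.5
        occipital = montage.positions[:, 1] < -0.5
        assert np.abs(sess.data[frontal]).max() > 10 * max(
            np.abs(sess.data[occipital]).max(), 1e-9)
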