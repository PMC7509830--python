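"""Forward simulation of acuity-sweep SSVEP sessions with known ground truth.

Each task is modeled by two phase-locked cortical sources with fixed scalp
topographies. A source at stimulus level ``l`` contributes

    A_k(l) * cos(2*pi*k*f*t - phi_k(l)),   k in {1, 2},  f = 3 Hz

projected through its topography, with a small multiplicative per-trial
amplitude jitter. Background activity is spatially correlated 1/f noise
plus frontal blink transients. Topographies are phenomenological scalp
patterns (smooth bumps around named sensors), which is all that parameter
recovery of the spatial-filtering stage requires — no biophysical head
model is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .montage import Montage, load_montage
from .session import RawSession
from .stimulus import Schedule, standard_condition_table

__all__ = [
    "SourceSpec",
    "NoiseSpec",
    "GroundTruth",
    "gaussian_topography",
    "default_ground_truth",
    "simulate_session",
]

STIM_FREQ_HZ = 3.0
DEG_PER_MS = 360.0 * STIM_FREQ_HZ / 1000.0  # 1.08 deg of 1F phase per ms


@dataclass(frozen=True)
class SourceSpec:
    """One source: unit-norm topography plus per-level harmonic tuning."""

    name: str
    topography: np.ndarray          # (128,), unit norm
    tuning_amp_1f: np.ndarray       # (5,) µV ASD
    tuning_amp_2f: np.ndarray
    phase_1f_deg: np.ndarray        # (5,) cosine-lag phase, [0, 360)
    phase_2f_deg: np.ndarray

    def __post_init__(self):
        for attr in ("topography", "tuning_amp_1f", "tuning_amp_2f",
                     "phase_1f_deg", "phase_2f_deg"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), float))
        if np.any(self.tuning_amp_1f < 0) or np.any(self.tuning_amp_2f < 0):
            raise ValueError("amplitudes must be nonnegative")
        for attr in ("phase_1f_deg", "phase_2f_deg"):
            ph = getattr(self, attr)
            if np.any(ph < 0) or np.any(ph >= 360):
                raise ValueError("phases must lie in [0, 360)")
        topo = self.topography / np.linalg.norm(self.topography)
        object.__setattr__(self, "topography", topo)


@dataclass(frozen=True)
class NoiseSpec:
    """Background noise model: 1/f^alpha spectrum, partial spatial mixing,
    and Poisson blink transients used to exercise epoch rejection."""

    pink_exponent: float = 1.0
    noise_rms_uv: float = 3.0
    n_mixing: int = 16              # rank of the spatially correlated part
    mixing_fraction: float = 0.1    # variance share of the correlated part
    blink_rate_hz: float = 0.04
    blink_amp_uv: float = 200.0
    blink_dur_s: float = 0.5

    def __post_init__(self):
        vals = [self.pink_exponent, self.noise_rms_uv, self.n_mixing,
                self.mixing_fraction, self.blink_rate_hz, self.blink_amp_uv]
        if any(v < 0 for v in vals):
            raise ValueError("noise parameters must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Two sources for one task plus their per-level 1F latency lag."""

    task: str
    source1: SourceSpec
    source2: SourceSpec
    latency_lag_ms: np.ndarray  # signed, source2 minus source1, per level

    def __post_init__(self):
        object.__setattr__(self, "latency_lag_ms", np.asarray(self.latency_lag_ms, float))
        dphi = (self.source2.phase_1f_deg - self.source1.phase_1f_deg) % 360.0
        lag_from_phase = dphi / DEG_PER_MS
        period_ms = 1000.0 / STIM_FREQ_HZ
        if not np.allclose(self.latency_lag_ms % period_ms, lag_from_phase % period_ms,
                           atol=1e-6):
            raise ValueError("latency_lag_ms inconsistent with 1F phase fields")

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else
                    {kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv)
                     for kk, vv in v.items()} if isinstance(v, dict) else v)
                for k, v in d.items()}


def gaussian_topography(montage: Montage, peak_ids: list[int],
                        width: float = 0.35) -> np.ndarray:
    """Unit-norm smooth scalp pattern: sum of spherical Gaussian bumps
    (chord-distance metric) centered at the given sensors."""
    topo = np.zeros(montage.n_sensors)
    for sid in peak_ids:
        d = np.linalg.norm(montage.positions - montage.position(sid), axis=1)
        topo += np.exp(-0.5 * (d / width) ** 2)
    return topo / np.linalg.norm(topo)


def _phases_from_lag(phase1_deg: np.ndarray, lag_ms: np.ndarray) -> np.ndarray:
    return (np.asarray(phase1_deg) + np.asarray(lag_ms) * DEG_PER_MS) % 360.0


def default_ground_truth(task: str, montage: Montage | None = None) -> GroundTruth:
    """Default two-source ground truth per task.

    Letter: a left-lateral occipital source (peaks at sensors 65/66) with a
    monotone-saturating 1F amplitude tuning and near-constant phase, and a
    medial-posterior source (75/83) whose amplitude peaks at the 0.6-logMAR
    level and which lags the first source by 100 ms at the smallest size,
    shrinking to 40 ms at the largest.

    Vernier: a medial-occipital source (75) and a weaker right-lateral
    source (90/91), both with amplitudes linear in log offset and a
    constant 90 ms lag of the lateral source behind the medial one.
    """
    montage = montage or load_montage()
    if task == "letter":
        phase1 = np.array([95.0, 93.0, 91.0, 89.0, 87.0])
        lag = np.array([100.0, 85.0, 70.0, 55.0, 40.0])
        s1 = SourceSpec(
            name="letter-lateral",
            topography=gaussian_topography(montage, [65, 66]),
            tuning_amp_1f=np.array([0.6, 1.4, 2.2, 2.7, 2.8]),
            tuning_amp_2f=np.array([0.3, 0.5, 0.7, 0.8, 0.8]),
            phase_1f_deg=phase1,
            phase_2f_deg=(2 * phase1) % 360.0,
        )
        phase2 = _phases_from_lag(phase1, lag)
        s2 = SourceSpec(
            name="letter-medial",
            topography=gaussian_topography(montage, [75, 83]),
            tuning_amp_1f=np.array([0.6, 1.2, 1.6, 1.1, 0.6]),
            tuning_amp_2f=np.array([0.4, 0.9, 1.2, 1.0, 0.7]),
            phase_1f_deg=phase2,
            phase_2f_deg=(2 * phase2) % 360.0,
        )
        return GroundTruth(task="letter", source1=s1, source2=s2, latency_lag_ms=lag)
    if task == "vernier":
        phase1 = np.array([110.0, 105.0, 100.0, 95.0, 90.0])
        lag = np.full(5, 90.0)
        s1 = SourceSpec(
            name="vernier-medial",
            topography=gaussian_topography(montage, [75]),
            tuning_amp_1f=np.array([0.68, 1.28, 1.89, 2.5, 3.11]),
            tuning_amp_2f=np.array([0.3, 0.5, 0.7, 0.9, 1.1]),
            phase_1f_deg=phase1,
            phase_2f_deg=(2 * phase1) % 360.0,
        )
        phase2 = _phases_from_lag(phase1, lag)
        s2 = SourceSpec(
            name="vernier-lateral",
            topography=gaussian_topography(montage, [90, 91]),
            tuning_amp_1f=np.array([0.38, 0.7, 1.04, 1.38, 1.71]),
            tuning_amp_2f=np.array([0.25, 0.45, 0.65, 0.85, 1.05]),
            phase_1f_deg=phase2,
            phase_2f_deg=(2 * phase2) % 360.0,
        )
        return GroundTruth(task="vernier", source1=s1, source2=s2, latency_lag_ms=lag)
    raise ValueError(f"unknown task {task!r}")


def _pink_spectrum_shape(n_samples: int, fs: float, exponent: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, 1 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    return shape


def _make_noise(n_channels: int, n_samples: int, fs: float, noise: NoiseSpec,
                montage: Montage, rng: np.random.Generator) -> np.ndarray:
    """Spatially mixed 1/f noise, normalized to the target per-channel RMS.

    Synthesized in channel chunks and stored as float32: a full session is
    128 channels × ~0.5 M samples and the frequency-domain shaping would
    otherwise hold several complex float64 copies at once.
    """
    shape = _pink_spectrum_shape(n_samples, fs, noise.pink_exponent)

    def pink(n_series: int, chunk: int = 16) -> np.ndarray:
        out = np.empty((n_series, n_samples), dtype=np.float32)
        for lo in range(0, n_series, chunk):
            hi = min(lo + chunk, n_series)
            spec = (rng.standard_normal((hi - lo, len(shape)))
                    + 1j * rng.standard_normal((hi - lo, len(shape)))) * shape
            x = np.fft.irfft(spec, n=n_samples, axis=1)
            out[lo:hi] = (x / x.std(axis=1, keepdims=True)).astype(np.float32)
        return out

    out = pink(n_channels)
    out *= np.float32(np.sqrt(1.0 - noise.mixing_fraction))
    if noise.n_mixing > 0 and noise.mixing_fraction > 0:
        centers = rng.integers(1, montage.n_sensors + 1, size=noise.n_mixing)
        mixing = np.column_stack(
            [gaussian_topography(montage, [int(c)], width=0.5) for c in centers])
        mixing *= np.sqrt(n_channels / noise.n_mixing)  # keep unit variance scale
        shared = pink(noise.n_mixing)
        out += np.sqrt(noise.mixing_fraction) * (mixing.astype(np.float32) @ shared)
    out *= (noise.noise_rms_uv / out.std(axis=1, keepdims=True)).astype(np.float32)
    return out


def _blink_weights(montage: Montage) -> np.ndarray:
    w = np.clip(montage.positions[:, 1], 0.0, None) ** 2  # frontal (+y) emphasis
    return w / w.max()


def simulate_session(schedule: Schedule, gt: GroundTruth | list[GroundTruth],
                     noise: NoiseSpec | None = None, fs: float = 500.0,
                     seed: int = 0, montage: Montage | None = None,
                     condition_table: pd.DataFrame | None = None,
                     amp_jitter: float = 0.1) -> RawSession:
    """Render a schedule into a RawSession at the native acquisition rate.

    Trials are laid back-to-back. Each trial's clean signal is the sum over
    the task's two sources of their 1F/2F harmonic time courses (phases
    relative to trial onset) projected through the source topographies;
    per-trial source amplitudes get a seeded multiplicative jitter of
    ``±amp_jitter``. Conditions belonging to tasks without a supplied
    ground truth contribute noise only.
    """
    montage = montage or load_montage()
    noise = noise or NoiseSpec()
    if condition_table is None:
        condition_table = standard_condition_table()
    gts = {g.task: g for g in ([gt] if isinstance(gt, GroundTruth) else gt)}
    rng = np.random.default_rng(seed)

    # map condition id -> (task, level index within task, ascending logMAR)
    level_of = {}
    for task, sub in condition_table.groupby("task"):
        sub = sub.sort_values("logmar")
        for lvl, cond in enumerate(sub["condition"]):
            level_of[int(cond)] = (task, lvl)

    trials = list(schedule.trials())
    n_samples = int(sum(round(dur * fs) for *_, dur in trials))
    data = _make_noise(montage.n_sensors, n_samples, fs, noise, montage, rng)

    events = []
    onset = 0
    for trial, block, cond, dur in trials:
        n = int(round(dur * fs))
        task, lvl = level_of[cond]
        g = gts.get(task)
        if g is not None:
            t = np.arange(n) / fs
            block_sig = np.zeros((montage.n_sensors, n))
            for src in (g.source1, g.source2):
                course = np.zeros(n)
                for k, amps, phases in ((1, src.tuning_amp_1f, src.phase_1f_deg),
                                        (2, src.tuning_amp_2f, src.phase_2f_deg)):
                    jit = 1.0 + amp_jitter * rng.uniform(-1, 1)
                    amp = amps[lvl] * jit
                    course += amp * np.cos(2 * np.pi * k * STIM_FREQ_HZ * t
                                           - np.deg2rad(phases[lvl]))
                block_sig += np.outer(src.topography, course)
            data[:, onset:onset + n] += block_sig
        events.append({"trial": trial, "block": block, "condition": cond,
                       "onset": onset, "duration_s": dur})
        onset += n

    # blink transients at Poisson times over the whole session
    blink_w = _blink_weights(montage)
    blinks = []
    if noise.blink_rate_hz > 0 and noise.blink_amp_uv > 0:
        n_blinks = rng.poisson(noise.blink_rate_hz * n_samples / fs)
        dur_n = int(round(noise.blink_dur_s * fs))
        kernel = noise.blink_amp_uv * 0.5 * (1 - np.cos(
            2 * np.pi * np.arange(dur_n) / dur_n))
        for start in np.sort(rng.integers(0, max(n_samples - dur_n, 1), size=n_blinks)):
            data[:, start:start + dur_n] += np.outer(blink_w, kernel)
            blinks.append((float(start / fs), noise.blink_dur_s))

    return RawSession(
        data=data, fs=fs, events=pd.DataFrame(events),
        condition_table=condition_table, history=["simulate"],
        meta={"blinks_s": blinks, "gt_tasks": sorted(gts), "seed": seed},
    )
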