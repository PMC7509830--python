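"""Bin-centered spectral analysis of the steady-state response.

Trials are epoched into whole-cycle windows (2 s = 6 cycles at 3 Hz) after
a 1 s onset discard, transformed by a rectangular-window DFT with 0.5 Hz
resolution, and averaged *coherently* (complex mean, preserving phase) so
that non-phase-locked background cancels as 1/sqrt(N) while the evoked
harmonics survive.

Conventions
-----------
Amplitude scaling is single-sided amplitude spectral density: a pure
cosine of amplitude A µV at a bin center reads |coeff| = A. Phase is a
cosine *lag*: x(t) = A·cos(2πft − φ) yields a stored coefficient
A·e^{iφ} (the conjugate of the raw DFT coefficient), so a larger phase
means a later response and phase 0 is stimulus onset.

Noise at each harmonic is estimated from the two neighboring 0.5 Hz bins
(2.5/3.5 Hz for 1F, 5.5/6.5 Hz for 2F), coherently averaged the same way
as the signal, then magnitude-averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PreprocessReport, reject_epochs
from .session import AnalysisConfig, RawSession

__all__ = [
    "EpochSpectra",
    "HarmonicResponse",
    "epoch_trial",
    "collect_epochs",
    "dft_epoch",
    "compute_spectra",
    "coherent_average",
    "snr_db",
]


def epoch_trial(trial_data: np.ndarray, fs: float, discard_s: float = 1.0,
                epoch_s: float = 2.0) -> list[np.ndarray]:
    """Tile a trial into non-overlapping epochs after an onset discard.

    A partial tail shorter than one epoch is dropped. Returns an empty
    list (with a warning) if the trial cannot hold a single epoch.
    """
    trial_data = np.atleast_2d(trial_data)
    n_discard = int(round(discard_s * fs))
    n_epoch = int(round(epoch_s * fs))
    usable = trial_data.shape[1] - n_discard
    if usable < n_epoch:
        warnings.warn("trial too short for a single epoch", stacklevel=2)
        return []
    n_epochs = usable // n_epoch
    return [trial_data[:, n_discard + i * n_epoch: n_discard + (i + 1) * n_epoch]
            for i in range(n_epochs)]


def collect_epochs(session: RawSession, config: AnalysisConfig | None = None
                   ) -> dict[tuple[int, int], np.ndarray]:
    """All epochs of a session keyed by (trial, epoch index)."""
    config = config or AnalysisConfig()
    out = {}
    for row in session.events.itertuples(index=False):
        trial_data = session.data[:, session.trial_slice(row)]
        for i, ep in enumerate(epoch_trial(trial_data, session.fs,
                                           config.discard_s, config.epoch_len_s)):
            out[(int(row.trial), i)] = ep
    return out


def dft_epoch(epoch: np.ndarray, fs: float,
              epoch_s: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Single-epoch DFT under the package's amplitude/phase conventions.

    Returns ``(coeffs, freqs)`` where ``coeffs`` is channels × bins complex
    with |coeff| in µV ASD and angle the cosine lag. The epoch length must
    match ``epoch_s × fs`` exactly when ``epoch_s`` is given — no silent
    zero-padding.
    """
    epoch = np.atleast_2d(epoch)
    n = epoch.shape[1]
    if epoch_s is not None and n != int(round(epoch_s * fs)):
        raise ValueError(f"epoch has {n} samples, expected {int(round(epoch_s * fs))}")
    raw = np.fft.rfft(epoch, axis=1)
    coeffs = np.conj(raw) * (2.0 / n)
    coeffs[:, 0] /= 2.0
    if n % 2 == 0:
        coeffs[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return coeffs, freqs


@dataclass
class EpochSpectra:
    """Complex spectra for all surviving epochs.

    coeffs : (n_epochs, n_channels, n_bins) complex
    freqs : bin centers in Hz (0.5 Hz spacing for 2 s epochs)
    meta : DataFrame with columns trial, block, condition, epoch
    scaling : amplitude convention tag
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    meta: pd.DataFrame
    scaling: str = "asd-uv-single-sided"

    def bin_index(self, freq_hz: float) -> int:
        idx = int(np.argmin(np.abs(self.freqs - freq_hz)))
        if abs(self.freqs[idx] - freq_hz) > 1e-9:
            raise ValueError(f"{freq_hz} Hz is not an exact bin center")
        return idx


def compute_spectra(session: RawSession, config: AnalysisConfig | None = None,
                    reject: bool = True
                    ) -> tuple[EpochSpectra, PreprocessReport]:
    """Epoch a preprocessed session, reject artifacts, and transform.

    Rejection follows the configured voltage threshold; the report lists
    the rejected (trial, epoch) pairs and the rejection fraction.
    """
    config = config or AnalysisConfig()
    epochs = collect_epochs(session, config)
    if reject:
        report = reject_epochs(epochs, threshold_uv=config.reject_threshold_uv)
        bad = set(report.rejected_epochs)
    else:
        report = PreprocessReport(threshold_uv=None)
        bad = set()
    ev = session.events.set_index("trial")
    coeffs, meta = [], []
    freqs = None
    for (trial, i), ep in epochs.items():
        if (trial, i) in bad:
            continue
        c, freqs = dft_epoch(ep, session.fs, config.epoch_len_s)
        coeffs.append(c)
        meta.append({"trial": trial, "block": int(ev.loc[trial, "block"]),
                     "condition": int(ev.loc[trial, "condition"]), "epoch": i})
    if not coeffs:
        raise ValueError("no epochs survived rejection")
    return EpochSpectra(coeffs=np.array(coeffs), freqs=freqs,
                        meta=pd.DataFrame(meta)), report


@dataclass
class HarmonicResponse:
    """Coherent condition average at one harmonic.

    ``mean_coeff`` is the complex mean over epochs per channel (µV ASD);
    ``noise_coeffs`` holds the coherent averages at the two neighbor bins,
    and ``noise_amp`` their magnitude average — the empirical noise floor
    on the same scale as the signal.
    """

    harmonic: int
    freq_hz: float
    condition: int
    mean_coeff: np.ndarray     # (n_channels,) complex
    noise_coeffs: np.ndarray   # (2, n_channels) complex
    noise_amp: np.ndarray      # (n_channels,)
    n_epochs: int

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.mean_coeff)


def coherent_average(spectra: EpochSpectra, config: AnalysisConfig | None = None,
                     group_by: str = "condition") -> list[HarmonicResponse]:
    """Complex (phase-preserving) averages per condition and harmonic.

    Pooling is flat over surviving epochs, which reproduces the
    epochs-within-trials-within-blocks hierarchy when counts are equal and
    weights epochs equally when rejection made them unequal.
    """
    config = config or AnalysisConfig()
    out = []
    for cond, idx in spectra.meta.groupby(group_by).groups.items():
        rows = spectra.meta.index.get_indexer(idx)
        mean_spec = spectra.coeffs[rows].mean(axis=0)  # channels × bins
        for k in config.harmonics:
            f = k * config.stim_freq_hz
            sig = mean_spec[:, spectra.bin_index(f)]
            nb = [mean_spec[:, spectra.bin_index(nf)] for nf in config.noise_freqs(k)]
            noise_coeffs = np.array(nb)
            out.append(HarmonicResponse(
                harmonic=k, freq_hz=f, condition=int(cond), mean_coeff=sig,
                noise_coeffs=noise_coeffs,
                noise_amp=np.abs(noise_coeffs).mean(axis=0),
                n_epochs=len(rows)))
    return out


def snr_db(signal_amp, noise_amp):
    """Power SNR in dB: 10·log10(signal²/noise²). Zero noise → +inf."""
    signal_amp = np.asarray(signal_amp, dtype=float)
    noise_amp = np.asarray(noise_amp, dtype=float)
    if np.any(noise_amp == 0):
        warnings.warn("zero noise amplitude; SNR reported as +inf", stacklevel=2)
    with np.errstate(divide="ignore"):
        out = 10.0 * np.log10(signal_amp ** 2) - 10.0 * np.log10(noise_amp ** 2)
    return out if out.ndim else float(out)


def responses_to_frame(responses: list[HarmonicResponse],
                       condition_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-form export: one row per (condition, harmonic, channel)."""
    rows = []
    for r in responses:
        for ch in range(len(r.mean_coeff)):
            z = r.mean_coeff[ch]
            rows.append({
                "condition": r.condition, "harmonic": r.harmonic, "channel": ch + 1,
                "re": z.real, "im": z.imag, "amp": abs(z),
                "phase_deg": float(np.degrees(np.angle(z)) % 360.0),
                "noise_amp": r.noise_amp[ch],
                "snr_db": snr_db(abs(z), r.noise_amp[ch]),
            })
    df = pd.DataFrame(rows)
    if condition_table is not None:
        df = df.merge(condition_table, on="condition", how="left")
    return df
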