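"""Preprocessing chain: resample, bandpass, bad-channel replacement,
common average reference, and threshold-based epoch rejection.

Stages are applied in the fixed order resample → bandpass → replace_bad →
reref (epoch rejection then operates on epoched data); each stage records
itself in the session history and refuses to run after a later stage,
which keeps the 140-samples-per-cycle guarantee and the reference
convention consistent for the spectral stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .montage import Montage
from .session import RawSession

__all__ = [
    "PreprocessReport",
    "PipelineOrderError",
    "QualityError",
    "resample_session",
    "bandpass_session",
    "replace_bad_channels",
    "rereference_average",
    "reject_epochs",
]

_STAGE_ORDER = {"resample": 1, "bandpass": 2, "replace_bad": 3, "reref": 4}


class PipelineOrderError(RuntimeError):
    """A preprocessing stage was invoked after a later stage already ran."""


class QualityError(ValueError):
    """Data quality too poor to proceed (e.g. too many bad channels)."""


@dataclass
class PreprocessReport:
    replaced_channels: list[int] = field(default_factory=list)
    rejected_epochs: list[tuple[int, int]] = field(default_factory=list)
    rejection_fraction: float = 0.0
    threshold_uv: float | None = None

    def to_json(self) -> str:
        return json.dumps({
            "replaced_channels": list(map(int, self.replaced_channels)),
            "rejected_epochs": [list(map(int, e)) for e in self.rejected_epochs],
            "rejection_fraction": self.rejection_fraction,
            "threshold_uv": self.threshold_uv,
        })


def _check_order(session: RawSession, stage: str) -> None:
    done = [_STAGE_ORDER[s] for s in session.history if s in _STAGE_ORDER]
    if done and _STAGE_ORDER[stage] <= max(done):
        raise PipelineOrderError(
            f"stage '{stage}' cannot run after "
            f"{[s for s in session.history if s in _STAGE_ORDER]}")


def resample_session(raw: RawSession, target_hz: int = 420,
                     stim_freq_hz: float = 3.0) -> RawSession:
    """Polyphase resampling to a rate with an integer number of samples per
    stimulus cycle (420 Hz → 140 samples at 3 Hz); events are remapped."""
    _check_order(raw, "resample")
    spc = target_hz / stim_freq_hz
    if abs(spc - round(spc)) > 1e-9:
        raise ValueError(
            f"target rate {target_hz} Hz does not give an integer number of "
            f"samples per {stim_freq_hz} Hz cycle")
    if target_hz == raw.fs:
        return raw.with_data(raw.data.copy(), stage="resample")
    frac = Fraction(int(round(target_hz * 1000)), int(round(raw.fs * 1000)))
    up, down = frac.numerator, frac.denominator
    # computed in the session's own dtype (float32 sessions stay float32)
    data = signal.resample_poly(raw.data, up, down, axis=1)
    ratio = target_hz / raw.fs
    events = raw.events.copy()
    events["onset"] = np.round(events["onset"] * ratio).astype(int)
    return raw.with_data(data.astype(raw.data.dtype), fs=float(target_hz),
                         events=events, stage="resample")


def _fir_kernel(lo: float, hi: float, fs: float,
                trans_lo: float = 0.2, trans_hi: float = 5.0) -> np.ndarray:
    """Linear-phase bandpass as highpass*lowpass cascade with separate
    transition widths per edge; symmetric, hence zero-phase when applied
    centered."""
    def odd(n):
        return int(np.ceil(n)) | 1

    n_hp = odd(3.3 * fs / trans_lo)
    n_lp = odd(3.3 * fs / trans_hi)
    hp = signal.firwin(n_hp, lo + trans_lo / 2, fs=fs, pass_zero=False)
    lp = signal.firwin(n_lp, hi, fs=fs, pass_zero=True)
    kernel = np.convolve(hp, lp)
    kernel -= kernel.sum() / len(kernel)  # exact null at DC
    return kernel


def bandpass_session(raw: RawSession, lo: float = 0.3, hi: float = 50.0) -> RawSession:
    """Zero-phase FIR bandpass (applied by centered FFT convolution)."""
    _check_order(raw, "bandpass")
    if not 0 < lo < hi < raw.fs / 2:
        raise ValueError(f"invalid band edges ({lo}, {hi}) at fs={raw.fs}")
    kernel = _fir_kernel(lo, hi, raw.fs).astype(raw.data.dtype)
    data = signal.fftconvolve(raw.data, kernel[None, :], mode="same", axes=1)
    return raw.with_data(data.astype(raw.data.dtype), stage="bandpass")


def replace_bad_channels(raw: RawSession, bad: list[int], montage: Montage,
                         n_neighbors: int = 6) -> tuple[RawSession, PreprocessReport]:
    """Replace each bad channel by the unweighted mean of its ``n_neighbors``
    nearest non-bad sensors (chord distance), widening past immediate
    adjacency when needed."""
    _check_order(raw, "replace_bad")
    bad = sorted(set(int(b) for b in bad))
    if len(bad) > 0.25 * raw.n_channels:
        raise QualityError(f"{len(bad)} bad channels exceeds 25% of the montage")
    data = raw.data.copy()
    for sid in bad:
        donors = montage.nearest(sid, k=n_neighbors, exclude=set(bad))
        data[sid - 1] = np.mean([raw.data[d - 1] for d in donors], axis=0)
    out = raw.with_data(data, stage="replace_bad")
    return out, PreprocessReport(replaced_channels=bad)


def rereference_average(raw: RawSession) -> RawSession:
    """Common average reference: subtract the instantaneous channel mean."""
    _check_order(raw, "reref")
    data = raw.data - raw.data.mean(axis=0, keepdims=True)
    return raw.with_data(data, stage="reref")


def reject_epochs(epochs, threshold_uv: float = 60.0,
                  max_bad_fraction: float = 0.1) -> PreprocessReport:
    """Threshold-based artifact rejection.

    ``epochs`` maps ``(trial, epoch)`` keys to channels × samples arrays
    (a plain sequence is keyed by ``(i, 0)``). An epoch is rejected when
    more than ``max_bad_fraction`` of its samples have ``|v|`` above the
    threshold on at least one channel.
    """
    if hasattr(epochs, "items"):
        items = list(epochs.items())
    else:
        items = [((i, 0), e) for i, e in enumerate(epochs)]
    if not 30.0 <= threshold_uv <= 80.0:
        warnings.warn("rejection threshold outside the usual 30-80 µV range",
                      stacklevel=2)
    rejected = []
    for key, ep in items:
        bad_sample = np.any(np.abs(ep) > threshold_uv, axis=0)
        if bad_sample.mean() > max_bad_fraction:
            rejected.append(tuple(int(k) for k in key))
    frac = len(rejected) / len(items) if items else 0.0
    return PreprocessReport(rejected_epochs=rejected, rejection_fraction=frac,
                            threshold_uv=threshold_uv)
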