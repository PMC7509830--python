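"""Annotated multichannel recordings and the shared analysis configuration.

A :class:`RawSession` is the container every stage consumes: a channels ×
samples voltage array (µV), its sampling rate, a trial event table and a
condition table mapping condition ids to (task, logMAR). The package's
native on-disk format is a documented HDF5 layout (groups ``/data``,
``/events``, ``/conditions``); EDF is supported read-only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "AnalysisConfig",
    "RawSession",
    "SessionFormatError",
    "read_session",
    "write_session",
]

EVENT_COLUMNS = ["trial", "block", "condition", "onset", "duration_s"]
CONDITION_COLUMNS = ["condition", "task", "logmar"]
TASKS = ("vernier", "letter")


class SessionFormatError(ValueError):
    """Raised when a session file violates the expected layout."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Fixed analysis parameters of the 3 Hz alternation paradigm.

    ``resample_hz`` must give an integer number of samples per stimulus
    cycle, and ``epoch_len_s`` an integer number of cycles per epoch; these
    two facts make the harmonic bins exact DFT bin centers.
    """

    stim_freq_hz: float = 3.0
    harmonics: tuple[int, int] = (1, 2)
    epoch_len_s: float = 2.0
    discard_s: float = 1.0
    resample_hz: int = 420
    bandpass_hz: tuple[float, float] = (0.3, 50.0)
    reject_threshold_uv: float = 60.0
    noise_offset_hz: float = 0.5  # neighbor bins at harmonic ± this offset

    def __post_init__(self) -> None:
        cycles = self.epoch_len_s * self.stim_freq_hz
        if abs(cycles - round(cycles)) > 1e-9:
            raise ValueError("epoch_len_s × stim_freq_hz must be an integer")
        spc = self.resample_hz / self.stim_freq_hz
        if abs(spc - round(spc)) > 1e-9:
            raise ValueError("resample_hz / stim_freq_hz must be an integer")
        if not 30.0 <= self.reject_threshold_uv <= 80.0:
            warnings.warn("rejection threshold outside the usual 30-80 µV range",
                          stacklevel=2)

    @property
    def cycles_per_epoch(self) -> int:
        return round(self.epoch_len_s * self.stim_freq_hz)

    @property
    def samples_per_cycle(self) -> int:
        return round(self.resample_hz / self.stim_freq_hz)

    def harmonic_freqs(self) -> dict[int, float]:
        return {k: k * self.stim_freq_hz for k in self.harmonics}

    def noise_freqs(self, harmonic: int) -> tuple[float, float]:
        f = harmonic * self.stim_freq_hz
        return (f - self.noise_offset_hz, f + self.noise_offset_hz)


@dataclass
class RawSession:
    """Channels × samples voltage data with trial annotations.

    Parameters
    ----------
    data : (n_channels, n_samples) array, µV
    fs : sampling rate in Hz
    events : DataFrame with columns trial, block, condition, onset, duration_s
        ``onset`` is a 0-based sample index; a trial occupies the half-open
        window ``[onset, onset + round(duration_s * fs))``.
    condition_table : DataFrame with columns condition, task, logmar
    history : ordered names of processing stages already applied
    meta : free-form extras (e.g. simulator ground-truth annotations)
    """

    data: np.ndarray
    fs: float
    events: pd.DataFrame
    condition_table: pd.DataFrame
    history: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        self.events = pd.DataFrame(self.events, columns=EVENT_COLUMNS).reset_index(drop=True)
        self.condition_table = pd.DataFrame(
            self.condition_table, columns=CONDITION_COLUMNS).reset_index(drop=True)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n = self.data.shape[1]
        ends = self.events["onset"] + np.round(self.events["duration_s"] * self.fs)
        if (self.events["onset"] < 0).any() or (ends > n).any():
            raise SessionFormatError("event window falls outside the data array")
        known = set(self.condition_table["condition"])
        used = set(self.events["condition"])
        if not used <= known:
            raise SessionFormatError(
                f"events reference unknown condition ids {sorted(used - known)}")
        bad_tasks = set(self.condition_table["task"]) - set(TASKS)
        if bad_tasks:
            raise SessionFormatError(f"unknown tasks {sorted(bad_tasks)}")

    # -- helpers ---------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def trial_slice(self, event_row) -> slice:
        onset = int(event_row.onset)
        return slice(onset, onset + int(round(event_row.duration_s * self.fs)))

    def conditions_for_task(self, task: str) -> pd.DataFrame:
        sub = self.condition_table[self.condition_table["task"] == task]
        return sub.sort_values("logmar").reset_index(drop=True)

    def with_data(self, data: np.ndarray, *, fs: float | None = None,
                  events: pd.DataFrame | None = None, stage: str | None = None) -> "RawSession":
        new = replace(
            self,
            data=data,
            fs=self.fs if fs is None else fs,
            events=self.events.copy() if events is None else events,
            condition_table=self.condition_table.copy(),
            history=list(self.history) + ([stage] if stage else []),
            meta=dict(self.meta),
        )
        return new


# -- HDF5 native layout --------------------------------------------------
#   /data/voltage   float array (channels × samples), attrs: fs, unit="uV"
#   /events         structured dataset with EVENT_COLUMNS
#   /conditions     structured dataset with CONDITION_COLUMNS
#   attrs: history (JSON list), meta (JSON object)

def write_session(session: RawSession, path: str | Path) -> None:
    """Write a session in the package's native HDF5 layout."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("data")
        ds = grp.create_dataset("voltage", data=session.data)
        ds.attrs["fs"] = float(session.fs)
        ds.attrs["unit"] = "uV"
        ev = session.events
        ev_rec = np.rec.fromarrays(
            [ev["trial"].astype(np.int64), ev["block"].astype(np.int64),
             ev["condition"].astype(np.int64), ev["onset"].astype(np.int64),
             ev["duration_s"].astype(np.float64)],
            names=EVENT_COLUMNS)
        f.create_dataset("events", data=ev_rec)
        ct = session.condition_table
        ct_rec = np.rec.fromarrays(
            [ct["condition"].astype(np.int64),
             ct["task"].astype("S16"), ct["logmar"].astype(np.float64)],
            names=CONDITION_COLUMNS)
        f.create_dataset("conditions", data=ct_rec)
        f.attrs["history"] = json.dumps(session.history)
        f.attrs["meta"] = json.dumps(session.meta, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _read_hdf5(path: Path) -> RawSession:
    with h5py.File(path, "r") as f:
        for key in ("data", "events", "conditions"):
            if key not in f:
                raise SessionFormatError(f"missing required group/dataset '/{key}'")
        ds = f["data"]["voltage"]
        data = ds[()]
        fs = float(ds.attrs["fs"])
        ev = pd.DataFrame(np.asarray(f["events"][()]))
        ct = pd.DataFrame(np.asarray(f["conditions"][()]))
        ct["task"] = ct["task"].str.decode("utf-8")
        history = json.loads(f.attrs.get("history", "[]"))
        meta = json.loads(f.attrs.get("meta", "{}"))
    return RawSession(data=data, fs=fs, events=ev, condition_table=ct,
                      history=history, meta=meta)


def _read_edf(path: Path) -> RawSession:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE stores volts
    fs = float(raw.info["sfreq"])
    sidecar = path.with_suffix(".events.json")
    if not sidecar.exists():
        raise SessionFormatError(
            "EDF session is missing its events: expected sidecar file "
            f"{sidecar.name} with 'events' and 'conditions' tables")
    payload = json.loads(sidecar.read_text())
    for key in ("events", "conditions"):
        if key not in payload:
            raise SessionFormatError(f"EDF sidecar missing field {key!r}")
    ev = pd.DataFrame(payload["events"], columns=EVENT_COLUMNS)
    ct = pd.DataFrame(payload["conditions"], columns=CONDITION_COLUMNS)
    return RawSession(data=data, fs=fs, events=ev, condition_table=ct)


def read_session(path: str | Path, dialect: str = "hdf5",
                 expect_channels: int | None = 128) -> RawSession:
    """Read a session from disk.

    Parameters
    ----------
    dialect : {"hdf5", "edf"}
        ``hdf5`` is the native read/write layout; ``edf`` is read-only and
        takes its event tables from a ``<name>.events.json`` sidecar.
    expect_channels : int or None
        Required channel count (None disables the check).
    """
    path = Path(path)
    if dialect == "hdf5":
        session = _read_hdf5(path)
    elif dialect == "edf":
        session = _read_edf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if expect_channels is not None and session.n_channels != expect_channels:
        raise SessionFormatError(
            f"expected {expect_channels} channels, file has {session.n_channels}")
    return session
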