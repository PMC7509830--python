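"""Shared fixtures: montage, small synthetic sessions, and (for the
acceptance suite) full-size simulated sessions analyzed once per run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ssvepkit as sk


@pytest.fixture(scope="session")
def montage():
    return sk.load_montage()


@pytest.fixture(scope="session")
def condition_table():
    return sk.standard_condition_table()


def tiny_session(n_channels=4, n_trials=3, fs=50.0, trial_s=4.0, seed=0):
    """A small annotated session with arbitrary data for I/O tests."""
    rng = np.random.default_rng(seed)
    n = int(n_trials * trial_s * fs)
    events = pd.DataFrame({
        "trial": np.arange(n_trials),
        "block": np.zeros(n_trials, dtype=int),
        "condition": np.ones(n_trials, dtype=int),
        "onset": (np.arange(n_trials) * trial_s * fs).astype(int),
        "duration_s": np.full(n_trials, trial_s),
    })
    table = pd.DataFrame({"condition": [1], "task": ["vernier"], "logmar": [0.15]})
    return sk.RawSession(data=rng.standard_normal((n_channels, n)), fs=fs,
                         events=events, condition_table=table)


def write_minimal_edf(path, data, fs):
    """Hand-rolled minimal EDF writer (int16, one data record per second).

    Only what the reader needs: ns channels, physical range scaled to the
    data extremes, integer-second record layout.
    """
    n_ch, n_samp = data.shape
    n_records = n_samp // int(fs)
    spr = int(fs)

    def pad(s, n):
        return s[:n].ljust(n)

    hdr = b""
    hdr += pad("0", 8).encode()
    hdr += pad("X X X X", 80).encode()          # patient
    hdr += pad("Startdate X X X X", 80).encode()
    hdr += pad("01.01.20", 8).encode() + pad("00.00.00", 8).encode()
    hdr += pad(str(256 + 256 * n_ch), 8).encode()
    hdr += pad("", 44).encode()
    hdr += pad(str(n_records), 8).encode()
    hdr += pad("1", 8).encode()                  # record duration s
    hdr += pad(str(n_ch), 4).encode()
    for i in range(n_ch):
        hdr += pad(f"EEG {i+1:03d}", 16).encode()
    for _ in range(n_ch):
        hdr += pad("AgAgCl electrode", 80).encode()
    for _ in range(n_ch):
        hdr += pad("uV", 8).encode()
    # round the physical range so the 8-char ASCII header holds it exactly
    lo = float(np.floor(data.min() * 100) / 100)
    hi = float(np.ceil(data.max() * 100) / 100)
    for _ in range(n_ch):
        hdr += pad(f"{lo:.2f}", 8).encode()
    for _ in range(n_ch):
        hdr += pad(f"{hi:.2f}", 8).encode()
    for _ in range(n_ch):
        hdr += pad("-32768", 8).encode()
    for _ in range(n_ch):
        hdr += pad("32767", 8).encode()
    for _ in range(n_ch):
        hdr += pad("", 80).encode()
    for _ in range(n_ch):
        hdr += pad(str(spr), 8).encode()
    for _ in range(n_ch):
        hdr += pad("", 32).encode()

    scale = (hi - lo) / (32767 - (-32768))
    with open(path, "wb") as f:
        f.write(hdr)
        for rec in range(n_records):
            seg = data[:, rec * spr:(rec + 1) * spr]
            dig = np.round((seg - lo) / scale + (-32768)).astype("<i2")
            f.write(dig.tobytes())
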