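"""Tuning curves, phase-to-latency estimation, and the statistical tests.

Phase is a cosine lag relative to stimulus onset (larger phase = later
response). A phase difference Δφ at frequency f maps to a latency of
Δφ/(360·f)·1000 ms — but only modulo one stimulus period (333.3 ms at
3 Hz), so every estimate carries its family of wrap-around candidates
Δt + k·(1000/f). The minimal-magnitude candidate (k = 0) is reported by
default; disambiguation beyond that is a plausibility argument, not an
algorithm, and the candidates are always exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TuningResult",
    "LatencyEstimate",
    "phase_deg",
    "phase_difference",
    "phase_to_latency",
    "component_latency_lag",
    "snr_significance",
    "rm_anova_2way",
]


def phase_deg(z: complex) -> float:
    """Angle of a complex coefficient in [0, 360); NaN (with warning) at 0."""
    if z == 0:
        warnings.warn("phase of a zero coefficient is undefined", stacklevel=2)
        return float("nan")
    return float(np.degrees(np.angle(z)) % 360.0)


def phase_difference(phi1_deg: float, phi2_deg: float) -> float:
    """Minimal signed difference phi2 − phi1, wrapped into (−180, 180]."""
    d = (np.asarray(phi2_deg, dtype=float) - phi1_deg) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    return d if d.ndim else float(d)


@dataclass(frozen=True)
class LatencyEstimate:
    """A phase difference expressed as a latency plus its wrap-around family."""

    delta_phase_deg: float
    freq_hz: float
    latency_ms: float
    candidates_ms: tuple[float, ...]
    chosen_k: int = 0

    @property
    def latency_ms_report(self) -> float:
        """Latency rounded to 0.1 ms for reporting."""
        return round(self.latency_ms, 1)


def phase_to_latency(delta_deg: float, freq_hz: float,
                     candidate_ks=(-1, 0, 1, 2)) -> LatencyEstimate:
    """Latency implied by a phase difference, with wrap-around candidates."""
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    period_ms = 1000.0 / freq_hz
    latency = delta_deg / 360.0 * period_ms
    candidates = tuple(latency + k * period_ms for k in candidate_ks)
    return LatencyEstimate(delta_phase_deg=float(delta_deg), freq_hz=freq_hz,
                           latency_ms=latency, candidates_ms=candidates)


@dataclass
class TuningResult:
    """Per-component amplitude/phase/SNR across the five stimulus levels."""

    component: int
    task: str
    harmonic: int
    logmar_levels: np.ndarray
    amplitude: np.ndarray
    phase_deg: np.ndarray
    snr_db: np.ndarray
    noise_floor: np.ndarray

    def __post_init__(self):
        for attr in ("logmar_levels", "amplitude", "phase_deg", "snr_db",
                     "noise_floor"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        n = len(self.logmar_levels)
        for attr in ("amplitude", "phase_deg", "snr_db", "noise_floor"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} not aligned with logmar_levels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": self.component, "task": self.task,
            "harmonic": self.harmonic, "logmar": self.logmar_levels,
            "amplitude": self.amplitude, "phase_deg": self.phase_deg,
            "snr_db": self.snr_db, "noise_floor": self.noise_floor,
        })


def component_latency_lag(tuning1: TuningResult, tuning2: TuningResult
                          ) -> list[LatencyEstimate]:
    """Per-level latency of component 2 relative to component 1.

    Positive values mean component 2 lags (responds later than)
    component 1, consistent with phase measured as lag.
    """
    if (tuning1.task != tuning2.task or tuning1.harmonic != tuning2.harmonic
            or not np.allclose(tuning1.logmar_levels, tuning2.logmar_levels)):
        raise ValueError("tuning results are not comparable (task/harmonic/levels)")
    freq = tuning1.harmonic * 3.0
    out = []
    for p1, p2 in zip(tuning1.phase_deg, tuning2.phase_deg):
        out.append(phase_to_latency(phase_difference(p1, p2), freq))
    return out


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def snr_significance(signal_amps, noise_amps) -> PairedTTestResult:
    """Paired two-sided t-test of per-subject signal vs noise amplitudes.

    A conservative test of signal presence: the null is the additive EEG
    noise floor, not zero signal.
    """
    signal_amps = np.asarray(signal_amps, dtype=float)
    noise_amps = np.asarray(noise_amps, dtype=float)
    if signal_amps.shape != noise_amps.shape or signal_amps.ndim != 1:
        raise ValueError("signal and noise amplitudes must be paired 1-D arrays")
    n = len(signal_amps)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    diffs = signal_amps - noise_amps
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return PairedTTestResult(t=0.0, df=n - 1, p=1.0, degenerate=False)
        return PairedTTestResult(t=float("inf") * np.sign(diffs.mean()),
                                 df=n - 1, p=0.0, degenerate=True)
    res = stats.ttest_rel(signal_amps, noise_amps)
    return PairedTTestResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue))


def rm_anova_2way(values, factor_rc, factor_logmar, subject_id) -> dict:
    """Two-way repeated-measures ANOVA (component × logMAR, both within).

    Long-form inputs of equal length. Delegates to a standard
    repeated-measures routine; returns ``{'rc': (F, p), 'logmar': (F, p),
    'interaction': (F, p), 'df': {...}}``.
    """
    from statsmodels.stats.anova import AnovaRM

    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "rc": np.asarray(factor_rc),
                       "logmar": np.asarray(factor_logmar),
                       "subject": np.asarray(subject_id)})
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    res = AnovaRM(df, depvar="value", subject="subject",
                  within=["rc", "logmar"], aggregate_func="mean").fit()
    tab = res.anova_table
    out = {}
    for key, label in (("rc", "rc"), ("logmar", "logmar"),
                       ("interaction", "rc:logmar")):
        row = tab.loc[label]
        out[key] = (float(row["F Value"]), float(row["Pr > F"]))
    out["df"] = {label: (float(tab.loc[label, "Num DF"]),
                         float(tab.loc[label, "Den DF"]))
                 for label in tab.index}
    return out
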