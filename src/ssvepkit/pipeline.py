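"""End-to-end analysis: raw session → RCA component tunings and lags.

Chains the individual stages in their fixed order: resample to 420 Hz,
bandpass 0.3-50 Hz, optional bad-channel replacement, common average
reference, epoching with artifact rejection, bin-centered DFT, coherent
condition averages, per-task RCA at the chosen harmonic, component
projection, and RC1-vs-RC2 latency lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import LatencyEstimate, TuningResult, component_latency_lag
from .montage import Montage, load_montage
from .preprocess import (PreprocessReport, bandpass_session,
                         replace_bad_channels, rereference_average,
                         resample_session)
from .rca import RCModel, build_rc_input, fit_rca, project, reliability_explained
from .session import AnalysisConfig, RawSession
from .spectral import EpochSpectra, HarmonicResponse, coherent_average, compute_spectra

__all__ = ["TaskResult", "AnalysisResult", "StudyResult", "preprocess_session",
           "analyze_session", "analyze_study"]


@dataclass
class TaskResult:
    """RCA decomposition and component tunings for one task at one harmonic."""

    task: str
    harmonic: int
    model: RCModel
    tunings: list[TuningResult]                 # index 0 = RC1, 1 = RC2, ...
    lags: list[LatencyEstimate]                 # RC2 relative to RC1, per level
    reliability_top2: float
    projection: pd.DataFrame

    @property
    def lag_ms(self) -> np.ndarray:
        return np.array([e.latency_ms for e in self.lags])


@dataclass
class AnalysisResult:
    report: PreprocessReport
    responses: list[HarmonicResponse]
    spectra_meta: pd.DataFrame
    tasks: dict[str, TaskResult] = field(default_factory=dict)

    def tuning_frame(self) -> pd.DataFrame:
        frames = [t.to_frame() for tr in self.tasks.values() for t in tr.tunings]
        return pd.concat(frames, ignore_index=True)

    def lag_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.tasks.values():
            levels = tr.tunings[0].logmar_levels
            for lv, est in zip(levels, tr.lags):
                rows.append({"task": tr.task, "harmonic": tr.harmonic,
                             "logmar": lv, "delta_phase_deg": est.delta_phase_deg,
                             "latency_ms": est.latency_ms,
                             "candidates_ms": list(est.candidates_ms)})
        return pd.DataFrame(rows)


def preprocess_session(raw: RawSession, config: AnalysisConfig | None = None,
                       montage: Montage | None = None,
                       bad_channels: list[int] | None = None) -> RawSession:
    """The fixed preprocessing chain up to (and including) re-referencing."""
    config = config or AnalysisConfig()
    out = resample_session(raw, config.resample_hz, config.stim_freq_hz)
    out = bandpass_session(out, *config.bandpass_hz)
    if bad_channels:
        montage = montage or load_montage()
        out, _ = replace_bad_channels(out, bad_channels, montage)
    return rereference_average(out)


def _tunings_for_task(projection: pd.DataFrame, sub_conditions: pd.DataFrame,
                      task: str, harmonic: int, n_components: int
                      ) -> list[TuningResult]:
    merged = projection.merge(sub_conditions, on="condition")
    tunings = []
    for comp in range(1, n_components + 1):
        sub = merged[merged["component"] == comp].sort_values("logmar")
        tunings.append(TuningResult(
            component=comp, task=task, harmonic=harmonic,
            logmar_levels=sub["logmar"].to_numpy(),
            amplitude=sub["amplitude"].to_numpy(),
            phase_deg=sub["phase_deg"].to_numpy(),
            snr_db=sub["snr_db"].to_numpy(),
            noise_floor=sub["noise_amp"].to_numpy()))
    return tunings


@dataclass
class StudyResult:
    """Group-level analysis: RCA fit on observations pooled across
    subjects (sessions), grand-average tunings, and per-subject component
    responses for the statistical tests."""

    tasks: dict[str, TaskResult]
    per_subject: pd.DataFrame     # subject, task, component, logmar, ...
    reports: list[PreprocessReport]

    def subject_amplitudes(self, task: str, component: int
                           ) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject (signal, noise) amplitudes averaged over levels —
        the inputs of the signal-vs-noise-floor paired t-test."""
        sub = self.per_subject[(self.per_subject["task"] == task)
                               & (self.per_subject["component"] == component)]
        g = sub.groupby("subject")
        return (g["amplitude"].mean().to_numpy(),
                g["noise_amp"].mean().to_numpy())


def analyze_study(sessions, config: AnalysisConfig | None = None,
                  montage: Montage | None = None,
                  tasks: list[str] | None = None, harmonic: int = 1,
                  n_components: int = 2, phases_from: str = "filter",
                  preprocessed: bool = False) -> StudyResult:
    """Pooled analysis of several sessions (one per subject).

    RCA observations are pooled across subjects before the fit, as are the
    coherent condition averages (grand averages over all surviving
    epochs); per-subject responses are then projected through the common
    filters. ``sessions`` may be RawSession objects or callables returning
    one (so the caller can generate sessions lazily and bound memory).
    """
    from .rca import RCInput
    from .spectral import HarmonicResponse

    config = config or AnalysisConfig()
    reports, per_subject_rows = [], []
    obs_by_task: dict[str, list] = {}
    tid_by_task: dict[str, list] = {}
    resp_by_subject: list[dict] = []
    condition_table = None
    trial_offset = 0

    for subj, item in enumerate(sessions):
        raw = item() if callable(item) else item
        clean = raw if preprocessed else preprocess_session(raw, config, montage)
        del raw
        condition_table = clean.condition_table
        spectra, report = compute_spectra(clean, config)
        reports.append(report)
        responses = coherent_average(spectra, config)
        resp_by_subject.append({(r.condition, r.harmonic): r for r in responses})
        session_tasks = tasks or sorted(clean.condition_table["task"].unique())
        for task in session_tasks:
            conds = clean.conditions_for_task(task)["condition"].tolist()
            if not set(spectra.meta["condition"]) & set(conds):
                continue
            rc_in = build_rc_input(spectra, harmonic, conds, config, task=task)
            obs_by_task.setdefault(task, []).append(rc_in.observations)
            tid_by_task.setdefault(task, []).append(rc_in.trial_ids + trial_offset)
        trial_offset += int(clean.events["trial"].max()) + 1
        del clean, spectra

    out_tasks: dict[str, TaskResult] = {}
    for task, obs_list in obs_by_task.items():
        inp = RCInput(np.concatenate(obs_list),
                      np.concatenate(tid_by_task[task]), harmonic, task)
        model = fit_rca(inp, n_components=n_components)
        sub = condition_table[condition_table["task"] == task] \
            .sort_values("logmar").reset_index(drop=True)
        conds = sub["condition"].tolist()

        # grand averages: epoch-weighted complex means across subjects
        grand = []
        for cond in conds:
            parts = [d[(cond, harmonic)] for d in resp_by_subject
                     if (cond, harmonic) in d]
            w = np.array([p.n_epochs for p in parts], dtype=float)
            mean_coeff = sum(wi * p.mean_coeff for wi, p in zip(w, parts)) / w.sum()
            noise_coeffs = sum(wi * p.noise_coeffs for wi, p in zip(w, parts)) / w.sum()
            grand.append(HarmonicResponse(
                harmonic=harmonic, freq_hz=harmonic * config.stim_freq_hz,
                condition=cond, mean_coeff=mean_coeff,
                noise_coeffs=noise_coeffs,
                noise_amp=np.abs(noise_coeffs).mean(axis=0),
                n_epochs=int(w.sum())))
        projection = project(model, grand, phases_from=phases_from)
        tunings = _tunings_for_task(projection, sub, task, harmonic, n_components)
        lags = component_latency_lag(tunings[0], tunings[1]) \
            if n_components >= 2 else []
        out_tasks[task] = TaskResult(
            task=task, harmonic=harmonic, model=model, tunings=tunings,
            lags=lags,
            reliability_top2=reliability_explained(model, k=min(2, n_components)),
            projection=projection)

        for subj, d in enumerate(resp_by_subject):
            parts = [d[(cond, harmonic)] for cond in conds
                     if (cond, harmonic) in d]
            proj = project(model, parts, phases_from=phases_from)
            proj = proj.merge(sub, on="condition")
            for row in proj.itertuples(index=False):
                per_subject_rows.append({
                    "subject": subj, "task": task, "component": row.component,
                    "logmar": row.logmar, "amplitude": row.amplitude,
                    "phase_deg": row.phase_deg, "noise_amp": row.noise_amp,
                    "snr_db": row.snr_db})

    return StudyResult(tasks=out_tasks, per_subject=pd.DataFrame(per_subject_rows),
                       reports=reports)


def analyze_session(raw: RawSession, config: AnalysisConfig | None = None,
                    montage: Montage | None = None,
                    bad_channels: list[int] | None = None,
                    tasks: list[str] | None = None, harmonic: int = 1,
                    n_components: int = 2, phases_from: str = "filter",
                    preprocessed: bool = False) -> AnalysisResult:
    """Run the full pipeline on one session.

    Set ``preprocessed=True`` if ``raw`` already went through
    :func:`preprocess_session`. RCA filters are learned separately per
    task on the pooled five-level observations at ``harmonic``.
    """
    config = config or AnalysisConfig()
    clean = raw if preprocessed else preprocess_session(raw, config, montage,
                                                        bad_channels)
    spectra, report = compute_spectra(clean, config)
    responses = coherent_average(spectra, config)
    result = AnalysisResult(report=report, responses=responses,
                            spectra_meta=spectra.meta)

    tasks = tasks or sorted(clean.condition_table["task"].unique())
    for task in tasks:
        sub = clean.conditions_for_task(task)
        conds = sub["condition"].tolist()
        if not set(spectra.meta["condition"]) & set(conds):
            continue
        rc_in = build_rc_input(spectra, harmonic, conds, config, task=task)
        model = fit_rca(rc_in, n_components=n_components)
        task_responses = [r for r in responses
                          if r.condition in conds and r.harmonic == harmonic]
        projection = project(model, task_responses, phases_from=phases_from)
        tunings = _tunings_for_task(projection, sub, task, harmonic, n_components)
        lags = component_latency_lag(tunings[0], tunings[1]) \
            if n_components >= 2 else []
        result.tasks[task] = TaskResult(
            task=task, harmonic=harmonic, model=model, tunings=tunings,
            lags=lags, reliability_top2=reliability_explained(model, k=min(2, n_components)),
            projection=projection)
    return result
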