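"""Reliable Components Analysis for frequency-domain SSVEP data.

RCA finds spatial filters w that maximize trial-to-trial consistency,

    maximize  w' R_between w / w' R_within w,

where R_between averages cross-covariances over pairs of distinct trials
(only activity reproduced across trials survives) and R_within is the
pooled covariance over all observations. The maximizers are generalized
eigenvectors; eigenvalues order components by the reliability they carry.
Observations are the real and imaginary parts of the per-epoch complex
coefficient at a single harmonic bin, two rows per epoch across the 128
channels, pooled over all stimulus levels of a task.

R_within is rank-reduced by PCA before solving (background EEG makes the
full 128-channel covariance ill-conditioned); forward-model topographies
A = R_within·W translate filters back into scalp patterns comparable to
source topographies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.optimize import linear_sum_assignment

from .session import AnalysisConfig
from .spectral import EpochSpectra, HarmonicResponse

__all__ = [
    "RCInput",
    "RCModel",
    "build_rc_input",
    "cross_trial_covariances",
    "fit_rca",
    "project",
    "reliability_explained",
    "match_topographies",
    "phase_randomize",
    "permutation_null_top_eig",
]


@dataclass(frozen=True)
class RCInput:
    """Real/imaginary observation rows grouped by trial.

    Rows are interleaved as (re, im) per epoch. Trials may contribute
    different numbers of epochs (artifact rejection makes counts unequal);
    the covariance stage pools them with weights proportional to the
    available cross-trial pairs.
    """

    observations: np.ndarray  # (n_obs, n_channels)
    trial_ids: np.ndarray     # (n_obs,)
    harmonic: int
    task: str

    def __post_init__(self):
        obs = np.asarray(self.observations, dtype=float)
        tid = np.asarray(self.trial_ids)
        object.__setattr__(self, "observations", obs)
        object.__setattr__(self, "trial_ids", tid)
        if obs.shape[0] != tid.shape[0]:
            raise ValueError("observations and trial_ids disagree in length")
        if obs.shape[0] % 2:
            raise ValueError("row count must be even (re/im pairs)")
        for t in np.unique(tid):
            if len(np.flatnonzero(tid == t)) % 2:
                raise ValueError("each trial must contribute whole (re, im) pairs")

    @property
    def n_trials(self) -> int:
        return len(np.unique(self.trial_ids))

    def by_trial(self) -> list[np.ndarray]:
        """Per-trial (rows_i, n_channels) arrays in trial-id order."""
        order = np.unique(self.trial_ids)
        return [self.observations[self.trial_ids == t] for t in order]


def build_rc_input(spectra: EpochSpectra, harmonic: int, task_conditions: list[int],
                   config: AnalysisConfig | None = None,
                   task: str = "") -> RCInput:
    """Assemble RCA observations from epoch spectra.

    Pools all epochs of the given conditions (the five sizes of one task);
    trials are truncated to the common minimum epoch count so that each
    contributes the same observation structure.
    """
    config = config or AnalysisConfig()
    freq = harmonic * config.stim_freq_hz
    bin_idx = spectra.bin_index(freq)
    meta = spectra.meta
    sel = meta["condition"].isin(task_conditions)
    coeff = spectra.coeffs[sel.to_numpy(), :, bin_idx]  # (n_epochs, channels)
    trials = meta.loc[sel, "trial"].to_numpy()

    rows, tids = [], []
    for t in np.unique(trials):
        for z in coeff[trials == t]:
            rows.append(z.real)
            rows.append(z.imag)
            tids.extend([t, t])
    return RCInput(observations=np.array(rows), trial_ids=np.array(tids),
                   harmonic=harmonic, task=task)


def cross_trial_covariances(rc_input: RCInput, center: bool = False
                            ) -> tuple[np.ndarray, np.ndarray]:
    """(R_between, R_within) over the observation rows.

    R_between averages, over all ordered pairs of distinct trials and row
    positions, the outer products of position-matched rows (complete
    pairing); R_within is the pooled second-moment matrix of all rows.
    Both are symmetric and R_within is positive semi-definite.

    ``center=True`` removes the grand mean over all observations first.
    The default keeps it: the phase-locked mean response *is* the reliable
    signal of interest, and centering cancels most of the amplitude-tuning
    structure that separates co-tuned sources (their deviations from the
    grand mean are strongly correlated across stimulus levels even when
    their mean responses are not).
    """
    if rc_input.n_trials < 2:
        raise ValueError("need at least 2 trials for cross-trial covariance")
    trials = rc_input.by_trial()
    if center:
        mean = rc_input.observations.mean(axis=0)
        trials = [t - mean for t in trials]
    return _covariances_from_trials(trials)


def _covariances_from_trials(trials: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    n_ch = trials[0].shape[1]
    n_obs = sum(t.shape[0] for t in trials)
    within_raw = np.zeros((n_ch, n_ch))
    # Cross-trial products pair every epoch of trial i with every epoch of
    # trial j, separately for real and imaginary rows (the phase-locked
    # part is constant across a trial's epochs, so all pairings share the
    # same expectation and the extra pairs shrink the sampling noise).
    # sum_{i!=j} Si Sj' = (sum_i Si)(sum_i Si)' - sum_i Si Si'
    S_tr = np.empty((len(trials), 2, n_ch))
    m = np.empty(len(trials))
    for i, t in enumerate(trials):
        within_raw += t.T @ t
        S_tr[i, 0] = t[0::2].sum(axis=0)   # re rows
        S_tr[i, 1] = t[1::2].sum(axis=0)   # im rows
        m[i] = t.shape[0] // 2
    tot = S_tr.sum(axis=0)
    cross = np.einsum("kc,kd->cd", tot, tot) - np.einsum("ikc,ikd->cd", S_tr, S_tr)
    n_pairs = m.sum() ** 2 - (m ** 2).sum()  # sum_{i!=j} m_i m_j
    r_between = cross / (n_pairs * 2)
    r_within = within_raw / n_obs
    r_between = 0.5 * (r_between + r_between.T)
    r_within = 0.5 * (r_within + r_within.T)
    return r_between, r_within


@dataclass(frozen=True)
class RCModel:
    """Fitted spatial filters and their forward topographies.

    W : channels × n_components filter weights
    A : channels × n_components forward models (unit norm, peak positive)
    eigvals : full reliability spectrum on the reduced subspace, descending
    """

    W: np.ndarray
    A: np.ndarray
    eigvals: np.ndarray
    reliability_fraction: np.ndarray
    n_components: int
    rank: int

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]


def fit_rca(rc_input: RCInput, n_components: int = 2, rank: int | None = None,
            var_keep: float = 0.999, max_rank: int = 60,
            center: bool = False, shrink: float = 0.0) -> RCModel:
    """Solve the generalized eigenproblem R_between·w = λ·R_within·w.

    The problem is solved on the top principal components of R_within
    (retaining ``var_keep`` of its variance, capped at ``max_rank``, or an
    explicit ``rank``); eigenvectors are mapped back to channel space.
    Each component is sign/scale-fixed so its forward topography has unit
    norm with a positive peak entry.

    ``shrink`` regularizes the within covariance toward a scaled identity
    ((1-shrink)·R_within + shrink·(tr/d)·I) before solving; with a few
    hundred observations across 128 channels the raw R_within is a noisy
    whitener and its sampling error, not the eigen-spectrum, is what
    perturbs the recovered filters.
    """
    r_between, r_within_raw = cross_trial_covariances(rc_input, center=center)
    d = r_within_raw.shape[0]
    r_within = ((1.0 - shrink) * r_within_raw
                + shrink * (np.trace(r_within_raw) / d) * np.eye(d))
    evals, evecs = linalg.eigh(r_within)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if rank is None:
        pos = np.clip(evals, 0, None)
        cum = np.cumsum(pos) / pos.sum()
        rank = min(int(np.searchsorted(cum, var_keep) + 1), max_rank, len(evals))
    V = evecs[:, :rank]
    rw_red = V.T @ r_within @ V
    if np.linalg.cond(rw_red) > 1e12:
        raise np.linalg.LinAlgError(
            f"reduced within-trial covariance is numerically singular at rank "
            f"{rank}; lower the rank or supply more trials")
    rb_red = V.T @ r_between @ V
    lam, w_red = linalg.eigh(rb_red, rw_red)
    order = np.argsort(lam)[::-1]
    lam, w_red = lam[order], w_red[:, order]

    W = V @ w_red[:, :n_components]
    A = r_within @ W
    for j in range(W.shape[1]):
        scale = np.linalg.norm(A[:, j])
        sign = np.sign(A[np.argmax(np.abs(A[:, j])), j]) or 1.0
        A[:, j] *= sign / scale
        W[:, j] *= sign / scale
    pos = np.clip(lam, 0, None)
    frac = pos / pos.sum() if pos.sum() > 0 else np.full_like(lam, np.nan)
    return RCModel(W=W, A=A, eigvals=lam, reliability_fraction=frac,
                   n_components=n_components, rank=rank)


def reliability_explained(model: RCModel, k: int = 2) -> float:
    """Fraction of total positive reliability carried by the top k components."""
    if k > len(model.eigvals):
        raise ValueError("k exceeds the number of retained eigenvalues")
    pos = np.clip(model.eigvals, 0, None)
    if pos.sum() == 0:
        raise ValueError("no positive reliability eigenvalues; fraction undefined")
    return float(pos[:k].sum() / pos.sum())


def project(model: RCModel, responses: list[HarmonicResponse],
            phases_from: str = "filter"):
    """Pass coherent condition averages through the component filters.

    Returns a long-form DataFrame with one row per (component, condition):
    the complex component coefficient, amplitude (µV ASD), phase (deg,
    cosine-lag convention), the noise floor passed through the same filter,
    and the resulting SNR in dB.

    ``phases_from="inverse"`` reports phases from the pseudoinverse of the
    forward matrix instead of the filters. A generalized-eigenvector
    filter retains a small systematic residual of the other component
    (pencil orthogonality is with respect to the covariances, not the
    topographies), which biases relative-phase estimates; inverting the
    fitted forward model nulls the co-estimated topographies and leaves
    the phase of each source unbiased up to the topography estimation
    error. Amplitude, noise and SNR always come from the filters.
    """
    import pandas as pd

    from .spectral import snr_db

    if phases_from not in ("filter", "inverse"):
        raise ValueError("phases_from must be 'filter' or 'inverse'")
    A_pinv = np.linalg.pinv(model.A) if phases_from == "inverse" else None
    rows = []
    for r in responses:
        if len(r.mean_coeff) != model.n_channels:
            raise ValueError("channel dimension mismatch between model and response")
        comp = model.W.T @ r.mean_coeff                    # (n_components,)
        comp_noise = np.abs(model.W.T @ r.noise_coeffs.T)  # (n_components, 2)
        noise = comp_noise.mean(axis=1)
        phase_src = A_pinv @ r.mean_coeff if A_pinv is not None else comp
        for j in range(model.n_components):
            z = comp[j]
            rows.append({
                "component": j + 1, "condition": r.condition,
                "harmonic": r.harmonic, "n_epochs": r.n_epochs,
                "re": z.real, "im": z.imag, "amplitude": abs(z),
                "phase_deg": float(np.degrees(np.angle(phase_src[j])) % 360.0),
                "noise_amp": noise[j],
                "snr_db": snr_db(abs(z), noise[j]),
            })
    return pd.DataFrame(rows)


def match_topographies(A: np.ndarray, targets: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Match components to reference topographies by maximum |Pearson r|.

    Returns (assignment, abs_r): ``assignment[j]`` is the column of
    ``targets`` matched to component ``j`` (Hungarian algorithm on -|r|).
    """
    A = np.atleast_2d(A)
    targets = np.atleast_2d(targets)
    n_c, n_t = A.shape[1], targets.shape[1]
    corr = np.zeros((n_c, n_t))
    for j in range(n_c):
        for k in range(n_t):
            corr[j, k] = abs(np.corrcoef(A[:, j], targets[:, k])[0, 1])
    rows, cols = linear_sum_assignment(-corr)
    assignment = np.empty(n_c, dtype=int)
    assignment[rows] = cols
    return assignment, corr[rows, cols]


# -- null calibration ----------------------------------------------------

def _top_eig(trials: list[np.ndarray], rank: int) -> float:
    between, within = _covariances_from_trials(trials)
    evals, evecs = linalg.eigh(within)
    V = evecs[:, ::-1][:, :rank]
    lam = linalg.eigh(V.T @ between @ V, V.T @ within @ V, eigvals_only=True)
    return float(lam[-1])


def phase_randomize(rc_input: RCInput, seed: int = 0) -> RCInput:
    """Rotate each epoch's complex coefficient by an iid uniform phase,
    destroying cross-trial phase consistency while keeping magnitudes."""
    rng = np.random.default_rng(seed)
    obs = rc_input.observations.reshape(-1, 2, rc_input.observations.shape[1]).copy()
    theta = rng.uniform(0, 2 * np.pi, size=obs.shape[0])
    c, s = np.cos(theta), np.sin(theta)
    re = c[:, None] * obs[:, 0] - s[:, None] * obs[:, 1]
    im = s[:, None] * obs[:, 0] + c[:, None] * obs[:, 1]
    out = np.stack([re, im], axis=1).reshape(rc_input.observations.shape)
    return RCInput(observations=out, trial_ids=rc_input.trial_ids.copy(),
                   harmonic=rc_input.harmonic, task=rc_input.task)


def permutation_null_top_eig(rc_input: RCInput, n_perm: int = 200,
                             seed: int = 0, rank: int | None = None
                             ) -> tuple[float, np.ndarray]:
    """Observed top reliability eigenvalue vs a trial-shuffled null.

    Each permutation reassigns whole epochs (re/im row pairs) to trials at
    random and refits; returns (observed, null top eigenvalues). The rank
    of the reduction is fixed from the observed fit so that eigenvalues
    are comparable across permutations.
    """
    if rank is None:
        rank = fit_rca(rc_input).rank
    trials = rc_input.by_trial()
    n_ch = trials[0].shape[1]
    counts = [t.shape[0] // 2 for t in trials]
    observed = _top_eig(trials, rank)

    # epoch units keep their re/im pairing; permutations reassign whole
    # epochs to trials while preserving the per-trial epoch counts
    units = np.concatenate(trials).reshape(sum(counts), 2, n_ch)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(len(units))
        shuffled, pos = [], 0
        for c in counts:
            shuffled.append(units[perm[pos:pos + c]].reshape(2 * c, n_ch))
            pos += c
        null[p] = _top_eig(shuffled, rank)
    return observed, null
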