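# Methods

`ssvepkit` implements a frequency-domain analysis chain for steady-state
visual evoked potentials (SSVEPs) recorded with a 128-channel geodesic
net during visual-acuity sweep paradigms, together with a forward
simulator that generates sessions with known ground truth so that every
stage of the chain can be validated by parameter recovery.

## Paradigm and signal model

Two tasks share a 3 Hz two-state alternation. The *Vernier* task
alternates a 2 c/deg square-wave grating with a version in which
alternating 2°-high bands are displaced laterally by 1.4–5.6 arcmin
(0.15–0.75 logMAR in five equal log steps). The *letter* task alternates
arrays of optotype letters with phase-scrambled counterparts of
identical amplitude spectrum, at letter sizes 0.15–1.06 logMAR (equal
logMAR steps; letter height anchored to the standard 5-arcmin optotype
at logMAR 0). A session presents 8 blocks × 2 trials of each of the 10
conditions in random order, 12 s per trial — 16 trials per condition.

The evoked response is modeled as a sum of cortical sources, each with a
fixed scalp topography and per-condition harmonic content at 1F = 3 Hz
(asymmetry-specific, "configural") and 2F = 6 Hz (transient). At level
`l` a source contributes `A_k(l)·cos(2πk·3t − φ_k(l))` per harmonic `k`.
Phase is a cosine **lag** relative to stimulus onset throughout the
package: the stored DFT coefficient of `A·cos(2πft − φ)` is `A·e^{iφ}`,
so a larger phase means a later response and phase differences convert
to latencies by `Δt = Δφ/(360·f)·1000` ms. Because the paradigm is
periodic, a latency is defined only modulo one period (333.3 ms at 3 Hz);
every latency estimate carries its wrap-around candidate family
`Δt + k·333.3` ms, `k ∈ {−1, 0, 1, 2}`, and reports the minimal-magnitude
member by default.

## Preprocessing

Fixed order, enforced and logged on the session history: polyphase
resampling 500 → 420 Hz (integer 140 samples per 3 Hz cycle), zero-phase
linear-phase FIR bandpass 0.3–50 Hz (transition widths 0.2 Hz and 5 Hz,
exact null at DC, applied by centered FFT convolution), optional
replacement of bad channels by the mean of their 6 nearest good sensors
(chord distance on the montage sphere), and common average reference.
Epochs (2 s, i.e. 6 whole stimulus cycles, after a 1 s onset discard;
5 per trial) are rejected when more than 10% of their samples exceed a
voltage threshold on any channel; the default threshold is 60 µV, the
midpoint of the conventional 30–80 µV per-subject range.

## Spectral analysis

Whole-cycle 2 s epochs give a leakage-free rectangular-window DFT with
0.5 Hz resolution and the harmonics exactly bin-centered (3 Hz = bin 6,
6 Hz = bin 12). Scaling is single-sided amplitude spectral density: a
unit-amplitude cosine at a bin center reads 1 µV. Epochs are averaged
*coherently* (complex mean) per condition, so non-phase-locked activity
cancels as 1/√N. The noise floor at each harmonic is the mean magnitude
of the coherently averaged coefficients at the two neighboring bins
(2.5/3.5 Hz for 1F; 5.5/6.5 Hz for 2F), which shrinks at the same 1/√N
rate as the residual noise at the signal bin, making
`SNR = 10·log10(signal²/noise²)` a calibrated statistic. This also fixes
the coherent-averaging gain law, SNR(N) − SNR(1) ≈ 10·log10(N) dB,
which the acceptance suite verifies.

## Reliable Components Analysis

RCA finds spatial filters `w` maximizing trial-to-trial reliability,
`w'R_between w / w'R_within w`, via a generalized eigenproblem.
Observations are the real and imaginary parts of each surviving epoch's
complex coefficient at one harmonic bin (two rows per epoch × 128
channels), pooled over the five levels of a task and — in the
study-level pipeline — over subjects. Numerical and estimator choices:

- **Complete cross-trial, cross-epoch pairing.** `R_between` averages
  outer products of real (and, separately, imaginary) rows over *all*
  pairs of distinct trials and all epoch combinations. The phase-locked
  signal is constant across a trial's epochs, so all pairings share the
  same expectation; the extra pairs reduce the sampling noise of
  `R_between` by roughly √(epochs/trial), and unequal epoch counts after
  artifact rejection are handled by weighting each trial pair by its
  available epoch pairs.
- **No mean-centering by default.** The phase-locked mean response *is*
  the reliable quantity of interest. Removing the grand mean leaves the
  deviations of the two sources' tuning curves, which are strongly
  correlated across stimulus levels (both grow with size), collapsing
  the reliable covariance toward rank one and destroying separability;
  centering remains available as an option.
- **Rank reduction.** The eigenproblem is solved on the principal
  subspace of `R_within` retaining 99.9% of its variance, capped at 60
  dimensions (configurable), guarding against the rank deficiency the
  common average reference introduces.
- **Sign/scale convention.** Each filter is scaled so its forward
  topography `A = R_within·W` has unit norm with a positive peak entry,
  resolving the inherent sign ambiguity of eigenvectors (the scalp
  counterpart of the 180° source-orientation ambiguity).
- **Phase estimation.** Amplitudes, phases, noise floors and SNR are
  filter projections (`W'x`) by default. An alternative mode reports
  phases from the pseudoinverse of the fitted forward matrix (`A⁺x`);
  it removes the filters' structural phase coupling (next paragraph) but
  amplifies topography-estimation error, and in validation the filter
  phases were the more accurate estimator overall. Both modes are
  exposed on `project` and the pipeline entry points.

A structural property of this whole estimator family deserves note:
because the fitted components are uncorrelated by construction
(B-orthogonal), the reliability-weighted cosine of their projected phase
difference is zero — two truly *correlated* sources are therefore
recovered with their phase split pulled toward quadrature. For sources
90 ms apart at 3 Hz (a 97.2° split, cosine −0.125) this compresses the
recovered lag by about 7 ms. The effect is a property of
reliability-maximizing decompositions, not of this implementation, and
it is visible in the validation numbers below.

Reliability eigenvalues order the components; the fraction of total
positive reliability carried by the top two components is reported, and
a permutation null (epochs reassigned to trials at random, 200 draws)
calibrates the top eigenvalue against chance.

## Synthetic sessions and what recovery shows

The simulator inverts the measurement model: two sources per task with
smooth unit-norm scalp topographies (Gaussian bumps on the montage
sphere around the electrodes where the components of interest peak:
letter sources at sensors 65/66 and 75/83; Vernier at 75 and 90/91),
per-level amplitude and phase tuning, ±10% per-trial amplitude jitter,
spatially correlated 1/f background noise, and frontal blink transients.
Default tunings encode the qualitative physiology the analysis is meant
to resolve: the letter lateral source saturates at large sizes while the
medial source peaks at 0.6 logMAR and declines; the medial source lags
by 100 ms at the smallest size shrinking to 40 ms; the Vernier medial
and lateral sources grow linearly in log offset with a constant 90 ms
lag. Background defaults: 1/f exponent 1.0, 3 µV RMS per channel, a
rank-16 correlated component carrying 10% of the variance, 0.04 blinks/s
of 200 µV and 0.5 s (tuned so threshold rejection removes several
percent of epochs, exercising that stage).

The headline validation is end-to-end parameter recovery under the study
design: 14 synthetic subjects × 16 trials/condition, RCA pooled across
subjects (the analysis is defined on observations pooled across trials
*and participants*). Under these conditions the forward topographies
match ground truth at |r| ≥ 0.95 after Hungarian matching, the constant
90 ms Vernier lag is recovered within ±10 ms at every level (the
quadrature pull described above accounts for most of the remaining
error), and the letter lag is recovered as strictly decreasing.

Two deliberate departures from realism are documented rather than
hidden. First, the background noise level is set well below typical raw
EEG: at realistic noise (component-level SNR near 10 dB) the two-source
decomposition is not identifiable from a 6-subject × 80-trial synthetic
study — the eigenvalue gap collapses into the sampling floor — whereas
the empirical study this design emulates had 18 subjects and real
inter-subject variability. The pipeline SNR obtained under the default
noise (roughly 25–35 dB for RC1) is reported as a measured quantity,
not matched to any empirical figure. Second, topographies are
phenomenological scalp patterns, not biophysical projections; recovery
therefore validates the estimator, not a head model. Passing tests show
the chain is correct and calibrated, not that real data of any
particular quality would yield these numbers.

## Statistics

Signal presence is tested per component by a paired two-sided t-test of
per-subject signal vs noise-floor amplitudes averaged over the five
levels — a conservative test against the EEG noise floor rather than
against zero. Tuning-shape comparisons between RC1 and RC2 use a
two-way repeated-measures ANOVA (component × logMAR, both within
subject), delegated to standard routines; its type-I calibration for the
interaction term is verified by simulation (500 null datasets, rejection
rate ≈ 0.05 ± 0.03 at α = 0.05).

## Problem sizes

Simulated studies use 14 subjects × 80 trials (one task) at 500 Hz native
rate, preprocessed to 420 Hz; the permutation null uses 200 draws on one
subject's input; the coherent-gain check uses 50 epochs × 50 seeds; the
ANOVA calibration uses 500 simulated datasets of 18 subjects. These
sizes were chosen so the full validation runs comfortably on a single
CPU while leaving the statistical checks well-powered.

## Known limitations

- Latency is recovered only modulo the 333.3 ms stimulus period; the
  package enumerates candidates but does not disambiguate them.
- With more than two comparably reliable sources, or sources with
  near-identical tuning *and* overlapping topographies, the generalized
  eigendecomposition returns stable mixtures rather than the generating
  sources; this is a property of the method, not of the implementation.
- EDF support is read-only and expects an events sidecar; the native
  format is the documented HDF5 layout.
- The 2F pathway is simulated and analyzable (the spectral and RCA
  stages take the harmonic as a parameter), but default ground-truth
  validation targets the 1F components.
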