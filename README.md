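# ssvepkit

Frequency-domain analysis of steady-state visual evoked potentials
(SSVEPs) for visual-acuity sweep paradigms, built for the question of
whether letter acuity and Vernier acuity are served by the same cortical
sources. The package implements the full chain — stimulus and schedule
arithmetic, 128-channel session handling, preprocessing, bin-centered
harmonic decomposition with coherent averaging, Reliable Components
Analysis (RCA), neighbor-bin SNR statistics, and phase-to-latency
dynamics — together with a forward simulator that generates synthetic
sessions with known ground truth, so the whole pipeline is validated by
parameter recovery.

It is intended for researchers analyzing (or prototyping analyses of)
periodic visual stimulation EEG: 3 Hz alternations between intact and
scrambled letter arrays, or between aligned and Vernier-offset gratings,
with responses read out at the stimulus harmonics.

## The analysis in brief

A stimulus alternating at f = 3 Hz drives responses at exact harmonics
kf. Whole-cycle 2 s epochs give a leakage-free DFT with 0.5 Hz
resolution in which 1F = 3 Hz and 2F = 6 Hz are exact bin centers.
Complex coefficients are averaged **coherently** (phase-preserving), so
background EEG cancels as 1/√N while the evoked response survives; the
noise floor is estimated the same way from the two neighboring bins
(2.5/3.5 Hz for 1F) and SNR is reported as `10·log10(signal²/noise²)` dB.

RCA reduces the 128-channel montage to a few components by maximizing
trial-to-trial reliability: filters `w` solve the generalized
eigenproblem `R_between·w = λ·R_within·w`, where `R_between` pools
cross-covariances over all pairs of distinct trials (only activity
reproduced across trials survives) and `R_within` is the pooled
observation covariance. Each component has a spatial filter, a forward
scalp topography, an amplitude/phase tuning across the five stimulus
sizes, and an SNR against the projected noise floor. Phase is a cosine
lag relative to stimulus onset; a phase difference Δφ between two
components maps to a latency Δφ/(360·f)·1000 ms, defined only modulo
the 333.3 ms stimulus period (wrap-around candidates are always
reported).

## Worked example

Simulate one letter-task session (5 letter sizes × 16 trials at the
default two-source ground truth), run the full analysis, and look at the
component tunings:

```python
import numpy as np
import ssvepkit as sk

montage = sk.load_montage()                      # 128-sensor geodesic net
table = sk.standard_condition_table()            # 10 conditions, both tasks
conds = table[table.task == "letter"]["condition"].tolist()
schedule = sk.build_schedule(n_blocks=8, per_block_per_cond=2,
                             conditions=conds, trial_s=12.0, seed=7)
gt = sk.default_ground_truth("letter", montage)
session = sk.simulate_session(schedule, gt, seed=7, montage=montage)

result = sk.analyze_session(session)             # preprocess → DFT → RCA
tr = result.tasks["letter"]
print(np.round(tr.tunings[0].amplitude, 2))      # RC1 µV per logMAR level
print(np.round(tr.tunings[0].snr_db, 1))         # RC1 SNR (dB)
print(np.round(tr.lag_ms, 1))                    # RC2 lag behind RC1 (ms)
```

Typical output (seed 7):

```
[0.34 0.65 1.05 1.19 1.23]
[16.4 31.8 31.7 32.5 32.8]
[109.4  89.3  82.9  63.2  71.3]
```

The RC1 amplitude rises with letter size and saturates at the two
largest sizes, its SNR sits far above the noise floor, and the second
component lags the first by ~110 ms near threshold, shrinking as the
letters grow — the generative lag pattern (100 → 40 ms) read back
through the full pipeline, here from a single noisy simulated subject
(hence the bumpy tail). Group-level numbers use `analyze_study`, which
pools RCA observations across subjects before fitting, as the analysis
is defined; at the study scale the recovered lag decreases strictly.

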