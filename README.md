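# microstates

Resting-state EEG **microstate analysis** with a built-in **test–retest
reliability layer**, plus a synthetic-EEG generator with known ground truth
for end-to-end validation.

Multichannel resting-state EEG spends most of its time in a handful of
quasi-stable scalp potential topographies ("microstates") that dominate for
roughly 80–120 ms before abruptly switching. Features of the microstate
sequence — how long each class lasts, how often it appears, what fraction of
time it covers — are candidate neurophysiological biomarkers, which makes
their *measurement reliability* across repeated sessions the central
question this package addresses: before a change in a patient's microstate
duration can mean anything, you need to know how large a change could arise
from measurement error alone.

## What it computes

**Microstate pipeline**

- Signal conditioning: 2-s epochs, 55–65 Hz notch, 1–50 Hz band-pass
  (2nd-order zero-phase Butterworth), deterministic amplitude-based epoch
  rejection, average reference, 1–30 Hz analysis band, 200 Hz.
- Global field power `GFP(t) = sqrt(1/n · Σᵢ (vᵢ(t) − v̄(t))²)` and the
  "original maps" at its strict local maxima.
- Polarity-invariant clustering of original maps into K = 4 template maps by
  **TAAHC** (atomize-and-agglomerate hierarchical clustering) or **modified
  k-means** (best of 300 random restarts by GEV), under three derivation
  strategies: one *global* map set, maps *by session*, or maps
  *by recording*; template quality as global explained variance
  `GEV = Σᵤ (GFPᵤ·Cᵤ)² / Σᵤ GFPᵤ²`.
- Back-fitting by highest absolute spatial correlation (a map and its
  negation are the same microstate), midpoint-rule segmentation, and the
  three features per class: mean lifespan (ms), frequency (1/s), coverage.

**Reliability layer**

- Cronbach's α `= K/(K−1) · (1 − Σᵢσ²ᵢ/σ²_Y)` (≡ ICC(3,k)), the standard
  error of measurement `SEM = √MS_error`, and the smallest detectable change
  `SDC₉₅ = 1.96·√2·SEM`, computed over sessions (test–retest), over
  clustering algorithms, or over electrode montages (30/19/8 channels) as
  the repeated measurement.
- TANOVA: a paired randomization test on mean topographies with the global
  map dissimilarity `GMD = √(2(1−C))` as test statistic.
- Feature–feature correlations and OLS of overall duration/frequency on
  relative band powers (δ, θ, α, β).

**Synthetic ground truth** — `microstates.synthetic` simulates a full
multi-session study: four canonical dipolar template maps, truncated-Gamma
dwell times with per-subject mean-duration factors shared across sessions,
a 10 Hz amplitude-modulated carrier with polarity inversions, and spatially
smooth band-limited noise at a configurable SNR. Every downstream stage is
validated against this known truth.

## Worked example

```python
import pandas as pd
from microstates import (SynthConfig, generate_study, standard_chain,
                         find_gfp_peaks, derive_maps,
                         features_for_recording, reliability_report)

cfg = SynthConfig(n_subjects=5, n_sessions=3, n_channels=30,
                  record_length_s=60.0, seed=42)
study = generate_study(cfg)
peaks = [find_gfp_peaks(standard_chain(rec)) for rec in study.recordings]
maps = derive_maps(peaks, strategy="global", algorithm="taahc",
                   seed=42)["global"]
feats = pd.concat([features_for_recording(ps, maps, montage=30)
                   for ps in peaks], ignore_index=True)
report = reliability_report(feats)
print(report[["class", "feature", "mean", "sd", "alpha",
              "sem", "sem_pct", "sdc95"]].round(3).to_string(index=False))
```

```
class          feature   mean     sd  alpha   sem  sem_pct  sdc95
    A mean_lifespan_ms 98.504  7.323  0.909 3.761    3.818 10.425
    A     frequency_hz  2.708  0.247  0.890 0.137    5.068  0.380
    A         coverage  0.265  0.016 -0.122 0.017    6.300  0.046
  All mean_lifespan_ms 96.729  8.216  0.964 2.820    2.915  7.816
  All     frequency_hz 10.409  0.893  0.969 0.285    2.739  0.790
    ...
```

Reading the `All mean_lifespan_ms` row: across 5 simulated subjects the
overall mean microstate lifespan is ≈ 97 ms (the generator's dwell mean is
100 ms), its test–retest reliability over the 3 sessions is α = 0.96, the
absolute measurement error is SEM ≈ 2.8 ms (≈ 3% of the mean), and a change
larger than SDC₉₅ ≈ 7.8 ms in a repeated measurement of one individual would
exceed what measurement error can explain with 95% confidence. Coverage
shows low α here by design: the generator gives every subject the same
expected coverage (≈ 0.25 per class), so there is almost no between-subject
variance for a *relative* reliability coefficient to detect, while its
absolute error stays small.

The same grid is available from the shell:

```bash
microstates simulate --subjects 10 --sessions 3 --channels 30 sim/
microstates run-all --ci-profile out/
```

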