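# commondrive

Analysis of the **central common drive** to a motoneuron pool from paired
surface-EMG recordings, and of **functional reciprocal inhibition** from
stimulus-locked H-reflex sweeps — with a synthetic-data generator that
emulates the statistical structure both analyses assume.

The package is aimed at motor-control and clinical neurophysiology work
where two EMG channels over the same muscle (e.g. proximal and distal
tibialis anterior during static dorsiflexion) are used to quantify shared
oscillatory synaptic input, and where soleus H-reflex suppression at the
onset of dorsiflexion indexes the ability to inhibit antagonist motoneurons
at movement initiation — the contrast of interest between adults with
cerebral palsy (CP) and controls (CON).

## What it computes

**Individual records.** After full-wave rectification and unit-variance
normalisation, each record pair is analysed with the disjoint-segment
estimator (L untapered segments of T = fs/Δf samples, Δf = 1 Hz):
autospectra f_xx, f_yy, cross-spectrum f_xy, coherence

&nbsp;&nbsp;&nbsp;&nbsp;R²_xy(λ) = |f_xy(λ)|² / (f_xx(λ) f_yy(λ)) ∈ [0, 1]

with the exact upper 95 % confidence limit 1 − 0.05^(1/(L−1)), phase
Φ_xy(λ), and the cumulant density q_xy(u) (±250 ms) with flat independence
limits.  A cross-talk screen flags record pairs showing broadband coherence
together with a significant zero-lag cumulant peak.

**Groups.** Segment-weighted pooled coherence per group, pooled cumulant
density, the extended χ² difference-of-coherence test per frequency
(z_g = arctanh |ĉ_g|, χ² = Σ w_g (z_g − z̄_w)², df = groups − 1), and
Student's t comparisons of log10 alpha (5–15 Hz) and beta (15–35 Hz)
coherence areas.

**Reflexes and force.** M-wave and H-reflex peak-to-peak amplitudes in % of
M_max, percent suppression 100·(rest − onset)/rest, mixed group × state
repeated-measures ANOVA with paired post-hocs, M_max plateau detection,
MVC peak torque with countermovement rejection, RFD₂₀₀, and the
soleus/TA cocontraction index.

## Worked example

```python
from commondrive import (DriveSimConfig, IntramuscularCoherence,
                         simulate_common_drive_emg)

record = simulate_common_drive_emg(DriveSimConfig(duration_s=120.0, kappa=0.5, seed=7))
print(IntramuscularCoherence(record).fit().summary())
```

```
Intramuscular coherence
===============================================
subject: sim   group: CON
segments L = 120, segment length T = 2000 samples (1 Hz resolution)
coherence 95% confidence limit: 0.0249
cumulant peak: +6.5 ms (95% limits +/-0.00813)
cross-talk flagged: False (broadband fraction 0.52)
alpha band 5-15 Hz: area = 1.928, log10 = 0.285
beta band 15-35 Hz: area = 1.490, log10 = 0.173
```

A 120 s record at 2 kHz gives L = 120 one-second segments, hence the 0.0249
coherence limit; with coupling κ = 0.5 the alpha- and beta-band coherence
areas sit well above what independent channels would produce (≈0.5 per
10-bin band), and the cumulant peak lies at +6.5 ms — the conduction-delay
difference between the two simulated recording sites — so the pair is not
flagged as cross-talk.

```python
from commondrive import HReflexSimConfig, ReciprocalInhibition, simulate_hreflex_dataset

trials = [(f"CON_{s}", "CON", ss) for s, _, ss in
          simulate_hreflex_dataset(HReflexSimConfig(n_subjects=14, suppression_fraction=0.37, seed=1))]
trials += [(f"CP_{s}", "CP", ss) for s, _, ss in
           simulate_hreflex_dataset(HReflexSimConfig(n_subjects=16, suppression_fraction=0.0, seed=2))]
print(ReciprocalInhibition(trials).fit().summary())
```

```
Functional reciprocal inhibition
===============================================
CON: H-reflex 35.6 %Mmax at rest -> 21.7 %Mmax at onset (39.0% suppression)
CP: H-reflex 42.5 %Mmax at rest -> 41.8 %Mmax at onset (1.7% suppression)
group x state interaction: F(1,28) = 73.42, p = 2.59e-09
  post-hoc rest vs onset in CON: p = 5.93e-07
  post-hoc rest vs onset in CP: p = 0.161
M-wave control (%Mmax): CON/onset 10.0, CON/rest 10.2, CP/onset 9.9, CP/rest 10.2
```

The control-like group suppresses its H-reflex at dorsiflexion onset while
the CP-like group does not, producing a large group × state interaction;
the M-wave stays at ~10 % of M_max in every cell, confirming constant
afferent input across states.

A thin CLI wraps the same stages:

```sh
commondrive simulate-emg --kappa 0.5 --seed 7 --out rec.csv
commondrive coherence rec.csv --out coh.json
commondrive simulate-hreflex --suppression 0.37 --seed 1 --out ds/
commondrive hreflex ds/ --out suppression.json
```

## Layout

- `src/commondrive/io.py` — data model (EMG records, sweep sets, torque
  trials, analysis config) and CSV/JSON round trips
- `src/commondrive/preprocess.py` — band-pass, rectify, normalise, envelopes
- `src/commondrive/spectral.py` — disjoint-segment spectra, coherence,
  phase, cumulant density, cross-talk screen
- `src/commondrive/pooled.py` — pooled group estimates and the χ²
  difference-of-coherence test
- `src/commondrive/bands.py` — band areas, log transform, t-tests, Pearson
- `src/commondrive/reflex.py` — M/H amplitudes, suppression, mixed ANOVA,
  torque metrics
- `src/commondrive/simulate.py` — the generators
- `src/commondrive/models.py` — `IntramuscularCoherence`,
  `GroupCoherenceComparison`, `ReciprocalInhibition` model classes with
  `fit()`/results/`summary()`
- `docs/methods.md` — estimator definitions, generator assumptions, and the
  reasoning behind every default
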