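# Methods

This note documents the estimators, the statistical model behind each
pipeline stage, the synthetic-data generator, and the numerical choices the
implementation makes where the underlying protocol leaves them open.

## Problem setting

Two analyses of ankle-muscle electrophysiology are covered:

1. **Central common drive.** During a static dorsiflexion contraction, the
   motoneuron pool of tibialis anterior (TA) receives rhythmic synaptic input
   that is partially shared across the pool.  Surface EMG recorded at two
   sites over TA (`TA_prox`, `TA_dist`), far enough apart that the two
   electrodes see distinct motor-unit territories, will then be coherent at
   the frequencies of the shared drive — in particular the beta band
   (15–35 Hz), whose EMG–EMG coherence depends on intact corticospinal
   transmission, and the alpha band (5–15 Hz).
2. **Functional reciprocal inhibition.** At the onset of a fast dorsiflexion,
   descending commands to the dorsiflexors normally co-activate spinal
   inhibitory interneurons projecting to the antagonist (soleus) pool.  This
   is quantified as the suppression of the soleus H-reflex, elicited at the
   onset of contraction, relative to rest — with the M-wave in the same
   sweeps held near 10 % of M_max as a control that afferent input was
   constant.

## Spectral estimation

The two EMG channels are conditioned in a fixed order — optional band-pass,
full-wave rectification, normalisation to exactly zero mean and unit
variance (population 1/N convention) — and treated as realisations of
stationary zero-mean series *x*, *y*.

The estimator splits each record into *L* disjoint, non-overlapping,
untapered segments of *T* = fs/Δf samples (Δf = 1 Hz by default, so
T = 2000 at fs = 2 kHz; the trailing partial segment is discarded; no
zero-padding, which keeps bin centres at integer frequencies).  Each segment
is additionally demeaned — this touches only the DC bin, which is treated as
empty downstream.  Averaged periodograms give the autospectra f_xx, f_yy and
cross-spectrum f_xy, normalised as ⟨|X|²⟩/T² so that Σ_k f_xx equals the
segment-mean signal power (Parseval).  Derived quantities:

* **Coherence** R²(λ) = |f_xy|²/(f_xx f_yy) ∈ [0, 1] (bounded by
  Cauchy–Schwarz over segments), with the exact upper 95 % confidence limit
  under independence, 1 − α^{1/(L−1)}, α = 0.05.  For this estimator class
  the null distribution of R² is Beta(1, L−1), so the limit is exact, not
  asymptotic; the test suite verifies ≈5 % exceedance by Monte Carlo.
* **Phase** Φ(λ) = arg f_xy; a pure delay *d* of the second channel gives a
  line of slope −2πd.
* **Cumulant density** q(u) = T·IDFT[f_xy](u) = (1/T) Σ_n x_n y_{n+u},
  restricted to |u| ≤ 250 ms, with flat confidence limits
  ±1.96·√(Σ_k f_xx f_yy / L).  That lag-constant variance is the
  independence null; the constant was verified against a Monte-Carlo null
  (per-lag coverage ≈95 %) before being frozen into the tests.  A positive
  lag means the second channel follows the first; exact peak ties resolve to
  the smallest |lag|.

Band statistics and QC are read over 1–60 Hz.

### Cross-talk screen

Electrode cross-talk — one electrode picking up the other muscle territory's
signal — mimics common drive.  Its signature differs from genuine drive in
two ways: coherence appears across a broad frequency range rather than in
restricted bands, and synchronisation is instantaneous, putting the cumulant
peak at zero lag, whereas genuine common drive arrives with different
conduction delays at the two recording sites and synchronises at a distinct
non-zero lag.  A record pair is flagged when **both** hold: more than a
threshold fraction of 1–60 Hz bins exceed the coherence limit, **and** the
dominant cumulant peak is significant and within ±3 ms of zero.

The broadband threshold defaults to 0.10 — twice the 5 % null exceedance
rate.  It is deliberately permissive: rectification roughly squares the
underlying linear mixing coherence (an amplitude mixing fraction of 0.3
yields rectified-EMG coherence of only ~0.01 per bin), so the decisive
discriminator is the zero-lag condition, which genuine lagged drive never
satisfies under the default conduction-delay geometry.  A genuine common
drive arriving with *equal* delays at both electrodes would be
indistinguishable from cross-talk by this rule — the same ambiguity that
motivates wide electrode separation in practice.

## Pooled estimates and the between-group test

Per-record normalised coherencies c_i = f_xy,i/√(f_xx,i f_yy,i) are pooled
with segment-count weights: c_pool = Σ L_i c_i / Σ L_i, pooled R² =
|c_pool|², with the confidence limit computed at L = Σ L_i.  Weighting
normalised coherencies (rather than summing raw spectra) makes records with
different power scales commensurate, consistent with unit-variance
preprocessing; spectra-sum pooling is available via `method="spectra"` for
sensitivity analysis.  Complex averaging means records with opposing
cross-spectral phase cancel — pooled coherence is a statement about
*consistent* phase relations across a group.

The pooled cumulant density is the cumulant of the segment-weighted pooled
cross-spectrum (records being commensurate after unit-variance
normalisation), so pooling a single record reproduces its individual
cumulant exactly; its confidence limits use the group's total segment count.

**Difference-of-coherence test.**  For each group g the pooled coherency
modulus is variance-stabilised, z_g = arctanh |c_pool,g|, with weight
w_g = 2 Σ L_i (the asymptotic inverse variance of z_g).  The statistic

χ²(λ) = Σ_g w_g (z_g − z̄_w)²,  z̄_w the weighted mean,  df = groups − 1

is referred per frequency to the upper 95 % χ² critical value, with no
multiplicity correction across frequencies (each bin is reported against its
own 5 % level).  The binding contract is behavioural rather than
derivational: under the null of equal (non-zero) coupling the per-bin
rejection rate in the driven band is 5 % within Monte-Carlo error (verified
at 100 replicate experiments, 15 records per group, 30 s records).  Where
true coherence is ≈0 the arctanh statistic is conservative (the modulus of a
near-zero complex mean is not Gaussian), so rejections concentrate where
coherence actually lives — acceptable for a test read out within the
physiologically driven bands.

## Band areas and group statistics

Band coherence is summarised as the **area**: the sum of per-bin coherence
over the band at 1 Hz resolution.  The alpha (5–15 Hz) and beta (15–35 Hz)
bands share the 15 Hz endpoint; to avoid double counting, alpha is the
half-open [5, 15) (bins 5–14) and beta the closed [15, 35] (bins 15–35).
Areas are log10-transformed to symmetrise their distribution; zero areas
have no log and are excluded from group tests pairwise with an explicit
warning and count (silent imputation would bias group means).  Groups are
compared with Student's two-sample t on log areas, reported as mean ± SE;
associations use Pearson product–moment correlations.

## H-reflex analysis

Sweeps are stimulus-locked (stimulus at t = 0).  Peak-to-peak amplitudes are
taken as max − min within the M-window (default 5–25 ms post-stimulus) and
H-window (default 25–55 ms) — standard soleus latencies; both windows are
configuration, not claims about any particular dataset.  All amplitudes are
normalised to M_max, determined from a recruitment series as the plateau of
the M-response (plateau declared when the relative increase is < 1 % over
the final two intensity steps; if no plateau is reached the maximum is
returned with a warning flag).

Percent suppression is 100·(rest − onset)/rest on mean H amplitudes;
negative values indicate facilitation.  Group × state effects are assessed
with a mixed-design repeated-measures ANOVA (between: group; within: state)
on per-subject mean amplitudes, implemented via `pingouin.mixed_anova` and
cross-checked in the test suite against a hand-written sums-of-squares
decomposition.  Post-hoc rest-vs-onset comparisons are paired t-tests within
each group, reported uncorrected (the choice is documented and switchable by
using the returned per-group p values as inputs to any correction).

## Torque metrics

Contraction onset is the first sample exceeding baseline mean + 2 SD
continuously for 10 ms (500 ms baseline required).  A countermovement is a
pre-onset drop below baseline strictly exceeding a threshold (default 2 % of
the trial's peak torque — a quantitative proxy for a "visible drop");
affected trials are excluded before the maximal-voluntary-contraction trial
is selected as the argmax of per-trial peaks.  RFD200 is the torque increase
over the first 200 ms after onset divided by 0.2 s.  The cocontraction index
is the rectified, smoothed (50 ms moving average — a conventional envelope
window, exposed in config) soleus EMG area in % of soleus M_max divided by
the TA EMG area in % of TA M_max over the first second of contraction,
expressed in percent.

## Synthetic-data generator

The generator produces data with the statistical structure the analyses
assume, not a biophysical simulation.

**Common-drive EMG.**  Each channel sums the spike trains of its own pool of
40 motor units (no shared units between channels, mirroring the electrode-
separation argument: coherence must come from shared *input*, not shared
*sources*).  Unit *i* on channel *c* fires as an inhomogeneous point process
(per-sample thinning at fs) with rate

r_i(t) = r₀ · max(0, 1 + g·[κ·s(t − d_c) + (1 − κ)·ξ_ci(t)])

with r₀ = 10 Hz, modulation depth g = 1, one shared band-limited Gaussian
drive s(t) (unit variance, power split equally over 5–15 and 15–35 Hz,
synthesised in the frequency domain), independent band-limited noises ξ_ci,
and per-channel conduction delays d = (2, 9) ms so genuine drive
synchronises at a clearly non-zero lag (~7 ms between sites, consistent with
widely separated electrodes).  κ ∈ [0, 1] is the common-drive coupling —
the one free parameter without an empirical anchor; it is calibrated only
qualitatively (κ ≈ 0.15 reproduces the weak-coupling pattern, κ ≈ 0.4–0.6
the strong one, and expected beta-band coherence area is non-decreasing in
κ).  Spike trains are convolved with a biphasic motor-unit action-potential
kernel (first derivative of a Gaussian, 10 ms) with per-unit amplitudes in
0.5–1.5 mV, plus additive Gaussian noise (0.05 mV).  The max(0, ·)
rectification keeps rates valid; thinning at fs trades exactness for speed
at desk scale.  Channel 2 optionally receives a cross-talk fraction of
channel 1 added at the signal level.

Defaults follow the recording protocol: fs = 2 kHz, 120 s records.  The
simulator does **not** emulate motor-unit recruitment/derecruitment,
fatigue, volume-conductor filtering, or non-stationarity — so passing tests
demonstrate correctness of the estimators under the assumed stationary
common-drive model, not robustness to real-data violations of it.

**H-reflex sweeps.**  Per subject and state, sweeps superpose fixed biphasic
templates: an M-wave centred at 15 ms and an H-reflex centred at 38 ms,
scaled to drawn peak-to-peak amplitudes.  M amplitudes are drawn around the
10 %-of-M_max target (SD 1.5 points) in both states — the stimulation
control.  Subject resting H means are Normal(40, 12) %M_max (a realistic
between-subject spread around resting soleus H-reflex sizes); the onset mean
is the subject's resting mean times (1 − suppression_fraction); trial-level
noise has SD 5 points.  Drawn amplitudes are floored at zero.  Defaults: 15
subjects, 15 trials per state, suppression 0.37 (control-like); a CP-like
group uses suppression 0.

**Torque trials.**  A logistic rise to the target peak whose maximum slope
equals the requested rise rate, shifted and clipped so the trace is exactly
zero before a well-defined onset (the 0.5 %-of-peak crossing, which inflates
the realised maximal slope by a factor 1/0.995), with an optional Gaussian
countermovement dip ~300 ms before onset and optional additive noise.

**Randomness.**  Every generator draws from `numpy.random.SeedSequence(seed)`
with `spawn()` for sub-streams (drive, per-unit noise, thinning, additive
noise; one child per subject for the H-reflex generator), so one integer
seed fixes every output bit-for-bit.

## Problem sizes used in the checks

The self-calibration checks run at sizes chosen to keep a desk run
comfortable while leaving Monte-Carlo error well inside the asserted
tolerances: confidence-limit coverage uses 50 replicates of 120 s records;
the type-I calibration of the difference-of-coherence test uses 100
replicate experiments of 15 records per group at 30 s; suppression recovery
uses 1000 trials per state; the coupling-monotonicity check uses 30
replicates per κ at 20 s.

## Known limitations

* The pooled-coherence confidence limit assumes homogeneous records within a
  group; strong heterogeneity (e.g. one cross-talk-contaminated record)
  should be caught upstream by the QC screen, which is why pooling is only
  offered after per-record reports are available.
* The difference-of-coherence test is conservative at frequencies with
  near-zero true coherence (see above).
* `find_mmax` assumes a monotone recruitment protocol; it does not model
  H-reflex contamination of the M-window at low intensities.
* The vendor acquisition format of the original recordings is not parsed;
  signals enter as CSV + JSON sidecar only.
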