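# Methods

This note documents the models implemented in `mieeg`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Preprocessing

The chain runs in a fixed order — notch → band-pass → ocular-channel
exclusion → (optional ICA hook) → average reference → 2-s epoching →
amplitude rejection → region averaging — and each step appends its name to
the recording's provenance list.

* **Notch.** The line-noise filter is a 4th-order Butterworth band-stop at
  49–51 Hz applied forward-backward. A 2 Hz stop band removes the 50 Hz
  line while leaving neighbouring EEG (±5 Hz) essentially untouched.
* **Band-pass.** 6th-order Butterworth, 1–45 Hz, applied forward-backward
  (zero-phase). Zero-phase filtering matters because the connectivity
  metric downstream is a phase statistic; the price is a doubled effective
  magnitude order.
* **Average reference** is computed after dropping the ocular channels
  (HEOL, HEOR), i.e. over the 28 scalp electrodes, so eye-movement signal
  is never mixed back into the scalp channels.
* **Epoching** is non-overlapping, 2 s per epoch; a trailing partial
  segment is discarded.
* **Rejection** discards an epoch when any channel sample *exceeds* 75 μV
  in absolute value — strictly greater, so an epoch peaking at exactly
  75 μV is kept. Rejected epochs remain in the container with a mask so
  the rejection decisions stay inspectable.
* **ICA hook.** Component-based artifact removal is exposed as an optional
  callable stage (identity by default, recorded in provenance). The core
  pipeline relies on amplitude rejection, which is deterministic and
  testable; a selection rule for artifact components is deliberately not
  hard-coded.
* **Regions.** The 28 scalp channels map onto 10 regions (prefrontal,
  left/right/central frontal, left/right/central parietal, occipital,
  left/right temporal); FT7 and FT8 each belong to two regions and
  contribute to both. A region signal is the arithmetic mean of its member
  channels per sample.

## Spectral features

The PSD estimator is Welch's method with one 2-s Hamming window per kept
epoch (no overlap within an epoch, averaging across epochs). With 2-s
windows the frequency resolution is 0.5 Hz at both sampling rates used
(500 Hz resting, 250 Hz task). Band powers integrate the PSD over half-open
intervals [lo, hi) with the rectangle rule, so the five bands partition the
1–45 Hz total exactly and relative powers sum to 1 by construction. The
relative-power denominator is the sum over the five defined bands — the
same support as the filter pass-band. The α band is 8–15 Hz throughout the
resting-state scheme (wider than the textbook 8–13 Hz), and dB values are
10·log10 of the quantity as given. TAR and TBR return 0 when θ power is
zero and NaN (flagged undefined, never ±inf) when the denominator is zero.

## Connectivity (wPLI)

For each band and region pair the cross-spectrum is formed from per-epoch
analytic signals: the band is extracted with a zero-phase 4th-order
Butterworth band-pass, the Hilbert transform gives a(t), and
X(t) = a_x(t)·conj(a_y(t)). Five per cent of samples at each epoch edge are
discarded to limit transform end effects. Then

    wPLI = |⟨ℑ(X)⟩| / ⟨|ℑ(X)|⟩

with the expectation pooling epochs × retained samples (a per-epoch variant,
averaged across epochs, is available via `pool="epoch"`). Conventions:

* the 0/0 case is defined as 0 — implemented with a relative tolerance
  (denominator below 1e-9 of the mean cross-spectral magnitude), so that
  zero-lag mixtures of a common source, whose imaginary cross-spectrum is
  pure rounding noise, score exactly 0 rather than an arbitrary ratio of
  round-off terms;
* the diagonal of a connectivity matrix is 0 (self-connectivity is
  meaningless for a phase-lag statistic);
* wPLI is computed between the 10 region-mean signals, matching
  region-level connectivity matrices, not channel-level then averaged.

A complex Morlet path (`band_decompose(..., method="morlet")`, cmor1.5-1.0,
0.5 Hz-spaced centre frequencies) is provided behind the same contract as
the filter path for band extraction.

wPLI's defining robustness — instantaneous linear mixtures of one source
score 0 — is what motivates the metric for scalp EEG, where volume
conduction creates exactly such zero-lag correlations. This is asserted in
tests rather than assumed.

## Brain networks

* **Proportional threshold.** Of the K = N(N−1)/2 undirected edges the
  strongest round(sparsity·K) are retained with their weights (half-up
  rounding: sparsity 0.3 on 10 nodes keeps round(13.5) = 14 edges). Ties
  are broken deterministically by ascending (row, column) index. Sparsity 1
  is the identity.
* **Group aggregation** sums the per-subject thresholded matrices
  element-wise and re-applies the proportional threshold at the same
  sparsity, so group graphs honour the configured density.
* **Paths and efficiency.** Edge distance is 1/weight — the standard
  "stronger = closer" convention for connectivity-weighted graphs —
  shortest paths are computed by Dijkstra, unreachable pairs have d = ∞,
  and E_glob = 1/(N(N−1)) Σ_{i≠j} 1/d_ij with 1/∞ = 0. For unit weights a
  complete graph gives exactly 1; two disconnected unit-weight 5-cliques
  give 40/90 ≈ 0.444.
* Efficiency is computed on thresholded matrices by default (consistent
  with the thresholding step preceding topology analysis);
  `build_network(..., threshold=False)` analyses the raw weighted graph.

## Engagement and time-frequency analysis

The engagement (attention) index uses its own band scheme — α 7–13 Hz,
β 14–30 Hz — kept separate by type from the resting five-band scheme, and
the central midline channels Cz, FCz, CPz (lower-limb motor area),
configurable. The bounded form

    E = 100 · P_β / (P_α + P_β)

is adopted as "the α/β energy ratio" because it lives on a 0–100 scale and
rises with β dominance (focused engagement); the raw P_β/P_α ratio is
exposed as an alternative (`ratio=True`). The index is invariant to overall
amplitude scaling and strictly monotone in each band's amplitude.

Time-frequency maps use a complex Morlet wavelet (cmor1.5-1.0) at 1–45 Hz
in 1 Hz steps. Absolute power (μV²) and power in dB relative to each
frequency's mean over the recording are both carried; the dB normalisation
makes session-internal dynamics visible (a stationary rhythm sits at 0 dB),
while ridge extraction uses absolute power.

## Cohort statistics

Test selection is a pure function of two gates and is recorded on every
result:

* Shapiro-Wilk normality gate (normal iff p > 0.05); applied to the
  *difference scores* for paired designs.
* Levene variance gate (centre = mean) before two-sample t-tests.
* Paired: t-test when differences pass normality, else two-sided Wilcoxon
  signed-rank with the exact null distribution for n ≤ 25. All-zero
  differences return a degenerate p = 1 rather than an error.
* Between-group: Student's t when both groups pass normality and Levene
  passes; Welch's t when normality passes but variances differ (the safer
  default when homogeneity fails); otherwise two-sided Mann-Whitney U,
  exact for small untied samples. Groups of size 2 cannot be
  normality-tested and go straight to the exact rank test.
* Chi-square: Pearson without continuity correction; expected counts are
  reported and flagged when below 5; Fisher's exact test is available via a
  flag for the tiny tables typical of pilot trials.
* Bonferroni: p_adj = min(1, m·p).
* Region maps report −log10(p) of the paired comparison per region with a
  significance flag at the configured α.

Quartiles use the inclusive-median method; SD uses the n−1 denominator.

## Synthetic data generator

The generator emulates a two-arm pre/post study with 20 task sessions per
subject. Design:

* **Rhythms** are narrow-band Gaussian processes synthesised in the
  frequency domain, one independent process per region per band, shared by
  the region's channels. Default sinusoid-equivalent amplitudes:
  δ 8, θ 6, α 10, β 4, γ 2 μV — conventional resting-EEG scale (no
  amplitude scale is standard for patient EEG; these are configurable).
* **Background** is 1/f^a noise (default a = 1, RMS 5 μV) synthesised in
  the frequency domain with random phases, giving an exactly controlled
  log-log PSD slope; 50 Hz line noise (2 μV) is added per channel.
* **Coupling** copies a source region's band process into a target region
  at a fixed phase lag, mixed at strength s with the target's own process
  (amplitude-preserving: s·lagged + √(1−s²)·own). The default resting
  coupling set places moderate (s = 0.25–0.40) links around posterior and
  frontal hubs in all five bands, at lags of π/4–π/3.
* **Artifacts** are 0.3 s, ±150 μV square pulses on three random scalp
  channels, centred in round(rate·n_epochs) distinct epochs — far enough
  above the 75 μV bound to survive filtering, and centred so filter ringing
  stays inside the epoch; the rejection rule therefore fires on exactly the
  planted epochs.
* **Ocular channels** carry low-frequency high-amplitude (40 μV RMS,
  0.3–5 Hz) activity; their content is irrelevant as they are dropped.
* **Treatment effects** (per arm): post-treatment θ amplitude ×√1.3 /
  √1.2 (experimental/control; i.e. θ power ×1.3 / ×1.2), β power ×0.7 /
  ×0.8, δ- and θ-band coupling strengths +0.25 / +0.15, and engagement
  trajectories with baselines 43.15 / 44.36 and slopes 1.84 / 1.60 index
  units per session — the arm-wise session-1 → session-20 trajectory
  reported for this study design. Between-subject variability: log-normal
  amplitude jitter (σ = 0.08) per subject plus session-to-session wobble
  (σ = 0.05), and a subject-level engagement baseline spread of SD 10 with
  per-session noise SD 4.
* **Determinism.** Every stream is derived from (cohort seed, stage label,
  subject, condition/session) via hashed seed sequences, so recordings are
  pure functions of their labels and adding subjects never perturbs
  existing ones. Cohort recordings are generated on demand to keep memory
  flat.
* **Clinical scores** are drawn from normal distributions truncated to the
  instrument ranges (ASIA motor 0–100, sensory 0–224, BBS 0–56, FAC 0–5),
  with group-specific post-treatment gains; a printed demographic fixture
  (5 control / 6 experimental rows) can seed the manifest.

What the generator does **not** emulate: biophysical head geometry and
volume conduction (region channels share their region's process exactly
rather than through a leadfield), realistic ocular topographies, non-square
artifact morphologies, non-stationarity within a session, and
electrode-specific noise. Consequently, passing tests demonstrate that the
estimators recover what was planted under the stated signal model — not
that the pipeline is robust to every pathology of real clinical EEG.

## Problem sizes

Unit tests use 6–120 s single recordings. The parameter-recovery suite uses
cohorts of n = 6 per arm with 32 s resting recordings (16 epochs) per
subject and condition, over 100 seeds for the injected-effect direction
check and 100 independent null-cohort seeds for false-positive calibration
— sizes chosen so the whole suite runs on a laptop in a few minutes while
keeping the paired tests at the study's n. The acceptance script uses 20
two-second epochs per coupled pair, where the wPLI values are analytic.

## Known limitations

* The EDF interface is read-only (via MNE); recordings are written in the
  plain matrix + sidecar text format.
* No debiased wPLI² estimator and no surrogate-based edge significance;
  single-edge inference on 16–60 epochs is noisy, and group/suite level
  statistics are the supported inference route.
* No bad-channel interpolation and no built-in ICA algorithm (hook only).
* The repeated-measures ANOVA variant of the gated decision tree is not
  implemented; all supported comparisons are pre/post or two-group.
* The dB rendering of relative power applies 10·log10 to the dimensionless
  fraction as defined, without further scaling.
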