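# mieeg

EEG analysis for motor-imagery brain-computer-interface (BCI) rehabilitation
studies — built for small two-arm clinical trials (for example in incomplete
spinal cord injury) where 30-channel resting-state EEG is recorded before and
after a training programme and task-state EEG during each training session.

The package provides the full analysis chain as a tested library plus a thin
command-line tool:

* **Preprocessing** — 50 Hz notch, 6th-order Butterworth band-pass 1–45 Hz
  (zero-phase), ocular-channel exclusion, average reference, 2-s epoching,
  rejection of epochs whose absolute amplitude exceeds 75 μV, and averaging
  of the 28 scalp channels into 10 brain regions.
* **Spectral features** — Welch power spectral density, relative power in
  the five bands δ (1–4), θ (4–8), α (8–15), β (15–30), γ (30–45 Hz),
  and the quantitative-EEG ratios TAR = P(θ)/P(α) and TBR = P(θ)/P(β).
* **Functional connectivity** — the weighted phase lag index between region
  signals per band,

  wPLI = |⟨ℑ(X)⟩| / ⟨|ℑ(X)|⟩,

  where ℑ(X) is the imaginary part of the cross-spectrum between the two
  signals: values in [0, 1], insensitive to zero-lag (volume-conduction)
  coupling.
* **Brain-network topology** — proportional thresholding (default sparsity
  0.3, i.e. the 14 strongest of the 45 region-pair edges), within-group
  summation and re-thresholding, and global efficiency
  E_glob = 1/(N(N−1)) Σ_{i≠j} 1/d_ij with edge distance 1/weight.
* **Task-state engagement** — the attention index
  E = 100 · P_β/(P_α + P_β) over the central midline channels, using the
  attention bands α 7–13 Hz and β 14–30 Hz, tracked across 20 training
  sessions; complex-Morlet time-frequency maps of the Cz channel.
* **Cohort statistics** — Shapiro-Wilk and Levene gates feeding paired t /
  exact Wilcoxon signed-rank (within-group), Student/Welch t / exact
  Mann-Whitney U (between-group), chi-square for categorical tables,
  Bonferroni adjustment, and −log10(p) region maps.
* **Synthetic data** — a generator producing 30-channel recordings with
  band-limited rhythms, 1/f background, 50 Hz line noise, planted artifact
  epochs, controllable cross-region phase lags, and injectable treatment
  effects (θ power up, β power down, δ/θ coupling up, engagement rising
  over sessions), so every stage can be validated against known ground
  truth.

## Worked example

```python
import numpy as np
from mieeg import (generate_cohort, generate_coupled_pair, band_decompose,
                   analytic_cross_spectrum, wpli, preprocess_recording,
                   band_power_table, wpli_matrix, build_network, paired_compare)

# 1. wPLI on a pair with a planted quarter-cycle phase lag
ep = generate_coupled_pair(freq=10.0, lag=np.pi / 2, coupling_strength=1.0,
                           noise_sd=0.0, n_epochs=20, fs=500.0)
band = band_decompose(ep, "alpha")
cross = analytic_cross_spectrum(band.epochs[:, 0, :], band.epochs[:, 1, :])
print("wPLI (quarter-cycle lag):", wpli(cross))

# 2. one synthetic experimental-arm subject, pre vs post
cohort = generate_cohort(n_per_group=6, seed=1, resting_duration=60.0)
for cond in ("pre", "post"):
    epochs = preprocess_recording(cohort.resting_recording("expe01", cond))
    tbl = band_power_table(epochs)
    theta = tbl[tbl.band == "theta"].relative_power.mean()
    e_glob = build_network(wpli_matrix(epochs, "theta"), sparsity=0.3).e_glob
    print(f"{cond:>4}: mean theta share {theta:.3f}   theta-band E_glob {e_glob:.3f}")
```

prints

```
wPLI (quarter-cycle lag): 1.0
 pre: mean theta share 0.200   theta-band E_glob 0.116
post: mean theta share 0.271   theta-band E_glob 0.199
```

The planted quarter-cycle lag gives the analytic wPLI of exactly 1 (the
imaginary cross-spectrum keeps a constant sign). The synthetic subject
carries the injected treatment effect: the θ share of total power and the
θ-band global efficiency both rise from pre to post. Running the gated
paired test on all six experimental-arm subjects'
θ shares (`paired_compare`) selects the paired t-test and yields
`statistic 4.478, p = 0.0065` — the injected effect is recovered as a
significant within-group increase.

## Command line

```sh
mieeg synth   --out study --seed 1            # write a synthetic cohort
mieeg resting --out study --seed 1            # resting-state pipeline
mieeg task    --out study --seed 1 --sessions 1,20
```

Artifacts are flat CSV (band power, connectivity matrices, group networks,
efficiency, statistics, engagement, time-frequency maps) plus a provenance
manifest and the echoed config; reruns with the same seed are
byte-identical. Recordings are read from EDF or a plain numeric-matrix
format with a channel-name sidecar.

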