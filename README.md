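# mspilot

EEG microstate analysis for repeated-session training studies — built
for monitoring cognitive control in simulator-based pilot training, and
usable for any protocol that alternates short repeated tasks with longer
varied ones across sessions.

The EEG microstate model treats the scalp potential field as a sequence
of quasi-stable topographies ("microstates", conventionally labelled
A–G), each lasting tens of milliseconds.  `mspilot` implements the full
analysis chain:

* **Preprocessing** — 1–40 Hz zero-phase FIR filtering, three
  bad-channel criteria (flat / unpredictable-by-neighbourhood /
  deviant amplitude), 2 s epoching with per-epoch channel repair,
  ±100 µV and probability-based segment rejection, Perrin
  spherical-spline interpolation, average referencing, 250 Hz
  resampling.
* **Microstate fitting** — topographies at Global Field Power (GFP)
  peaks are clustered by the polarity-invariant modified k-means
  minimising

      F = (1/(N_T(N_S−1))) Σ_t ‖V_t − a_kt Γ_k‖²,  a_kt = Γ_kᵀV_t,

  with 100 restarts scored by the predictive cross-validation criterion
  CV = σ̂²·((N_S−1)/(N_S−1−N_K))²; global explained variance (GEV) is
  reported alongside.
* **Group maps** — exact full-permutation alignment of per-task map sets
  (all K! relabelings + signs per member), then canonical A–G labelling
  by Hungarian matching against template topographies.
* **Backfitting & parameters** — every sample gets the class of the map
  with the highest |spatial correlation| (no smoothing); coverage,
  occurrence (/s) and duration (ms) per class.
* **Temporal dependencies** — finite entropy rate (bits/sample) from
  Grassberger-corrected block entropies, and the Hurst exponent by
  detrended fluctuation analysis averaged over all 35 balanced ±1
  mappings of the 7 classes (0.5 = uncorrelated, >0.5 = persistent).
* **Spectral features** — Welch PSD (2 s Hamming, 50% overlap), theta
  band power (4–7.5 Hz) grouped into five cortical areas.
* **Statistics** — within-subject factorial ANOVA (TASK × STAGE ×
  AREA/CLASS) with Greenhouse–Geisser correction and partial η², plus
  Bonferroni-corrected paired post-hocs.
* **Synthetic data** — a generator that plants known topographies, label
  sequences, GFP envelopes and noise levels (and surrogate ±1 sequences
  of known Hurst exponent), so every stage is validated against a
  recoverable ground truth.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import numpy as np
from mspilot import (generate_template_maps, uniform_sequence_model,
                     sample_label_sequence, rectified_sine_envelope, render_eeg,
                     compute_gfp, find_gfp_peaks, modified_kmeans, backfit,
                     microstate_parameters, mean_hurst)

# plant 7 dissimilar topographies and an 80 ms-dwell microstate sequence
maps = generate_template_maps(n_classes=7, n_channels=64, max_similarity=0.7, seed=1)
model = uniform_sequence_model(7, mean_dwell=20)          # samples at 250 Hz
truth = sample_label_sequence(model, 30 * 250, seed=5, fs=250.0)
env = rectified_sine_envelope(truth.n_samples, fs=250.0)  # 10 Hz, ~10 µV GFP
rec = render_eeg(maps, truth, env, snr_db=20.0, seed=6)

# fit maps on the GFP peaks, backfit, measure
peaks = find_gfp_peaks(compute_gfp(rec))
sol = modified_kmeans(rec.data[:, peaks].T, n_classes=7, n_init=100, seed=3)
print(f"{len(peaks)} GFP peaks, CV = {sol.cv:.3f} uV^2, GEV = {sol.gev:.3f}")

pars = microstate_parameters(backfit(rec, sol.maps))
print(f"coverage sums to {pars.coverage.sum():.3f}; "
      f"mean duration {pars.duration.mean():.1f} ms; "
      f"mean occurrence {pars.occurrence.mean():.2f} /s")

dyn = mean_hurst(truth)
print(f"entropy rate {dyn.entropy_rate:.3f} bits/sample, "
      f"Hurst {dyn.hurst_mean:.3f} over {len(dyn.hurst_per_partition)} partitions")
```

prints

```
599 GFP peaks, CV = 0.638 uV^2, GEV = 0.995
coverage sums to 1.000; mean duration 76.5 ms; mean occurrence 1.86 /s
entropy rate 0.415 bits/sample, Hurst 0.994 over 35 partitions
```

The fitted solution explains 99.5% of the GFP-peak variance at 20 dB
SNR, the recovered mean duration (76.5 ms) sits just under the planted
80 ms (backfit errors split a few runs), and the planted sequence is
strongly persistent (Hurst ≈ 1 at this length) with a low entropy rate —
exactly what an 80 ms-dwell 7-class chain should look like.

## Command line

Each stage is also a subcommand operating on files (CSV matrix + JSON
sidecar; EDF/BDF/FIF are read via MNE):

```sh
mspilot simulate --seed 3 --out sim/            # 44 task recordings + ground truth
mspilot fit --in sim/Training_s01_Trial.csv --k 7 --ninit 100 --seed 1 --out maps.csv
mspilot dynamics --labels sim/Training_s01_Trial_labels.csv --out dyn.json
mspilot run-all --seed 0 --out results/         # the whole chain, one participant
```

`mspilot run-all` writes tidy CSVs (microstate parameters, dynamics,
theta power), ANOVA tables, the resolved configuration, and a manifest
with content hashes — two runs with the same seed produce identical
hashes.

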