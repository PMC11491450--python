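# Methods

`mspilot` implements a complete EEG microstate analysis chain for
repeated-session training protocols, together with a synthetic-data
generator that plants a recoverable ground truth under every stage.  This
note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic validation does and does
not establish about real data.

## Synthetic forward model

A microstate sequence is modelled as a semi-Markov chain over K classes:
runs of a class last a geometric (default) or fixed number of samples
(`mean_dwell`, default 20 samples = 80 ms at 250 Hz, in the range
commonly reported for microstate durations), and transitions follow a
row-stochastic matrix with zero diagonal (uniform off-diagonal by
default).

Each class k owns a unit-norm, zero-mean (average-referenced) scalp
topography.  Topographies are smooth Gaussian random fields: white noise
at the sensors smoothed with an `exp(-d²/2ℓ²)` kernel over great-circle
distance (ℓ = 0.8 rad), demeaned, normalised, and rejection-sampled
until every pairwise absolute spatial correlation is at or below
`max_similarity` (default 0.7, comparable to the similarity of published
microstate classes).  The 64-channel default montage is the standard
BioSemi 10-20 extended layout, so channel names carry real spatial
meaning; any other channel count falls back to a Fibonacci spiral on the
upper hemisphere.

A rendered sample is

    V(t) = g(t) · √N_S · s_r · Γ_{label(t)} + noise(t)

where `g(t)` is the GFP envelope, `s_r` is a random per-run polarity
sign (microstate polarity is not physiologically meaningful, and the
flips force every downstream consumer to honour polarity invariance),
and the `√N_S` factor makes the noiseless GFP equal `g(t)` exactly.  The
envelope is a rectified sinusoid, `g(t) = A·|sin(2πft + φ)|` with
f = 10 Hz and A ≈ 10 µV GFP, so GFP peaks exist at 2f per second — the
samples the map fitter consumes.  The phase defaults to π/2: with φ = 0
the envelope's zeros fall exactly on the 250 Hz sample grid, and a
zero-GFP sample carries no topographic information at all (under any
finite SNR it is pure noise and fragments the label runs); the cosine
phase keeps every rendered sample informative.  Amplitude scale is a
free choice — only ratios matter downstream.

Noise is i.i.d. Gaussian per channel, average-referenced, then scaled so
that total signal power over total noise power matches `snr_db`
(default 20 dB).  The protocol generator reproduces the 22-session
structure — Training (7 sessions), PracticeA (8), PracticeB (7), each
session a 30 s Baseline task followed by a 90 s Trial task — at the
250 Hz analysis rate (synthesis at the acquisition rate of 2048 Hz is
supported via `ProtocolSpec.sampling_rate` but serves no validation
purpose and costs 8× the memory).

Surrogate ±1 sequences with a known Hurst exponent are the sign of exact
fractional Gaussian noise, generated by Davies–Harte circulant
embedding.  Hard clipping preserves the asymptotic scaling exponent of a
Gaussian process but attenuates short-lag correlations by the arcsine
law, so DFA on clipped fGn with H = 0.8 reads ≈ 0.75–0.79 at n = 10⁵ —
a finite-length crossover effect of the clipping, not of the estimator.

**What the generator does not emulate:** broadband volume-conducted
background activity between GFP peaks, 1/f spectra, alpha rhythms,
eye/muscle artifacts, electrode drift, or inter-subject topography
variability.  Passing the recovery tests therefore shows the pipeline is
correct under the microstate model's own assumptions; it does not
certify performance on real recordings, whose GEV and temporal measures
live in a messier regime.

## Preprocessing

The chain is: 1–40 Hz zero-phase Hamming windowed-sinc FIR band-pass
(linear-phase FIR, single forward pass, group delay compensated;
low-side transition bandwidth = low/2 so sub-Hz drift is actually
attenuated) → whole-recording bad-channel screen → pluggable
artifact-rejection hook (no-op by default; an ICA-based stage can be
registered without reordering the chain) → 2 s epoching with local
channel repair and segment rejection → spherical-spline interpolation of
isolated bad global channels → average reference → polyphase
anti-aliased resampling to 250 Hz.

Bad-channel criteria:

* **flat** — peak-to-peak below 10⁻⁶ µV over any sliding 5 s window (the
  amplitude epsilon is ours; "flat" needs one to be computable);
* **amplitude** — channel standard deviation more than 3 across-channel
  standard deviations *above* the mean (one-sided: low amplitude is the
  flat criterion's business).  Any mean+3SD rule over 64 channels has a
  nonzero clean-data flag rate by construction (≈ 0.17 expected flags
  per recording under Gaussian spread); the planted-defect tests
  therefore bound the false-positive channel *rate* (≤ 2%) rather than
  demanding zero;
* **neighbour correlation** — the channel's correlation with its
  spherical-spline reconstruction from the remaining channels is below
  0.8.  Correlation with any *single* nearest neighbour proved
  unreliable under a pure K-map field (channels near field nodes of the
  planted topographies genuinely decorrelate from individual
  neighbours), whereas the reconstruction-based variant — the same idea
  as RANSAC-style consistency checks in robust referencing pipelines —
  separates cleanly (clean channels ≥ 0.97, a dead channel ≈ 0).  Two
  passes are run, with first-pass offenders excluded from everyone
  else's reconstruction pool, so a single gross channel cannot drag its
  neighbourhood below threshold; the amplitude screen runs first for the
  same reason.

Per-epoch local channel checks use the four classic statistics
(variance, median gradient, amplitude range, deviation from the epoch
mean), each z-scored across channels within the epoch; any |z| > 3
triggers within-epoch spherical-spline repair.  Segment rejection then
removes epochs with any |sample| > 100 µV, and epochs whose
single-electrode log-probability across epochs or electrode-group
log-probability within epoch deviates more than 3 SD (probability =
histogram density estimate per channel over the pooled epochs; computed
*after* local repair, following the stage order of the cleaning chain).

Spherical splines follow Perrin's formulation with stiffness m = 4,
regularisation λ = 10⁻⁵ on the diagonal, and a 7-term Legendre
truncation; good channels pass through bit-identical.  Resampling uses
`scipy.signal.resample_poly` with the rational rate approximation, and
the average reference is re-asserted afterwards (polyphase edges can
leave ~10⁻¹² µV reference drift).

## Microstate fitting

GFP is the spatial standard deviation per sample.  Peaks are strict
local maxima at least 10 ms apart (plateau centres counted once).  The
modified k-means on the peak topographies alternates:

* assignment: `argmax_k (Γ_k·V_t)²` — polarity-ignoring winner-take-all;
  ties resolve to the lowest class index for deterministic replay;
* update: Γ_k ← first principal eigenvector of the assigned samples'
  scatter matrix, the minimiser of the residual cost under the unit-norm
  constraint.  Empty clusters are re-seeded from a random sample.

Convergence is a relative cost change below 10⁻⁶ or 300 iterations
(logged warning).  One hundred restarts (each seeded from the master
seed by counter, initial maps drawn uniformly without replacement from
the peak samples) are scored by the predictive cross-validation
criterion

    CV = σ̂² · ((N_S−1)/(N_S−1−N_K))²,
    σ̂² = Σ_t (V_t·V_t − (V_t·Γ_{k(t)})²) / (N_T(N_S−1))

with k(t) read as the *assigned* class at t (the standard reading), and
the restart with the lowest CV wins.  Restarts matter: single random
starts routinely merge the two most similar planted classes while
splitting a well-covered one; best-of-100 recovers all seven planted
maps at |spatial correlation| ≈ 1.00 at 20 dB on 30 s of data.  K is
fixed at 7 by configuration; CV is reported so model-order studies
remain possible.  Global explained variance is the GFP²-weighted mean
squared spatial correlation between each peak topography and its
assigned map.

## Group maps and labelling

Per-task map sets are aligned by an exhaustive full-permutation search:
for each member all K! label permutations (with the optimal per-class
sign) are scored by mean absolute spatial correlation against the
current mean maps; the mean is then recomputed as the sign-aligned,
re-centred, re-normalised average (initialised from the first member),
and the alternation repeats until assignments stabilise.  The objective
is non-decreasing by construction and is asserted each sweep.  7! = 5040
keeps the search exact and fast; K ≤ 8 is enforced.

Aligned global maps are given the conventional A–G labels by a Hungarian
assignment maximising total absolute spatial correlation against
template topographies.  The shipped templates are *synthetic stand-ins*
generated by this package's own generator with a fixed seed (stored as
`data/canonical_templates_synthetic.csv`), not topographies from any
published atlas; for real data users should supply their own templates.

## Backfitting and parameters

Every sample of the cleaned recording (not only GFP peaks) receives the
class of the global map with the highest absolute spatial correlation;
no temporal smoothing of any kind is applied.  Zero-variance samples are
tagged `UNLABELED` and excluded from parameters.  Coverage is the
labelled-sample fraction per class; occurrence is runs per second of
analysis time; duration is mean run length in ms.  Boundary (first and
last) runs are included, which keeps
`coverage_k = occurrence_k × duration_k / 1000` exact when all samples
are labelled.

## Temporal dependencies

**Entropy rate** (short-range): block entropies H(k) of the k-gram
distributions, k = 1..6, with the estimate the least-squares slope of
H(k) against k (exact for any Markov source, where H(k) is affine in k).
Plug-in block entropies are biased once the number of distinct k-grams
approaches the sequence length — unavoidable at k = 6 over a 7-class
alphabet — so the default estimator is Grassberger's digamma-corrected
entropy, which keeps the i.i.d. 7-class slope within 0.003 bits of
log₂7 at n = 2·10⁵ (Miller–Madow leaves a ≈ 0.02-bit deficit there).
The plain plug-in and the conditional-entropy variant
H(k_max+1) − H(k_max) remain available (`bias_correction=False`,
`method="diff"`).

**Hurst exponent** (long-range): the label sequence is mapped to
{−1, +1} under every balanced bipartition — all C(7,3) = 35 splits
assigning 3 classes to +1 for K = 7 (for even K, complement-duplicate
splits are removed) — and DFA is run per mapping: profile = cumulative
sum of the mean-centred sequence, order-1 polynomial detrending over
non-overlapping windows, ~18 log-spaced window sizes from 10 to n/10,
least-squares slope of log F(s) on log s.  The per-partition exponents
are averaged.  Degenerate mappings (constant ±1 sequence) are skipped
with a warning.  Sequences are analysed per task (≈ 7,500 samples for a
Baseline, ≈ 22,500 for a Trial at 250 Hz); the entropy estimator warns
below ~24,000 samples because 4-gram statistics start to thin out.

## Spectral features

Welch periodograms with 2 s Hamming windows at 50% overlap (0.5 Hz
resolution), density-scaled so the integral approximates the variance.
Theta power is the trapezoidal integral of the PSD over the closed band
[4, 7.5] Hz.  Channel powers are averaged (unweighted) into five
cortical areas — frontal (Fp/AF/F), central (FC/C), temporal (FT/T/TP),
parietal (CP/P), occipital (PO/O/Iz) — from an editable mapping file for
the 64-channel 10-20 montage (`data/areas_biosemi64.json`); the mapping
is a partition: every channel belongs to exactly one area.

## Statistics

All designs are fully within-subject: 2 (TASK) × 3 (STAGE) × 5 (AREA)
for theta power, 2 × 3 × 7 (CLASS) per microstate parameter, 2 × 3 for
the temporal measures.  No installed routine provides
Greenhouse-Geisser ε and partial η² for three within factors, so the
decomposition is computed directly through orthonormal contrasts: per
effect, the Kronecker product of Helmert contrasts (factors in the
effect) and unit-norm averaging vectors (factors not in it) projects
each subject's cell means onto the effect subspace; SS, F, and dfs
follow from the projected scores, ε = tr(S)²/(d·tr(S²)) from their
covariance (clipped to [1/d, 1]), and partial η² =
SS_effect/(SS_effect+SS_error).  The implementation agrees with
`pingouin.rm_anova` (F, p, ε, η²) to 10⁻⁶ on two-factor designs and
with `statsmodels` `AnovaRM` (F, p, dfs) on three-factor designs; those
libraries serve as cross-checks in the test suite, never as the
implementation.  Corrected and uncorrected p are both always reported;
for single-df effects they coincide (sphericity holds trivially).

Post-hoc comparisons are two-sided paired t-tests with Bonferroni
correction; the family is the full set of comparisons made in one call
(all level pairs × all strata), with the family size recorded in the
output since family definitions are a reporting choice.  Significance
markers follow the *, **, *** convention at p ≤ 0.050, 0.010, 0.005.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations as
follows, as the package's own validation choices: single-task fits use
30 s recordings (≈ 600 GFP peaks); the cohort recovery check uses 24
simulated participants × 30 s at 20 dB with 100 restarts each; entropy
anchors use 2·10⁵-sample sequences; Hurst anchors use 10⁵-sample
sequences over all 35 partitions; the null-calibration of the ANOVA uses
1,000 replicates of the 2 × 3 design at n = 24.

## Known limitations

* The generator's realism gaps listed above; in particular clean-channel
  detection and backfit accuracy are easier under the pure microstate
  model than on real data.
* EDF/BDF/FIF files are read (via MNE) but only CSV + JSON sidecar is
  written.
* The entropy rate at a given history length is estimator- and
  length-dependent; absolute values should only be compared within one
  configuration.
* DFA on clipped surrogate sequences underestimates H > 0.5 slightly at
  finite length (arcsine-law attenuation); anchors at H = 0.5 are
  unaffected.
* The full-permutation alignment is exact but limited to K ≤ 8.
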