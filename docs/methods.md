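# Methods

This note documents the models, numerical choices and validation logic of
`munet`, in the spirit of the methods documentation of mature scientific
packages. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Analysis chain

### Preprocessing

Epochs span −1000…+1400 ms around stimulus onset at 500 Hz (1200 samples).
The chain runs in a fixed, logged order:

1. **High-pass 0.3 Hz** — 4th-order Butterworth applied forward–backward
   (zero phase) per trial and channel. The filter family is a package
   choice; at 7 Hz the attenuation is <1%.
2. **Amplitude criterion** — a trial × channel pair is bad when its absolute
   amplitude *strictly exceeds* 200 µV; a peak exactly at the threshold is
   kept. The criterion is applied after filtering, since DC offsets would
   otherwise dominate the comparison.
3. **Trial rejection** — a trial is rejected when its bad-channel fraction
   strictly exceeds 0.15 (on 128 channels: 20 bad channels reject, 19 keep).
   Rejection is monotone in the threshold (property-tested).
4. **Spherical-spline interpolation** — surviving trials' bad channels are
   re-estimated from that trial's good channels with the Perrin-style
   spherical spline (order m=4, 50 Legendre terms, ridge 1e-5; standard
   published defaults). Fewer than 4 good channels make the spline system
   unsolvable; such trials are marked unrecoverable. The operator reproduces
   constants exactly and matches MNE's interpolation matrix to numerical
   precision (cross-checked in the tests).
5. **Average reference** — per-sample channel mean subtracted; a state
   machine (`vertex → average → csd`) prevents double referencing.
6. **Inclusion rule** — a subject enters group analysis only if every
   emotion retains ≥5 trials.

### Time–frequency analysis

Complex Morlet wavelets at 1 Hz steps over 3–20 Hz, `n_cycles = 5` fixed
across frequencies (at 6 Hz the half-duration ≈ 0.42 s, consistent with the
400 ms edge trim). Wavelets are **amplitude-normalised**: a unit-amplitude
sinusoid at a wavelet's centre frequency yields modulus 1, so amplitudes
stay in µV — the analysis uses amplitude, not power. Convolution is
performed on reflect-padded signals so that every output sample sees the
full zero-mean kernel; residual edge distortion is handled by trimming
400 ms from both ends. The modulus is taken **per trial before averaging**
(the trial-average of moduli dominates the modulus of the average — a
Jensen inequality asserted in the tests). Baseline correction subtracts the
scalar mean over [−600, −100) ms per channel × frequency, applied to the
trial-averaged amplitude. The mu-suppression score averages the inclusive
6–9 Hz bins {6,7,8,9}, the cluster channels, and the inclusive 400–800 ms
window; negative values index suppression.

Cluster definitions (1-based channel numbers on the 128-channel net):
C3 = {30,31,36,37,41,42,53,54}, C4 = {79,80,86,87,93,103,104,105},
O = {70,71,75,76,83}. The occipital analysis reuses the same band and
window.

### Connectivity

CSD (the negative spherical-spline surface Laplacian, same spline family)
precedes connectivity always; it is reference-free and attenuates volume
conduction. Cross-spectra reuse the Morlet family at the band's integer
bins: per trial, `a_i a_j*` is averaged over the 6–9 Hz bins and the
post-stimulus 0–1000 ms window to one complex value per pair (the band is
averaged per trial *before* the across-trial ratio — the alternative order
is not implemented). Across trials the debiased WPLI-square estimator is
formed; pairs with a vanishing denominator (e.g. identical signals, all
imaginary parts zero) are set to 0 and counted. The estimator is symmetric,
zero-diagonal, ≤1, and may be negative at small samples. One matrix per
subject × condition × emotion.

A deliberate property of the estimator, verified analytically and in the
tests: for i.i.d. trial cross-spectra, E[numerator]/E[denominator] equals
the population ratio μ²/ν² for *every* trial count — the debiasing removes
the sample-size bias that makes phase-locking-value-type estimators drift
upward at small T (a PLV oracle is asserted to be biased on the same data).
Consequently the mean estimate is essentially flat in T; convergence with
trial count manifests as shrinking spread, and as means approaching 1 in
the strong-coupling regime.

### Network backbone

Weights map to lengths by `L_ij = 1/max(W_ij, ε)` with ε = 1e-6; negative
or sub-ε DWPLI values are clipped and counted. The MST is extracted with
Kruskal's algorithm; ties are broken deterministically by
(length, smaller index, larger index). Global efficiency and diameter are
computed on the **binarised** tree's hop-count distances; `BCnorm` is the
maximum weighted-shortest-path betweenness on the **full length matrix**
divided by (n−1)(n−2)/2 (an MST-based variant exists as an option but is
not the default — the two readings are both defensible and the weighted
full-matrix one is the more specific convention). Kruskal is validated
against exhaustive spanning-tree enumeration (Prüfer sequences, n ≤ 8) and
betweenness against simple-path enumeration.

### Statistics

The central design is a 2 (condition, between) × 2 (cluster, within) × 3
(emotion, within) mixed ANOVA; the occipital and network analyses use
2 × 3 designs. Effects use the conventional univariate error strata
(subjects-within-groups for the between effect; factor ×
subjects-within-groups per within stratum). No sphericity correction is
applied by default, matching the integer degrees of freedom convention
(e.g. df = (2,72) for the emotion effect at N = 38); partial η² =
df₁F/(df₁F + df₂). With unequal group sizes the weighted-means solution is
used; it agrees with `pingouin.mixed_anova` in the supported one-within
case (cross-checked in the tests). Post-hoc pairwise t-tests run only when
the omnibus effect is significant (Fisher's LSD logic, protective for
families of ≤3 means), with Holm–Bonferroni adjustment for families of more
than one comparison; contrast families are per-interaction post-hoc sets.
All tests are two-tailed at α = 0.05. FDR (Benjamini–Hochberg) is applied
across the network-metric omnibus families. The a-priori power computation
uses the within–between-interaction convention of common power software:
noncentrality λ = f²·N·m/(1−ρ)·ε, df₁ = (k−1)(m−1)ε, df₂ = (N−k)(m−1)ε,
defaults ρ = 0.5 and ε = 1; the smallest N reaching the target power is
returned (28 for f = 0.25, α = 0.05, power = 0.80, k = 2, m = 3).

## Synthetic generator

The generator emulates the study's signal structure, not its biophysics:

- **Montage** — a deterministic golden-angle spiral on the unit sphere;
  the study-cluster channel numbers are assigned to spatially coherent
  patches around left-central, right-central and occipital anchors, as on a
  physical geodesic net. Additional "region" clusters for coupling sources
  are placed by farthest-point sampling.
- **Background** — per-channel Gaussian noise with amplitude spectrum
  ∝ f^(−a), default a = 1 (fitted slope recovered within 0.2 over
  2–40 Hz), RMS 4 µV.
- **Source mixing** — Gaussian smoothing on the sphere (FWHM ≈ 30° of arc)
  instead of a boundary-element head model: it creates exactly the
  instantaneous volume-conduction structure that CSD and DWPLI must reject,
  with no anatomy required.
- **ERD** — each cluster carries a mu oscillation (7.5 Hz, random phase per
  trial, baseline source amplitude 10 µV) whose envelope drops during a
  200–1000 ms plateau with 100 ms raised-cosine ramps, leaving the baseline
  window clean and avoiding spectral splatter in the 400–800 ms window.
  Ground truth is defined **at the measurement level**: the injected drop is
  divided by (a) the analytic band-averaging gain of the wavelet family at
  the mu frequency and (b) the spatial gain of the smoothing kernel averaged
  over the cluster, so `truth.erd` is in the same µV units the analysis
  reports. Residual ~2–3% under-recovery from wavelet temporal smearing at
  the plateau edges is left uncorrected (well inside the ±0.1 µV recovery
  tolerance).
- **Coupling** — one oscillator per region; per trial, phases propagate
  along a BFS spanning forest of the coupling graph (child = parent − lag +
  jitter, jitter scaled by 1 − weight), so phase-lag consistency grows with
  edge weight. Default lag π/4 for true edges; lag 0 yields pure
  volume-conduction confounds for negative controls. Graphs with cycles are
  realised on a spanning forest only (non-tree edges are skipped with a
  warning) — a known limitation; the study topologies (star, line) are
  trees. Phase-lag chains produce transitive phase relations at short graph
  distances, so a line topology is recovered with occasional shortcuts;
  the star-vs-line *direction* of efficiency and diameter is what the
  validation asserts.
- **Study layout** — two groups (19 dynamic / 19 static by default), 8
  trials per emotion (matching reported artifact-free trial counts),
  subject-level ERD scattered around the population map with SD 0.3 µV
  (matching reported between-subject SDs), square-pulse amplitude artifacts
  (default 300 µV on 10% of trials) to exercise the rejection rules, and
  per-subject seeds spawned deterministically from the master seed. The
  default population ERD map reproduces the reported cell and marginal
  means of the emulated study (e.g. dynamic-happy C4 = −0.38 µV, occipital
  cells −0.97…−1.52 µV); central cells not individually reported are chosen
  consistent with the reported marginals.

### What the generator does *not* emulate

Realistic head-model lead fields, eye/muscle artifact morphology,
heteroscedastic or non-Gaussian noise, inter-channel noise correlation, and
developmental variability in peak mu frequency. Passing validation
therefore shows that the *pipeline* recovers the quantities it claims to
estimate under the study's signal structure — not that the pipeline is
robust to every pathology of real infant EEG.

## Validation experiments and problem sizes

The acceptance script and `tests/test_acceptance.py` run, per seed:
ERD recovery (20 subjects × 50 trials), DWPLI independent-noise null
(100 seeds × 30 trials at the signal level), zero-lag control through the
full CSD pipeline (50 seeds × 30 trials; at very small trial counts the
ratio estimator acquires a small positive skew, so the control is run at a
trial count where the debiasing property holds), coupling curve (weights 0.2/0.5/
0.8, 20 seeds), trial-count curve (10/50/200 trials, 20 seeds, at the
generator's oscillation-to-noise ratio of 1.5 where the estimator's
convergence toward 1 is monotone), topology recovery (20 star/line subject
pairs, 12 regions, 8 trials), and a 1000-rep null calibration of all seven
mixed-ANOVA effects. These sizes keep a full run to a few minutes on one
CPU while leaving comfortable Monte-Carlo margins for each check.

## Numerical details and degenerate inputs

- ms→sample mapping is floor-based at 500 Hz; baseline [−600, −100) is
  half-open, the analysis window [400, 800] closed.
- Zero-denominator DWPLI pairs → 0 (logged); DWPLI needs ≥2 trials.
- `to_lengths` requires ε > 0; clipped entries are counted.
- Spline systems are solved with a hard constraint on the constant term, so
  constants are reproduced exactly (interpolation) or annihilated (CSD).
- The mixed ANOVA refuses unbalanced within-cells, duplicated rows, and
  subjects appearing in both groups, naming the offender.
- All generator outputs are pure functions of (config, seed); study-level
  per-subject seeds come from `numpy.random.SeedSequence.spawn`.
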