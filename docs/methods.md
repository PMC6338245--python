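# Methods

## The selection statistic

Each voxel *i* of a 4D scan carries a time series
V<sub>i</sub> = [v<sub>i,1</sub> … v<sub>i,n</sub>]. The package computes,
per voxel,

- the temporal mean μ<sub>i</sub> = (1/n) Σ<sub>j</sub> v<sub>i,j</sub>,
- the absolute deviations d<sub>i,j</sub> = |v<sub>i,j</sub> − μ<sub>i</sub>|,
- their median M<sub>i</sub> (even n: midpoint of the two central order
  statistics) and their maximum.

A voxel counts as *highly activated* for a subject when its deviation
exceeds α·M<sub>i</sub> at **any** timepoint — i.e. when
max<sub>j</sub> d<sub>i,j</sub> > α·M<sub>i</sub> (strict). The criterion is
existential over time, needs no task timings or haemodynamic model, and is
invariant to affine intensity rescaling (v → a·v + c leaves it unchanged:
μ absorbs c, and both the deviations and M scale by |a|) and to any
permutation of the time axis. α defaults to 3 with a conventional sweep of
1–7 in unit steps; |S| is non-increasing in α by construction.

Two guards handle degenerate series. The comparison is strict, so ties at
exactly α·M<sub>i</sub> are excluded, and constant series
(max = M = 0) can never pass. An eligibility floor ε = 10⁻¹² on
M<sub>i</sub> (configurable) additionally excludes series whose median
deviation is exactly zero — e.g. a series where more than half the values
equal the mean — which would otherwise satisfy `anything > α·0` vacuously.

## Two-phase group analysis

**Phase I** applies the statistic per subject, yielding a per-subject set
of selected voxels. A subject's runs enter either as per-run selections
merged by union (default: activated in *any* run, consistent with the
existential reading of the statistic) or intersection, or pooled into one
long concatenated series (`run_combine="pooled"`).

**Phase II** intersects the per-subject sets within each group
(V<sub>S,G1</sub> = ∩<sub>k</sub> V<sub>s,k</sub>, likewise for G2) and
merges the two group sets: **S = V<sub>S,G1</sub> ∪ V<sub>S,G2</sub>**. A
consensus fraction generalizes the strict intersection — a voxel survives
when selected in ≥ ⌈consensus·m⌉ of the m subjects — because a strict
intersection across many subjects is brittle (one non-responder empties the
set). The default, consensus = 1.0, reproduces the strict rule exactly;
anything else is recorded in the output metadata as a deviation.

Voxel-index sets are stored lexicographically sorted, so all serialized
outputs are byte-reproducible.

## Coordinates and region labels

Voxel indices are 0-based (x, y, z) triples; world coordinates are RAS+
mm through the NIfTI affine, with `world_to_voxel` the rounded inverse.
MNI→Talairach conversion uses the widely published two-branch, translation-
free linear approximation (separate 3×3 matrices for z ≥ 0 and z < 0,
identical y-row at z = 0 so the map is continuous across the branch plane
and fixes the origin). The coefficients sit in one constants table
(`madvox.atlas`) so an alternative published affine can be swapped in.

Region lookup is a pluggable CSV of labelled axis-aligned boxes in
Talairach mm, *half-open* on each axis ([min, max)), with four hierarchy
levels: hemisphere, lobe, gyrus, Brodmann area. Unmatched coordinates are
labelled `unlabelled`; lookup is strict containment (no nearest-region
fallback) to keep labels auditable. The bundled `toy_atlas()` is a
synthetic eight-octant stand-in that exercises the interface; it does not
reproduce any real atlas, and real lookups require a user-supplied table.

## Classification

Features default to the selection statistic itself, `peak_ratio` =
max deviation / median deviation per voxel of S, averaged over a subject's
runs (ineligible voxels contribute 0); `peak_deviation` and
`mean_intensity` are alternatives. The per-voxel feature value feeding the
published workflow is not standardized anywhere we could anchor to, so the
scale-invariant choice that matches the selection statistic is the default
and is recorded in provenance.

The **ELM** (extreme learning machine) is implemented from scratch: input
weights and biases drawn from a seeded standard normal, logistic hidden
activations, and output weights solving the ridge-stabilized least-squares
problem against one-hot targets (λ = 10⁻⁸ — numerical safety only).
Retraining with the same seed is bit-for-bit reproducible. Default width
503 hidden units.

The **SVM** delegates to scikit-learn's `SVC(kernel="sigmoid")` — kernel
tanh(γ·x·x′ + c₀) with γ = 1/n_features, c₀ = 0, C = 1.09 — behind a
train-fold `StandardScaler`. Standardization is part of the classifier
handle because the tanh kernel saturates on raw intensity-scale features
(dot products ≫ 1 make the kernel matrix effectively constant, and
accuracy collapses below chance); on standardized features the same kernel
separates the synthetic cohorts cleanly.

Evaluation is stratified k-fold CV (default 10 folds, seed 0) with seeded
shuffling and a pooled confusion matrix; accuracy = 100·trace/sum. Feature
selection runs on all subjects before CV by default — a known optimistic
design kept for fidelity to the published workflow — and the chance-level
permutation/null checks in the test suite guard the pipeline against
silent leakage. Selection inside the CV loop can be composed manually from
the library pieces (select → fuse → features per training fold).

## Synthetic cohorts

`SyntheticSpec` defaults define the desk-scale study conditions: 12³ grid,
140 timepoints at TR = 2 s, 6 subjects per group × 2 runs, baseline 100,
noise SD 2, boxcar transients of amplitude 40 and width 3 TRs at seeded
random onsets, group effect +15, idiosyncratic extra-activation rate 0.001
per voxel. The two group-common sets are overlapping 3×3×3 clusters
(27 + 27 voxels, 8 shared; |union| = 46).

**Activation layout.** Every subject activates the *union* of the two
group-common sets at the base amplitude; each subject additionally gets
+`group_effect` of amplitude at their own group's common set. The group
difference is therefore purely one of response magnitude at fixed
locations: with `group_effect = 0` the groups are statistically identical
and classification must fall to chance, while the default effect separates
them cleanly. The group-wise intersection consequently recovers the union
of the common sets, which is what recovery metrics score against. Each
subject's idiosyncratic extras survive Phase I but essentially never
coincide across all subjects of a group, so the intersection strips them.

**Noise.** Default noise is i.i.d. uniform on [−√3·SD, +√3·SD] (variance
matched). Bounded noise gives the statistic a hard ceiling: a pure-noise
series has max/median deviation ratio < 2, so background voxels are never
selected at α = 3 and false-positive accounting is exact. White Gaussian
noise (`noise="gaussian"`) is available for realism but is unsuitable for
ground-truth recovery at α = 3: over 140 timepoints the maximum of
Gaussian deviations exceeds 3× their median (≈ 2.0σ) with probability
≈ 0.998 per voxel, so nearly the whole background is selected per subject.
This is a real property of the statistic on heavy-ish-tailed noise, worth
keeping in mind when interpreting α on real data, where temporal smoothing
and autocorrelation change the picture.

**Transients.** Boxcar rather than HRF-convolved by default — the
statistic is model-free, so only the deviation magnitude matters; an
optional double-gamma HRF-shaped mode (`hrf=True`) is included for
realism. The generator asserts post-hoc that every implanted voxel clears
α·M with a 1.2× margin and raises with guidance if amplitudes are too
small.

**What passing tests do and do not show.** The synthetic cohorts validate
the mechanics — selection, fusion, mapping, classification, determinism —
under controlled noise with known truth. They do not model physiological
noise, drift, motion, spatial autocorrelation, multi-site effects, or
realistic effect sizes, so test performance (perfect recovery, 100% CV
accuracy) says nothing about accuracy on real cohorts.

## Problem sizes

The recovery cohort uses 6 + 6 subjects × 2 runs on a 12³ grid; the
group-differential classification cohort (`classification_spec()`) uses
17 + 17 subjects × 1 run on a 10³ grid — enough subjects per class for
stratified 10-fold CV while staying desk-scale. The pipeline skips
classification with an explicit notice when the smallest class cannot
support the requested folds.

## Known limitations

- Strict intersection across many subjects is brittle on real data; the
  consensus fraction mitigates but deviates from the strict rule when < 1.
- The toy atlas is synthetic; region distributions on real data require a
  real lookup table.
- No preprocessing is performed or validated here: inputs are assumed
  already slice-time/motion corrected, normalized and smoothed, and all
  scans in one analysis must share a grid (enforced, not resampled).
- Feature selection before cross-validation inflates accuracy estimates;
  the defaults reproduce that published design rather than correct it.
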