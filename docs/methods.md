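# Methods

## The problem

A voltammetric e-tongue fingerprints a liquid sample with an array of
low-selectivity electrochemical sensors; multivariate analysis of the joint
signal then classifies the sample. Here the array is three modified
screen-printed carbon electrodes (SPCEs): CNP and GNP (copper/gold
nanoparticles, electrocatalytic for non-enzymatic glucose and fructose
oxidation) and Au/PEDOT (electrocatalytic for ascorbic-acid oxidation). The
classification task is tomato purée cultivar (perino, red datterino, yellow
datterino), whose glucose+fructose content differs significantly between
cultivars (reference IC-PAD quantification: 2.62+2.41, 3.37+4.02 and
3.92+4.17 g/100 g).

Each disposable electrode acquires 20 consecutive CV scans and is then
replaced; six aliquots (hence six electrodes) per cultivar and sensor give
3 × 3 × 6 = 54 measurements and 1080 scans in total.

## Synthetic signal model

No raw measurements are publicly deposited, so the `syndata` module
generates the campaign. The model is the simplest one exhibiting every
feature the preprocessing is designed to neutralize; it is **not** an
electrochemical simulation (no Butler–Volmer or Randles–Ševčík kinetics).

For a sensor with potential window [V₋, V₊], n points and a triangular
sweep (forward branch V₋→V₊, backward V₊→V₋; the upper bound is attained
exactly once), the current is

```
I(V) = b₀ + b₁·V ± c₀                      sloped baseline, ± double-layer
     + h · exp(−(V − Vp)² / 2w²)           forward-branch oxidation peak
     + α·h · exp(−(V − Vp + δ)² / 2w²)     backward branch, displaced by δ
     + ε,  ε ~ N(0, σ_noise²)
h  = S · L · g · (1 + i)^(−γ)
Vp = Vp⁰ + β·L
```

where L is the analyte load (glucose+fructose in g/100 g for CNP/GNP,
ascorbic acid in a.u. for PEDOT), S the sensitivity, g a per-electrode
lognormal factor (σ = `electrode_sd`), i the 0-based scan index and γ the
decay exponent. The ± capacitive term takes opposite signs on the two
branches, which together with the displaced backward peak produces the
hysteresis observed in real scans.

Parameter choices (frozen defaults, all overridable in `GeneratorConfig`):

| parameter | default | rationale |
|---|---|---|
| γ (decay exponent) | 0.5 | diffusion-limited decay of successive scan amplitudes |
| σ_noise | 0.05 µA | typical instrument noise at the µA current scale |
| electrode_sd | 0.05 | ≈5 % relative RSD, typical batch reproducibility of SPCEs |
| β (peak shift) | 8–10 mV per unit load | Tafel-type anodic shift of irreversible electrocatalytic oxidation with concentration |
| ascorbic-acid loads | 1.0 / 1.6 / 2.2 a.u. | unquantified in the reference data; chosen distinct so the PEDOT channel is class-separating |
| points per scan | 28000 / 27650 / 27650 | sampling rates are unreported; chosen so ⌊n/35⌋ sums to the documented 2380-feature instance |
| windows | 0→1, −0.5→0.6, −0.5→0.5 V | the stated CNP/GNP/PEDOT sweep windows |

Sensitivities and baselines are set so the CNP current range clearly
exceeds the GNP and PEDOT ranges, the condition that motivates the
range-equalization stage. The per-electrode factor scales only the peak
(the faradaic component), not the capacitive baseline, as electrode-area
and catalyst-loading variability act on the electroactive response.

What the generator does **not** emulate: drift within a scan, correlated
(1/f) noise, electrode fouling chemistry, temperature effects, and any
matrix interferences. Passing tests on this data therefore demonstrate the
pipeline's correctness and its behavior under the modeled nuisances — not
classifier performance on laboratory data. In particular the near-perfect
synthetic scores partly reflect the instance-level splitting protocol (scans
from one electrode can appear in both train and test); an electrode-level
split (`split_by="electrode"`) is provided for the stricter protocol.

## Preprocessing

* **Normalization to the first scan** maps scan *s* affinely so its extrema
  become the first scan *f*'s extrema; min/max in the denominator are those
  of the scan being normalized — the only reading under which the map lands
  exactly on *f*'s range. The first scan (index 0) maps to itself.
* **Range equalization** uses global training-set extrema per sensor; the
  maps are frozen at fit time, so an individual transformed test scan need
  not span the CNP range exactly. An ablated pipeline simply omits the
  removed sensor from fitting and concatenation.
* **Subsampling** averages disjoint windows of k points and discards the
  n mod k remainder, as the documented ⌊n/k⌋ output length implies
  (overlapping windows would not reduce the length by k). k = 1 is the
  identity; k > n is an error.
* **Pairing rule**: scans are grouped into three-sensor triples by
  (cultivar, electrode slot, scan index); the slot identifies the aliquot
  shared by the three sensors. Concatenation order is fixed CNP ‖ GNP ‖
  PEDOT. Instances are emitted sorted by key, so the result is invariant
  to input file order.
* **Fast path for repeated splits**: stage-1 normalization and subsampling
  are split-independent, so `PreparedDataset` caches the subsampled blocks
  and the full-resolution per-scan extrema once; each split refits the
  equalization constants from the cached extrema and applies them to the
  subsampled blocks. Window means commute with affine maps, so this is
  numerically identical (to rounding; asserted at 1e−9 in the tests) to the
  canonical order "equalize then subsample" while being ~50× cheaper over
  100 splits.

## Classification

* **LDA solver.** With m = 2380 features and d = 252 training instances the
  within-class scatter is singular. The package uses the SVD-based LDA
  solver, which is well defined in this regime (it operates in the data
  subspace and thresholds negligible singular values) and is fast enough
  for 100-split protocols; an explicit shrinkage estimate of a 2380 × 2380
  scatter would cost a dense generalized eigendecomposition per split for
  no accuracy benefit at this separation. c ≤ classes − 1 = 2 components.
* **Transform convention.** `transform(X) = (X − mean)·T`, the centered
  matrix product; centering shifts train and test identically and leaves
  nearest-centroid decisions unchanged.
* **KMeans head.** Clusters default to the number of classes; 10
  restarts seeded per run. Cluster labels are the majority class of the
  members; an empty cluster triggers a reseeded refit (bounded retries).
* **Tie-breaks.** Cluster-majority ties and nearest-centroid ties resolve
  to the lowest class/cluster index and are logged.
* **Comparators.** RF: 100 estimators, Gini, unlimited depth. SVM:
  polynomial kernel, degree 6. All unstated hyperparameters are
  scikit-learn defaults (logged at fit). The recurrent-network comparator
  is specified (dropout 0.6, softmax output, 30 % validation split) but has
  no backend in this dependency set; it raises a clear error and is skipped
  by the runner — no headline result depends on it.
* **Relevance.** For reporting, T's columns are rescaled to unit norm so
  coefficient magnitudes are comparable across components; each feature is
  annotated with its source sensor block.

## Evaluation protocol

100 independent random splits (test fraction 0.30; run r uses seed
base_seed + r), each refitting the equalization statistics and the
classifier on its training portion only. Metrics are macro-averaged over
classes — the design is balanced (120 scans per cultivar per sensor), where
macro ≈ micro — and accuracy is the fraction of correct predictions (the
multiclass reduction of the one-vs-rest TP+TN form). Runs whose training
split misses a class are skipped with a warning and excluded from the
averages. Measurement-level accuracy applies a majority vote over the
test-set predictions of each (cultivar, electrode) group.

Default splits are at the instance level, matching the scan-as-instance
protocol; the electrode-level alternative avoids within-electrode leakage
(see above). The one-way ANOVA check simulates triplicate glucose+fructose
sums per cultivar (sd 0.05 g/100 g, matching the reference quantification's
replicate scatter) and tests group-mean equality; degenerate zero-variance
inputs are handled explicitly (identical constants → F = 0, p = 1).

## Problem sizes and determinism

The test suite exercises the full campaign (1080 scans of 28000/27650
points, 2380 features) for the end-to-end checks; the LDA protocols run all
100 splits, while RF/SVM/PCA comparator ordering uses 20 splits of the same
seeded sequence — comparator means stabilize well before that, and the
ordering is what the check asserts. Unit and property tests use scaled-down
campaigns (same structure, shorter scans) generated at run time. Every
source of randomness flows from explicit seeds: the generator seed fixes
the dataset bit-for-bit; split r of a protocol uses base_seed + r; KMeans
and RF receive the run seed. Identical seeds reproduce every report
exactly.

## Serialization

Datasets are long-format CSV (one row per sampled point, 12-significant-
digit decimals; round-trips to ≤1e−9 relative) with a JSON manifest
recording files, class inventory, per-(cultivar, sensor) scan counts and an
optional generator-config echo. Fitted projection models serialize to JSON
(T, mean, centroids, cluster→class map, block lengths) and are sufficient
for prediction-only use — the property that makes this classifier attractive
for microcontroller deployment.

## Known limitations

* The synthetic generator's class signal (peak amplitude plus a small
  concentration-dependent peak shift) is idealized; real discrimination may
  rest on subtler waveform differences, and real scores may be lower.
* Ascorbic-acid loadings are placeholders (no reference quantification
  exists); the PEDOT channel's dominance in the relevance plots depends on
  them.
* The "without preprocessing" baseline feeds truncated raw sequences to the
  classifiers; how the original protocol made raw variable-length data
  rectangular is unknown, so those baseline numbers are indicative only.
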