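# Methods

This note documents the models, the synthetic data the package is exercised
on, the numerical choices, and the limitations — the things a maintainer or
reviewer would ask about that the API reference does not answer.

## The recognition problem

Three seed classes are measured by attenuated-total-reflection FT-IR on the
standard mid-IR grid (4000–650 cm⁻¹ at 2 cm⁻¹, 1676 points). Classes 1
and 2 are sibling species: same absorption band positions, band amplitudes
within a few percent of each other, so whole-spectrum distances are
dominated by within-class variation and cannot separate them. Class 3 is
chemically distinct. Specimens come from three collection locations
("batches") and each specimen is scanned three times.

Two analyses are implemented: (i) cluster analysis of 17-peak absorbance
tables (fuzzy compatibility relation + transitive closure + λ-cuts +
validity index, and a Ward dendrogram), which resolves the family-level
structure but not the siblings; and (ii) a discriminative pipeline —
5-level Daubechies DWT, five wavelet-energy features (three regions at
detail 3, two at detail 4), RBF-network classifier — which resolves all
three classes.

## Synthetic spectrum generator

No measured spectra ship with the package; all experiments run on a
generator whose defaults *are* the benchmark conditions.

A spectrum is a sum of Gaussian bands (Lorentzian available per band),
`A(ν) = Σ_b α_b exp(−4 ln2 · (ν − ν_b)² / w_b²)`, plus a linear baseline and
i.i.d. noise. The shared band table has 21 bands covering the classic seed
assignments (O–H/N–H 3400, =C–H 3010, C–H 2925/2854, ester C=O 1745, amide
I/II/III 1650/1545/1240, fingerprint C–O 1150/1035 cm⁻¹, …) with
class-specific amplitudes:

* class 1: reference amplitude profile;
* class 2: class 1's profile pulled toward the class-1/class-3 midpoint by
  `(1 − sibling_overlap)` (default overlap 0.9 → ~5 % amplitude shifts),
  plus one low-amplitude class-2-only *marker band* at 2240 cm⁻¹ (FWHM
  22 cm⁻¹, amplitude `0.4·(1 − overlap)` = 0.04 AU at default). The marker
  sits in the quiet 2500–1800 cm⁻¹ window — a nitrile-type stretch is the
  chemical analogue — so that sibling recognition is *possible* (a clean
  narrow-scale wavelet signature) but invisible to whole-spectrum peak
  similarity. In the `sibling_overlap = 1` limit classes 1 and 2 are
  bit-identical, because random streams are keyed by (batch, specimen,
  replicate) and never by class;
* class 3: an independently chosen amplitude profile differing strongly at
  several bands (3010, 1745, 1650, 1035, …).

Variation model and defaults, chosen once as plausible bench magnitudes for
powdered-seed ATR work:

| source | form | default |
|---|---|---|
| batch gain | per-batch multiplicative, N(1, σ) | σ = 0.02 |
| batch calibration shift | per-batch, all centers, N(0, σ) cm⁻¹ | σ = 1.0 |
| specimen gain | per-specimen multiplicative (amount/pressure) | σ = 0.02 |
| band jitter | per-band per-specimen multiplicative (composition) | σ = 0.03 |
| baseline | per-replicate `offset + slope·t`, t ∈ [0,1] | offset U(0.02, 0.06), slope U(0, 0.04) AU |
| noise | per-replicate i.i.d. N(0, σ) per point | σ = 0.002 AU |

The benchmark layout is 20 specimens per (class × batch) cell in each of a
train and a test split (360 specimens, 1080 scans), matching the 5 %
granularity of per-cell recognition rates on 20-specimen cells.

What the generator does *not* emulate: non-linear/curved baselines,
atmospheric CO₂/H₂O lines, ATR penetration-depth wavelength dependence,
band-shape asymmetry, correlated (pink) noise, or batch-specific chemistry.
Passing benchmarks here therefore demonstrate the pipeline's correctness
and its behavior under the modeled variation sources, not instrument-grade
robustness.

## Preprocessing

* **Baseline**: rubber-band correction — subtract the lower convex hull of
  the trace (exact monotone-chain hull, not a Qhull call, so exactly
  collinear input is handled). Parameter-free, idempotent, annihilates
  linear drift exactly, output ≥ 0 by construction.
* **Replicates**: pointwise mean of the three scans (noise SD shrinks by
  √3), then baseline correction.
* **Peak tables**: the 17 most topographically prominent local maxima, with
  a minimum separation of 3 grid points; prominence ties break toward the
  lower wavenumber. For cluster analysis the per-specimen tables are aligned
  onto the union of reference band centers (nearest center within
  ±20 cm⁻¹); where a specimen lacks a matched peak the absorbance at the
  center's grid point is used, so every specimen rates the same attribute
  set. Absorbance values only (not positions) feed the clustering.

## Fuzzy cluster analysis

Ratings are trapezoidal fuzzy numbers; crisp absorbances are wrapped as
degenerate TFNs so one code path serves both. Chen's squared distance is
implemented as the corner-averaged quadratic `¼ Σ (Δcorner)²` (the ¼ weight
is exposed), which reduces to the plain squared difference on crisp data.
Columns with zero range are dropped with a warning, since the min–max
normalization divides by the range. The transitive closure uses repeated
max–min self-composition (squaring), reaching the fixpoint in ≤ ⌈log₂(n−1)⌉
steps; λ-cuts then coincide with single-linkage components of the original
relation, which is the independent oracle used in tests. The λ series
enumerates only the distinct values of the closure (partitions change
nowhere else) and keeps the coarsest λ per cluster count.

**Validity index caveat.** `L = T/(n·d²_min)` is computed for every
partition with `2 ≤ h < n` (the all-singleton partition is excluded because
`T = 0` makes it trivially optimal). On data with continuous within-class
variation the index retains a bias toward near-singleton partitions: at
`h = n−1` the only scatter is one merged pair and `d²_min` is a
within-class distance, giving `L ≈ 1/(2n)` *independent of class
separation*. The index therefore identifies the true cluster count reliably
only when clusters are tight relative to their separation (where
`L(h_true) → 0`); on the default sibling benchmark the informative
comparison is among coarse partitions (e.g. `L(3)` vs `L(2)`), and both are
reported in the validity table rather than a single argmin.

## Wavelet features

Daubechies-4, periodized boundaries, 5 levels (defaults; db1–db10 and
symmetric extension are configurable). Periodization gives perfect
reconstruction at any length and makes the transform an orthonormal basis
whenever the length is divisible by 2⁵ — the Parseval identity is tested at
1e−10 relative on such lengths. On the native 1676-point grid the
odd-length stages each pad one sample, so energy equality is only
approximate there; feature energies are plain sums of squared coefficients
and do not rely on it. Detail coefficient `k` at level `j` is anchored to
source samples `[k·2ʲ, (k+1)·2ʲ)`, which maps every coefficient to a
half-open descending wavenumber interval for reporting.

**Region selection.** Boundaries are data-driven and deterministic: for
each target level, squared coefficients of the training specimens give a
per-coefficient Fisher ratio for *every class pair*
(`(μ_a − μ_b)²/(σ²_a + σ²_b)`); each pair's profile is smoothed (moving
average, window 3), edge-guarded (2 boundary coefficients excluded, since
periodization mixes both ends of the spectrum), and rescaled to its own
maximum; the selection score is the elementwise maximum over pairs. The
highest-scoring contiguous runs above a (relaxing) quantile threshold
become the 3 + 2 regions, ranked by peak score with ties to the lower start
index. The per-pair rescaling is deliberate: an unnormalized three-class
Fisher ratio lets the easily-separated class dominate every region, and the
sibling pair's best region — the only one that can resolve classes 1 and 2
— is never selected; rescaling guarantees each pair's strongest run competes
at the same scale. Manual region boundaries can be supplied instead.
Energies are used raw (no log, no normalization); a spectrum scaled by `c`
scales every feature by `c²`.

## RBF network

`φ_j(x) = exp(−‖x − c_j‖²/(2σ_j²))`, linear output layer with bias, one-hot
targets, argmax decision with ties to the lowest class index. Defaults:
per-feature standardization fitted on the training split (region energies
span orders of magnitude and Gaussian kernels need commensurate axes);
k = 12 centers by k-means (k-means++, 10 seeded restarts, best inertia);
widths = mean distance to the 2 nearest other centers; ridge 1e−6 on the
least-squares output weights. `center_method="all_samples"` with ridge 0
reproduces exact interpolation (solved by pseudo-inverse; a singular design
warns). Everything is deterministic given the training seed. The hidden
layer's input weights are fixed at 1 — only the output layer is trained —
so training is a single linear solve, no gradient descent.

## Experiment protocols

* **Cluster experiment**: 10 specimens per class (batches cycled), 17-peak
  aligned tables, Ward dendrogram + fuzzy λ series + validity table.
* **Classification experiment**: the full 360-specimen benchmark. Region
  selection, feature scaling and network training see the training split
  only; a `leak_regions` switch exists solely so tests can verify that
  violating the protocol can only raise, never lower, apparent accuracy.
* **Benchmark**: the classification experiment over 5 seeds; reports
  per-class cell-rate means pooled over seeds and the worst single cell per
  class. Sizes (20 per cell, 5 seeds) keep the whole benchmark under ten
  seconds while placing per-cell rates on the 5 % lattice.

## Degenerate inputs and tie-breaking

Identical objects make the compatibility scale factor η undefined: the
relation is returned as all-ones with a flag. λ-cuts on non-transitive
relations are refused rather than silently repaired. Validity needs h ≥ 2
and non-empty clusters. Peak picking raises when fewer than m local maxima
exist (e.g. flat traces). k > n is a configuration error for k-means
centers. Coincident k-means centers get the mean positive width as a
fallback. All ties anywhere (peak prominence, region ranking, class scores)
break deterministically, toward lower wavenumber / lower index / lower
class label.

## Known limitations

* The feature regions adapt to the training data; they are not fixed
  instrument-independent wavenumber windows, so models and regions must be
  serialized together (the CLI writes `regions.json` next to `model.json`).
* The validity index's near-singleton bias (above) limits its use for
  automatic cluster-count selection on noisy data.
* The generator's band table is a stylized model of seed tissue chemistry;
  amplitudes are plausible but not fitted to any measured spectrum.
* Only the Daubechies family is wired in; the family choice is a
  configuration default, not an optimized selection.
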