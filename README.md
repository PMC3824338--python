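# ftirseed

Classification of mid-infrared (FT-IR) absorbance spectra of three
confusable plant-seed classes — two *sibling* species with nearly identical
chemical composition plus one distinct species — using discrete-wavelet
energy features and a radial basis function (RBF) network, with a
fuzzy-relation / Ward cluster analysis of absorption-peak tables alongside.
The package is aimed at chemometricians who want a tested, reproducible
reference implementation of this classic recognition pipeline, exercised on
a synthetic spectrum generator that emulates the statistical structure of
real seed spectra (shared band positions, sibling amplitude overlap,
location-batch effects, replicate scans, baseline drift, detector noise).

## The method

**Cluster branch.** Specimens are described by the absorbances of their
*m* = 17 most prominent absorption peaks. Ratings are treated as
trapezoidal fuzzy numbers `x = (c, a, b, d)` (crisp values are the
degenerate case), min–max normalized per attribute, and compared with
Chen's squared geometrical distance `d²(x, y) = ¼ Σₖ (xₖ − yₖ)²`. The fuzzy
compatibility relation

    R(i, k) = 1 − η · Σⱼ d²(x̃ᵢⱼ, x̃ₖⱼ),   η = 1 / maxᵢₖ Σⱼ d²(x̃ᵢⱼ, x̃ₖⱼ)

is closed under max–min composition into a fuzzy equivalence relation; its
λ-cuts (λ descending over the distinct values of the closure) give a nested
partition series, ranked by the validity index `L = T / (n · d²_min)`
(within-cluster scatter over smallest squared centroid separation — smaller
is better). Ward's minimum-variance dendrogram of the same peak tables is
built alongside, with Newick export.

**Classification branch.** Each specimen's baseline-corrected (rubber-band),
replicate-averaged spectrum on the 4000–650 cm⁻¹ / 2 cm⁻¹ grid is
decomposed into 5 dyadic scales with a Daubechies-4 wavelet (periodized).
Five feature regions — three over the detail-3 coefficients, two over
detail 4 — are selected on the training split only, by smoothed pairwise
Fisher ratios of the squared coefficients. The feature vector is the region
energies `Sᵣ = Σₖ w²ⱼₖ`, and a 5-input / Gaussian-hidden-layer / 3-output
RBF network (k-means centers, ridge least-squares output weights) assigns
the class. Results are reported as per-(class × batch × split) recognition
rates in percent.

## Worked example

```python
from ftirseed import RunConfig, run_classification_experiment, run_cluster_experiment

# Ward clustering of 30 specimens (10 per class) on 17-peak tables
cluster = run_cluster_experiment(RunConfig(), n_per_class=10, seed=1)
fam = {g: sorted(set(cluster.class_ids[cluster.top_cut == g])) for g in (0, 1)}
print("top-level families:", fam)

# Full benchmark: 20 specimens per (class x batch) cell in train and test
res = run_classification_experiment(RunConfig(), seed=1)
print("per-class average recognition (%):",
      {c: round(v, 2) for c, v in res.report.class_averages.items()})
```

prints

```
top-level families: {0: [3], 1: [1, 2]}
per-class average recognition (%): {1: 100.0, 2: 100.0, 3: 100.0}
```

The first line is the cluster-analysis finding: the top split of the Ward
dendrogram isolates the distinct class (3) but lumps the sibling classes
(1, 2) into one family — whole-spectrum peak similarity cannot tell the
siblings apart. The second line shows that the wavelet-energy features can:
the RBF network recognizes all three classes, including the confusable
sibling, in every location batch of both splits.

The same experiments are available from the shell:

```bash
ftirseed all --seed 1 --out runs/demo          # cluster + 5-seed benchmark
ftirseed generate --seed 3 --out runs/data     # dataset as CSV + manifest
ftirseed classify --data runs/data --out runs/clf
```

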