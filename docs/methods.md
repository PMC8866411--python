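# Methods

## Subset-trim-average augmentation

For one subject and one parcellation resolution, probabilistic
tractography is run `R` times, giving `R` weighted graphs over the same
node universe ("interim" fiber-count weights per edge). Two reductions
are implemented, sharing the same zero-filter/trim/average core:

* **Consensus averaging** (`basic_average`): keep the edges with nonzero
  weight in all `R` runs; for each, delete the minimum and maximum of its
  `R` weights and assign the arithmetic mean of the remaining `R − 2`.
  One graph per subject; requires `R ≥ 3`.
* **Subset augmentation** (`newtonian_blur`): for every `k`-element
  subset of the runs, in lexicographic order over 0-based run indices,
  apply the same reduction within the subset — zero-filter over the `k`
  chosen runs only, then a trimmed mean with `trim` values removed per
  side. `C(R, k)` graphs per subject; the default `(10, 7, 1)` gives
  120, and `(R, R, 1)` recovers consensus averaging exactly (same code
  path, bitwise-equal output, asserted in tests).

The method's appeal is that it augments without fabricating data: every
output weight is a trimmed mean of measured fiber counts, and the
edge-set perturbation is exactly the reconstruction variability the
consensus step would otherwise average away. An edge with zero fibers in
exactly `z` runs survives in `C(R − z, k)` of the `C(R, k)` outputs —
those subsets drawn entirely from the `R − z` nonzero runs — which the
suite verifies both in closed form and against brute-force subset
enumeration.

### Numerical choices

* **Tie handling in trimming:** each trim step removes exactly one
  occurrence of the current maximum and one of the current minimum, so an
  all-equal list of length `k` keeps `k − 2·trim` values and its mean is
  unchanged. Any other convention would make all-equal edges
  ill-defined.
* **Determinism:** subsets are enumerated lexicographically and the
  trimmed core is summed in ascending order, so identical inputs always
  produce identical outputs and output files are byte-stable (edge rows
  are written sorted).
* **Degenerate inputs:** empty runs yield empty augmented graphs; the
  Jaccard distance of two empty edge sets is defined as 0 so
  self-distance always exists (logged when it triggers).
* **Weights are doubles** even though raw fiber counts are integers,
  since trimmed means are fractional; absent edge ≡ weight 0, and
  zero-weight rows on input are dropped with a warning rather than
  rejected.

## Jaccard diagnostics

`jaccard_distance` uses unweighted edge sets only — the statistic is
about *which* connections differ, not by how much — and is a true metric
(symmetry, identity, triangle inequality; property-tested).
`pairwise_class_distances` partitions all `C(|A|+|B|, 2)` pairs of two
augmented sets into within-A ("red"), within-B ("blue") and across
("green") classes; for two 120-graph sets that is 7140 + 7140 + 14400 =
28,680 pairs. Histograms use left-closed, right-open bins of width
0.005 by default, fine enough to resolve the narrow within-subject peak.

## Synthetic cohort generator

No real diffusion-MRI data is used anywhere; the generator produces run
ensembles with the statistical structure the method relies on:

* a cohort-level **backbone** of candidate node pairs (anatomy constrains
  which regions can connect), default 30% of all pairs at 83 nodes —
  roughly 500 latent edges per subject, a realistic edge count at that
  scale;
* per-subject **latent graphs**: each backbone pair present independently
  with `subject_edge_prob = 0.5`, so two subjects share only part of
  their edge sets (between-subject variability);
* per-run **detection**: each latent edge appears in a run with
  `detection_prob = 0.995`, calibrated so the mean within-subject
  augmented-set Jaccard distance lands near 0.02 — the magnitude
  reported for real repeated-tractography ensembles. (At `(10, 7)`, an
  edge zeroed in one run flips membership between 36/120 and 84/120 of
  the subsets, so within-distance is roughly `P(z=1) · 2·0.3·0.7 ≈
  10·(1−p)·p⁹ · 0.42`, putting `p` near 0.995 for a 0.02 distance.)
* **fiber counts**: latent means are log-normal (mean 30, log-dispersion
  1 — the simplest skewed positive model), per-run counts zero-truncated
  Poisson around the mean;
* a **class label** (emulating sex) that raises edge probability by
  `class_effect = 0.1` on a designated 20% of the backbone for label +1
  subjects — a weak, presence-based signal, matching the use of 0–1
  weighted graphs in the classifier.

All randomness is drawn from `numpy` substreams keyed by
`(seed, stream, subject_index)`, so cohorts are reproducible and
individual subjects can be regenerated independently of order.

What the generator does **not** model: spatial anatomy (no geometry or
hemispheres), weight-based group differences, correlated detection
failures across edges, scanner/site effects, and any coupling between
the five resolutions (each is generated independently). Passing tests
therefore demonstrate the combinatorial and ordering properties of the
pipeline, not performance on real connectomes; the between-subject
distances of synthetic pairs (~0.66) are much larger than those of the
two most similar real subjects (~0.14), because real anatomy is far more
shared than an independent-coin-flip backbone.

## SVM experiment

Graphs enter the classifier as binary upper-triangle indicator vectors
(`n(n−1)/2` features, lexicographic pair order). The model is the
soft-margin linear SVM `min ½ w·w + C Σ zᵢ` s.t. `yᵢ(w·xᵢ − b) ≥ 1 − zᵢ`,
`zᵢ ≥ 0`. When each training point is replaced by `fold` augmented
copies, the penalty becomes `C / fold`, which preserves the objective
under exact duplication — verified to 1e−6 against libsvm's exact dual
solver on a toy problem. `train_linear_svm` exposes that exact solver;
the experiment loop uses liblinear's hinge-loss dual coordinate descent,
which scales to the 120-fold training sets (its intercept regularization
is the one deviation from the exact objective, and it is likewise
invariant under the duplication/rescaling pair).

`augmentation_experiment` splits *subjects* (never graphs) into
train/test, stratified by label at fraction 0.7 — the split shape that
yields 737/316 on a 1053-subject cohort. The plain arm trains on one
consensus graph per training subject at penalty `C`; the augmented arm
on all `C(R, k)` augmented graphs per training subject at `C / C(R, k)`;
both evaluate on the identical held-out consensus graphs, and no
augmented graph of a test subject is ever constructed. The C grid is
`log₁₀ C ∈ [−4, 2]` in steps of 0.5. As the non-augmented baseline the
consensus-average graph is the natural choice (it is the graph one would
publish per subject); an alternative baseline — a single arbitrary run —
would conflate augmentation with run-selection noise.

At the scale the suite exercises (120 subjects, 40 nodes, 5 replicate
seeds, chosen so the whole experiment runs in well under a minute per
seed on one CPU), the augmented arm's mean test accuracy over the upper
(weakly regularized) half of the grid matches or exceeds the plain
arm's. The advantage is small and seed-dependent — with a weak synthetic
signal both arms hover between 0.52 and 0.62 — so it is asserted as an
ordering averaged over seeds, not as an effect size.

## Problem sizes and limitations

The acceptance computations use: 1053 subjects per resolution for the
count checks, with the backbone density scaled at finer resolutions to
keep roughly 1000 candidate edges per subject (real connectomes get
sparser as parcels shrink; this also keeps the 5 × 1053-subject run to a
few minutes); two default subjects for the deviation analysis; and the
120-subject/40-node cohort above for the classifier. Augmented sets are
materialized eagerly (120 dict-backed graphs per subject), which is fine
at these sizes but would need a streaming layout for full-resolution
cohorts at 1015 nodes. `R` is taken as given (the choice of 10
repetitions is an upstream design input, not analyzed here), and no
distributional fitting of the distance histograms is attempted.
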