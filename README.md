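# newtblur

Data augmentation for weighted braingraphs (connectomes) built from
repeated probabilistic tractography, with diagnostics and a classifier
experiment — exercised entirely on synthetic ensembles.

## The problem

A braingraph's nodes are anatomically labeled brain regions (ROIs) at a
fixed parcellation resolution (83, 129, 234, 463 or 1015 nodes in the
standard multiresolution atlas); an edge carries the number of
tractography streamlines ("fiber number") detected between two regions.
Streamline reconstruction is probabilistic: running it `R` times on the
same scan yields `R` slightly different weighted graphs. The usual
consensus construction keeps only edges detected in all `R` runs, drops
each edge's minimum and maximum weight and averages the rest — one robust
graph per subject.

For machine-learning applications one graph per subject is often too
little data. The augmentation implemented here perturbs the
*error-correcting step* rather than the data: for every `k`-element
subset of the `R` runs (each of the `C(R, k)` possible choices), edges
with zero fibers in any chosen run are deleted, then each surviving
edge's minimum and maximum weight among the `k` are dropped and the
remaining `k − 2` are averaged. With the default `(R, k, trim) =
(10, 7, 1)` each subject yields `C(10, 7) = 120` augmented graphs, every
one of them a trimmed mean of actually measured fiber counts — no
artificial noise is ever injected.

Two consequences the package computes and tests:

* **Edge-survival combinatorics.** An edge with zero fibers in exactly
  `z` of the `R` runs appears in exactly `C(R − z, k)` augmented graphs
  (0 if `k > R − z`): 120, 36, 8, 1, 0, … at the defaults, following the
  Pascal identity `C(9,6) + C(9,7) = C(10,7)`.
* **Diversity.** With the Jaccard distance on edge sets,
  `J(G₁, G₂) = |E₁ Δ E₂| / |E₁ ∪ E₂|`, the augmented graphs of one
  subject stay close to each other (mean distance on the order of 0.02)
  while graphs of different subjects differ several-fold more — the
  structure a useful augmentation needs.

The SVM experiment replaces each training subject's single consensus
graph (binary 0–1 edge indicators) by its 120 augmented graphs. Because
the soft-margin objective `½ w·w + C Σ zᵢ` scales its loss term with the
sample count, the penalty must become `C / 120` for the augmented problem
to be comparable: duplicating every point 120-fold at `C/120` provably
recovers the original optimum, a property the test suite checks to
1e−6.

## Worked example

```python
from newtblur import (AugmentationConfig, SyntheticCohortConfig,
                      generate_cohort, newtonian_blur, pairwise_class_distances)

cohort = generate_cohort(SyntheticCohortConfig(n_subjects=2, seed=6))
set_a, set_b = (newtonian_blur(e, AugmentationConfig()).graphs
                for e in cohort.ensembles)
d = pairwise_class_distances(set_a, set_b)
print(len(set_a), d.n_pairs, round(d.mean_within(), 4), round(d.mean_between(), 4))
```

prints

```
120 28680 0.0222 0.6632
```

Each subject's 10 runs became 120 augmented graphs; the 240 graphs form
28,680 pairs; augmented graphs of the same subject differ in ~2.2% of
their edges while graphs of different subjects differ in ~66% (synthetic
subjects share only a random half of the anatomical backbone, so they are
far less alike than two real people).

The same steps are available from the shell:

```bash
newtblur simulate --subjects 2 --seed 6 --out cohort/
newtblur blur --input-dir cohort/sub0000 --output-dir aug_a/
newtblur blur --input-dir cohort/sub0001 --output-dir aug_b/
newtblur jaccard --set-a aug_a --set-b aug_b --out hist.csv
newtblur svm-experiment --cohort-dir cohort/ --out curves.csv
```

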