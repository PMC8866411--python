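"""Subset-trim-average augmentation of braingraph run ensembles.

Probabilistic tractography makes repeated runs on the same scan disagree
slightly, both in which edges they detect and in the fiber counts.  The
standard consensus construction (:func:`basic_average`) keeps only edges
detected in all ``R`` runs, drops each edge's minimum and maximum weight
and averages the rest, producing one robust graph per subject.

The augmentation implemented here perturbs that error-correcting step
instead of the data: every ``k``-element subset of the ``R`` runs is
reduced the same way (zero-filter within the subset, trim, average),
yielding ``C(R, k)`` plausible consensus graphs per subject — e.g. 120
graphs from 10 runs at ``k = 7``.  No artificial noise is injected; every
augmented weight is a trimmed mean of actually measured fiber counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .graph_model import (
    AugmentationConfig,
    Edge,
    RunEnsemble,
    ValidationError,
    WeightedBraingraph,
    validate_ensemble,
)

__all__ = [
    "AugmentedSet",
    "enumerate_subsets",
    "surviving_edges",
    "trimmed_mean",
    "newtonian_blur",
    "basic_average",
    "edge_survival_count",
]


@dataclass
class AugmentedSet:
    """The full augmented output for one ensemble: one graph per subset.

    ``items`` pairs each sorted ``k``-tuple of run indices (in
    lexicographic order) with the graph built from that subset; its length
    is always ``C(R, k)``.
    """

    subject_id: str
    resolution_name: str
    config: AugmentationConfig
    items: list[tuple[tuple[int, ...], WeightedBraingraph]]

    def __post_init__(self) -> None:
        if len(self.items) != self.config.n_subsets:
            raise ValidationError(
                f"augmented set has {len(self.items)} items, expected "
                f"C({self.config.R},{self.config.k}) = {self.config.n_subsets}"
            )
        subsets = [s for s, _ in self.items]
        if subsets != sorted(set(subsets)):
            raise ValidationError("subsets must be distinct and in lexicographic order")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def graphs(self) -> list[WeightedBraingraph]:
        return [g for _, g in self.items]


def enumerate_subsets(R: int, k: int) -> list[tuple[int, ...]]:
    """All ``k``-element subsets of run indices ``0..R-1``, lexicographic.

    Exactly ``C(R, k)`` sorted tuples; e.g. ``(10, 7)`` yields 120.
    """
    if not 1 <= k <= R:
        raise ValidationError(f"need 1 <= k <= R, got k={k}, R={R}")
    return list(itertools.combinations(range(R), k))


def surviving_edges(ensemble: RunEnsemble, subset: Sequence[int]) -> set[Edge]:
    """Edges with nonzero weight in *every* run of ``subset``.

    The zero-filter is applied within the subset only: runs outside the
    subset are ignored, so an edge missing from an unchosen run survives.
    """
    for i in subset:
        if not 0 <= i < ensemble.n_runs:
            raise ValidationError(f"run index {i} out of range [0, {ensemble.n_runs})")
    if not subset:
        raise ValidationError("subset must be non-empty")
    sets = [ensemble.runs[i].edge_set() for i in subset]
    return set(frozenset.intersection(*sets))


def trimmed_mean(weights: Iterable[float], trim: int) -> float:
    """Mean of ``weights`` after removing ``trim`` smallest and ``trim`` largest.

    Exactly one occurrence is removed per extreme per trim step, so an
    all-equal list of length ``k`` keeps ``k - 2*trim`` values and its mean
    is unchanged.  The result always lies within ``[min, max]`` of the
    input.  Summation runs in ascending order for determinism.
    """
    vals = sorted(float(w) for w in weights)
    k = len(vals)
    if k - 2 * trim < 1:
        raise ValidationError(f"need k - 2*trim >= 1, got k={k}, trim={trim}")
    core = vals[trim : k - trim]
    return sum(core) / len(core)


def newtonian_blur(ensemble: RunEnsemble, config: AugmentationConfig) -> AugmentedSet:
    """Build the full ``C(R, k)`` augmented set for one subject's ensemble.

    For each ``k``-subset of runs, in lexicographic order: keep the edges
    nonzero in every run of the subset, and weight each by the trimmed
    mean of its ``k`` subset weights (``trim`` removed per side).

    The per-subset work is vectorized over the union edge set; the
    resulting weights agree with :func:`trimmed_mean` applied edge by
    edge to floating-point precision.
    """
    validate_ensemble(ensemble, config)
    R, k, trim = config.R, config.k, config.trim
    edges: list[Edge] = sorted(set().union(*(r.edges.keys() for r in ensemble.runs)))
    n_edges = len(edges)
    col = {e: j for j, e in enumerate(edges)}
    weights = np.zeros((R, n_edges), dtype=np.float64)
    for i, run in enumerate(ensemble.runs):
        for e, w in run.edges.items():
            weights[i, col[e]] = w

    items: list[tuple[tuple[int, ...], WeightedBraingraph]] = []
    for subset in enumerate_subsets(R, k):
        sub = weights[list(subset)]
        surviving = np.flatnonzero((sub > 0).all(axis=0))
        core = np.sort(sub[:, surviving], axis=0)[trim : k - trim]
        means = core.mean(axis=0).tolist()
        graph = WeightedBraingraph(
            ensemble.subject_id,
            ensemble.resolution_name,
            ensemble.parcellation,
            dict(zip((edges[j] for j in surviving.tolist()), means)),
        )
        items.append((subset, graph))
    return AugmentedSet(ensemble.subject_id, ensemble.resolution_name, config, items)


def basic_average(ensemble: RunEnsemble) -> WeightedBraingraph:
    """Plain consensus graph: zero-filter over all runs, trim 1, average.

    Keeps only edges nonzero in all ``R`` runs and assigns each the
    trimmed mean of its ``R`` weights with one extreme removed per side.
    Equivalent to the single graph of :func:`newtonian_blur` at
    ``(R, k=R, trim=1)``; requires ``R >= 3``.
    """
    if ensemble.n_runs < 3:
        raise ValidationError(
            f"consensus averaging needs at least 3 runs, got {ensemble.n_runs}"
        )
    config = AugmentationConfig.basic(R=ensemble.n_runs)
    return newtonian_blur(ensemble, config).items[0][1]


def edge_survival_count(zero_runs: int, config: AugmentationConfig) -> int:
    """Number of augmented graphs containing an edge absent in ``zero_runs`` runs.

    An edge with weight 0 in exactly ``zero_runs`` of the ``R`` runs
    survives precisely in the subsets drawn entirely from the remaining
    ``R - zero_runs`` runs: ``C(R - zero_runs, k)``, or 0 when fewer than
    ``k`` nonzero runs remain.  At ``(10, 7)``: 120 for 0 zero runs,
    36 for 1, 8 for 2, 1 for 3, 0 beyond.
    """
    R, k = config.R, config.k
    if not 0 <= zero_runs <= R:
        raise ValidationError(f"zero_runs must lie in [0, {R}], got {zero_runs}")
    if k > R - zero_runs:
        return 0
    return math.comb(R - zero_runs, k)
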