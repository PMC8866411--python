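"""Core domain types for weighted braingraph run ensembles.

A braingraph (connectome) is an undirected graph whose nodes are
anatomically labeled gray-matter parcels (ROIs, fixed by a
:class:`Parcellation`) and whose edges carry the number of tractography
streamlines ("fiber number") detected between two parcels.  Because
streamline reconstruction is probabilistic, repeated tractography runs on
the same scan yield slightly different graphs; a :class:`RunEnsemble`
collects the ``R`` run-graphs of one subject at one resolution.

:class:`AugmentationConfig` holds the ``(R, k, trim)`` triple that governs
subset-trim-average augmentation: every ``k``-subset of the ``R`` runs is
reduced to one graph by dropping ``trim`` minimum and ``trim`` maximum
weights per edge and averaging the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Iterator

#: Unordered node pair stored canonically as ``(min(u, v), max(u, v))``.
Edge = tuple[int, int]

#: Node counts of the standard multiresolution cortical/subcortical atlas.
STANDARD_RESOLUTIONS = (83, 129, 234, 463, 1015)


class ValidationError(ValueError):
    """A graph, ensemble or configuration violates a structural invariant."""


def canonical_edge(u: int, v: int) -> Edge:
    """Return the canonical (sorted) key for the unordered pair ``{u, v}``."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Parcellation:
    """A fixed, ordered node universe at one atlas resolution.

    Parameters
    ----------
    resolution_name
        Text label of the resolution, e.g. ``"scale83"``.
    nodes
        Ordered ``(node_id, label)`` pairs.  Node ids are 1-based positive
        integers, unique and strictly increasing, matching anatomical
        parcellation conventions.
    """

    resolution_name: str
    nodes: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        nodes = tuple((int(i), str(lab)) for i, lab in self.nodes)
        object.__setattr__(self, "nodes", nodes)
        ids = [i for i, _ in nodes]
        if len(ids) < 2:
            raise ValidationError("a parcellation needs at least 2 nodes")
        if ids[0] <= 0:
            raise ValidationError("node ids must be positive integers")
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValidationError("node ids must be unique and strictly increasing")

    @cached_property
    def node_ids(self) -> frozenset[int]:
        return frozenset(i for i, _ in self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @classmethod
    def generic(cls, n_nodes: int, resolution_name: str | None = None) -> "Parcellation":
        """A synthetic parcellation with nodes ``1..n_nodes`` and generic labels."""
        name = resolution_name if resolution_name is not None else f"scale{n_nodes}"
        return cls(name, tuple((i, f"roi_{i:04d}") for i in range(1, n_nodes + 1)))


@dataclass
class WeightedBraingraph:
    """One subject's undirected, fiber-count-weighted braingraph.

    ``edges`` maps canonical unordered node pairs to strictly positive
    weights; an absent pair encodes weight 0.  Weights are reals: raw runs
    carry integer streamline counts, but trimmed-mean graphs have
    fractional weights.
    """

    subject_id: str
    resolution_name: str
    parcellation: Parcellation
    edges: dict[Edge, float]

    def __post_init__(self) -> None:
        # fast path: already-canonical dicts (the common case for graphs
        # built by this package) need no rebuild
        if all(u <= v and type(w) is float for (u, v), w in self.edges.items()):
            return
        canon: dict[Edge, float] = {}
        for (u, v), w in self.edges.items():
            key = (u, v) if u <= v else (v, u)
            w = float(w)
            if key in canon and canon[key] != w:
                raise ValidationError(
                    f"graph {self.subject_id!r}: conflicting duplicate edge {key}"
                )
            canon[key] = w
        self.edges = canon

    def validate(self) -> "WeightedBraingraph":
        """Check self-loop, endpoint-membership and positivity invariants."""
        ids = self.parcellation.node_ids
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValidationError(f"graph {self.subject_id!r}: self-loop edge ({u},{v})")
            if u not in ids or v not in ids:
                raise ValidationError(
                    f"graph {self.subject_id!r}: edge ({u},{v}) has an endpoint "
                    f"outside parcellation {self.parcellation.resolution_name!r}"
                )
            if not w > 0:
                raise ValidationError(
                    f"graph {self.subject_id!r}: edge ({u},{v}) has non-positive weight {w}"
                )
        return self

    def weight(self, u: int, v: int) -> float:
        """Weight of the unordered pair ``{u, v}``; 0.0 when the edge is absent."""
        return self.edges.get(canonical_edge(u, v), 0.0)

    def edge_set(self) -> frozenset[Edge]:
        return frozenset(self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[Edge]:
        return iter(self.edges)


@dataclass
class RunEnsemble:
    """Ordered list of ``R`` run-graphs of one subject at one resolution.

    Run order is significant (runs are indexed ``0..R-1`` by subset
    enumeration) and preserved.
    """

    subject_id: str
    resolution_name: str
    parcellation: Parcellation
    runs: tuple[WeightedBraingraph, ...]

    def __post_init__(self) -> None:
        self.runs = tuple(self.runs)
        if len(self.runs) < 1:
            raise ValidationError(f"ensemble {self.subject_id!r}: needs at least one run")

    @property
    def n_runs(self) -> int:
        return len(self.runs)


@dataclass(frozen=True)
class AugmentationConfig:
    """The ``(R, k, trim)`` triple governing subset-trim-average augmentation.

    ``R`` is the ensemble size, ``k`` the subset size, and ``trim`` the
    number of extreme weights removed per side before averaging; at least
    one weight must survive (``k - 2*trim >= 1``).  The augmentation
    default is ``(10, 7, 1)``; plain consensus averaging is ``(R, R, 1)``.
    """

    R: int = 10
    k: int = 7
    trim: int = 1

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValidationError(f"R must be positive, got {self.R}")
        if not 1 <= self.k <= self.R:
            raise ValidationError(f"k must satisfy 1 <= k <= R, got k={self.k}, R={self.R}")
        if self.trim < 0:
            raise ValidationError(f"trim must be non-negative, got {self.trim}")
        if self.k - 2 * self.trim < 1:
            raise ValidationError(
                f"k - 2*trim must be >= 1, got k={self.k}, trim={self.trim}"
            )

    @property
    def n_subsets(self) -> int:
        """Number of augmented graphs produced per ensemble, ``C(R, k)``."""
        return math.comb(self.R, self.k)

    @classmethod
    def basic(cls, R: int = 10) -> "AugmentationConfig":
        """Config for plain consensus averaging: one graph from all R runs."""
        return cls(R=R, k=R, trim=1)


def validate_ensemble(ensemble: RunEnsemble, config: AugmentationConfig) -> RunEnsemble:
    """Validate all ensemble invariants against ``config`` and return it.

    Checks that the run count equals ``config.R``, that every run shares
    the ensemble's subject, resolution and parcellation, and that every
    run-graph satisfies the graph invariants (edge keys are canonicalized
    at graph construction, so validation is idempotent).

    Raises
    ------
    ValidationError
        Naming the offending run and edge.
    """
    if ensemble.n_runs != config.R:
        raise ValidationError(
            f"ensemble {ensemble.subject_id!r}: expected {config.R} runs, "
            f"got {ensemble.n_runs}"
        )
    for i, run in enumerate(ensemble.runs):
        if run.subject_id != ensemble.subject_id:
            raise ValidationError(
                f"run {i}: subject_id {run.subject_id!r} != ensemble "
                f"{ensemble.subject_id!r}"
            )
        if run.resolution_name != ensemble.resolution_name:
            raise ValidationError(
                f"run {i}: resolution {run.resolution_name!r} != ensemble "
                f"{ensemble.resolution_name!r}"
            )
        if run.parcellation != ensemble.parcellation:
            raise ValidationError(f"run {i}: parcellation differs from the ensemble's")
        try:
            run.validate()
        except ValidationError as exc:
            raise ValidationError(f"run {i}: {exc}") from exc
    return ensemble
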