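"""Jaccard distance on edge sets and pairwise-distance diagnostics.

The diversity of an augmented set is measured with the Jaccard distance
between edge sets,

    J(G1, G2) = |E(G1) Δ E(G2)| / |E(G1) ∪ E(G2)|,

the fraction of edges in which the two graphs differ (weights are
ignored).  For two subjects' augmented sets A and B, the pairwise
distances split into three classes — within A ("red"), within B ("blue")
and across ("green") — whose distributions show how tightly augmented
graphs cluster around their subject relative to the between-subject
separation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .graph_model import Edge, ValidationError, WeightedBraingraph

logger = logging.getLogger(__name__)

__all__ = [
    "PairClassDistances",
    "jaccard_distance",
    "pairwise_class_distances",
    "histogram",
]

#: Default histogram bin width; fine enough to resolve the narrow
#: within-subject peak.
DEFAULT_BIN_WIDTH = 0.005


@dataclass
class PairClassDistances:
    """Jaccard distances of all graph pairs from two sets, by class.

    ``red``: within set A (``C(|A|, 2)`` pairs), ``blue``: within set B,
    ``green``: across A×B (``|A|·|B|`` pairs).
    """

    red: list[float]
    blue: list[float]
    green: list[float]

    @property
    def n_pairs(self) -> int:
        return len(self.red) + len(self.blue) + len(self.green)

    def mean_within(self) -> float:
        """Pooled mean over both within-subject classes."""
        within = self.red + self.blue
        return float(np.mean(within))

    def mean_between(self) -> float:
        return float(np.mean(self.green))


def _check_same_parcellation(g1: WeightedBraingraph, g2: WeightedBraingraph) -> None:
    if g1.parcellation.nodes != g2.parcellation.nodes:
        raise ValidationError(
            f"parcellation mismatch: {g1.parcellation.resolution_name!r} vs "
            f"{g2.parcellation.resolution_name!r}"
        )


def _jaccard_sets(e1: frozenset[Edge], e2: frozenset[Edge]) -> float:
    inter = len(e1 & e2)
    union = len(e1) + len(e2) - inter
    if union == 0:
        return 0.0
    return (union - inter) / union


def jaccard_distance(g1: WeightedBraingraph, g2: WeightedBraingraph) -> float:
    """Fraction of edges in which the two graphs differ, in [0, 1].

    Uses unweighted edge sets.  Two empty graphs are at distance 0 by
    convention (so self-distance is always defined); this degenerate case
    is logged.
    """
    _check_same_parcellation(g1, g2)
    e1, e2 = g1.edge_set(), g2.edge_set()
    if not e1 and not e2:
        logger.debug(
            "jaccard_distance(%s, %s): both edge sets empty, returning 0 by convention",
            g1.subject_id,
            g2.subject_id,
        )
    return _jaccard_sets(e1, e2)


def pairwise_class_distances(
    set_a: Sequence[WeightedBraingraph], set_b: Sequence[WeightedBraingraph]
) -> PairClassDistances:
    """All within-A, within-B and across-pair Jaccard distances.

    For two 120-graph augmented sets this is 7140 + 7140 + 14400 = 28,680
    pairs, i.e. ``C(240, 2)`` in total.
    """
    if not set_a or not set_b:
        raise ValidationError("both graph sets must be non-empty")
    reference = set_a[0]
    for g in list(set_a) + list(set_b):
        _check_same_parcellation(reference, g)
    ea = [g.edge_set() for g in set_a]
    eb = [g.edge_set() for g in set_b]
    red = [_jaccard_sets(x, y) for x, y in combinations(ea, 2)]
    blue = [_jaccard_sets(x, y) for x, y in combinations(eb, 2)]
    green = [_jaccard_sets(x, y) for x in ea for y in eb]
    result = PairClassDistances(red=red, blue=blue, green=green)
    assert result.n_pairs == math.comb(len(set_a), 2) + math.comb(len(set_b), 2) + len(
        set_a
    ) * len(set_b)
    return result


def histogram(
    distances: Sequence[float], bin_width: float = DEFAULT_BIN_WIDTH
) -> list[tuple[float, int]]:
    """Histogram with left-closed right-open bins starting at 0.

    Returns ``(bin_start, count)`` for every bin from 0 through the last
    occupied bin (interior empty bins included); counts sum to the input
    length.  A value exactly on a bin edge falls in the bin starting
    there.
    """
    if bin_width <= 0:
        raise ValidationError(f"bin width must be positive, got {bin_width}")
    if len(distances) == 0:
        return []
    arr = np.asarray(distances, dtype=np.float64)
    if (arr < 0).any():
        raise ValidationError("distances must be non-negative")
    idx = np.floor(arr / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    return [(i * bin_width, int(c)) for i, c in enumerate(counts)]
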