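import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from newtblur.graph_model import Parcellation, RunEnsemble, WeightedBraingraph

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def parc5() -> Parcellation:
    return Parcellation.generic(5)


@pytest.fixture
def parc10() -> Parcellation:
    return Parcellation.generic(10)


def ensemble_from_matrix(parc, edges, weight_matrix, subject_id="s1"):
    """Build a run ensemble from an (R, n_edges) weight matrix; 0 = absent."""
    runs = []
    for row in weight_matrix:
        data = {e: float(w) for e, w in zip(edges, row) if w > 0}
        runs.append(
            WeightedBraingraph(subject_id, parc.resolution_name, parc, data)
        )
    return RunEnsemble(subject_id, parc.resolution_name, parc, tuple(runs))


def random_ensemble(rng, parc, n_edges, R, zero_prob=0.15, subject_id="s1"):
    """Random ensemble over `n_edges` distinct pairs with sprinkled zeros."""
    all_pairs = [
        (u, v)
        for i, (u, _) in enumerate(parc.nodes)
        for (v, _) in parc.nodes[i + 1 :]
    ]
    sel = rng.choice(len(all_pairs), size=min(n_edges, len(all_pairs)), replace=False)
    edges = [all_pairs[i] for i in sorted(sel)]
    W = rng.integers(1, 50, size=(R, len(edges))).astype(float)
    W[rng.random((R, len(edges))) < zero_prob] = 0.0
    return ensemble_from_matrix(parc, edges, W, subject_id), edges, W


@pytest.fixture
def make_ensemble(parc5):
    def _make(weight_matrix, edges=((1, 2), (1, 3), (2, 4), (3, 5)), subject_id="s1"):
        return ensemble_from_matrix(
            parc5, list(edges)[: len(weight_matrix[0])], weight_matrix, subject_id
        )

    return _make
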