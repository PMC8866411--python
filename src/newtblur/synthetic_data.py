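"""Synthetic tractography-run ensembles and labeled cohorts.

The generator emulates the statistical structure of repeated probabilistic
tractography over a cohort:

* a population-level *backbone* of candidate edges shared by all subjects
  (anatomy constrains which region pairs can plausibly connect);
* each subject's *latent* graph includes each backbone edge independently
  with probability ``subject_edge_prob``, so subjects differ from one
  another far more than runs on one subject differ;
* each of ``runs_per_subject`` runs detects each latent edge independently
  with probability ``detection_prob`` (close to 1: reconstruction is
  reliable but not perfectly reproducible) and reports an integer fiber
  count of at least 1 drawn around the edge's latent mean;
* a binary class label (e.g. sex) shifts ``subject_edge_prob`` by
  ``class_effect`` on a designated backbone subset — a weak,
  edge-presence-based structural signal.

All randomness is derived from ``(seed, subject_index)`` substreams, so a
cohort is fully reproducible and individual subjects can be regenerated
independently of generation order.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from . import graph_io
from .graph_model import (
    Parcellation,
    RunEnsemble,
    ValidationError,
    WeightedBraingraph,
)

__all__ = [
    "SyntheticCohortConfig",
    "LabeledCohort",
    "sample_latent_graph",
    "sample_run_ensemble",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate an 83-node resolution: ~30% of node pairs are
    anatomically plausible candidates, each present in a given subject
    with probability 0.5 (~500 latent edges, a realistic edge count at
    this scale), runs detect an existing edge with probability 0.995
    (repeated runs agree on all but a few edges, so within-subject
    augmented-set Jaccard distances land near 0.02), and fiber counts are
    skewed with mean 30.
    """

    n_subjects: int
    n_nodes: int = 83
    runs_per_subject: int = 10
    backbone_density: float = 0.3
    subject_edge_prob: float = 0.5
    detection_prob: float = 0.995
    mean_fibers: float = 30.0
    fiber_dispersion: float = 1.0
    class_effect: float = 0.1
    class_edge_fraction: float = 0.2
    class_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be positive")
        if self.n_nodes < 2:
            raise ValidationError("n_nodes must be at least 2")
        if self.runs_per_subject < 1:
            raise ValidationError("runs_per_subject must be positive")
        for name in ("backbone_density", "subject_edge_prob", "detection_prob"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValidationError(f"{name} must lie in (0, 1], got {value}")
        if not 0 <= self.class_fraction <= 1:
            raise ValidationError("class_fraction must lie in [0, 1]")
        if not 0 < self.class_edge_fraction <= 1:
            raise ValidationError("class_edge_fraction must lie in (0, 1]")
        if self.class_effect < 0:
            raise ValidationError("class_effect must be non-negative")
        if self.mean_fibers <= 0 or self.fiber_dispersion <= 0:
            raise ValidationError("mean_fibers and fiber_dispersion must be positive")

    @property
    def parcellation(self) -> Parcellation:
        return Parcellation.generic(self.n_nodes)


@dataclass
class LabeledCohort:
    """Per-subject run ensembles with ±1 class labels."""

    ensembles: list[RunEnsemble]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.ensembles) != len(self.labels):
            raise ValidationError("ensembles and labels must have equal length")
        if any(y not in (-1, 1) for y in self.labels):
            raise ValidationError("labels must be +1 or -1")

    @property
    def n_subjects(self) -> int:
        return len(self.ensembles)


@lru_cache(maxsize=32)
def _backbone(config: SyntheticCohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Cohort-level candidate pairs and the class-effect mask over them.

    Drawn once per config from the cohort substream ``(seed, 0)`` and
    shared by all subjects.
    """
    rng = np.random.default_rng([config.seed, 0])
    iu, ju = np.triu_indices(config.n_nodes, k=1)
    pairs = np.column_stack([iu + 1, ju + 1])  # 1-based node ids
    total = len(pairs)
    m = max(1, int(round(config.backbone_density * total)))
    chosen = np.sort(rng.choice(total, size=m, replace=False))
    backbone = pairs[chosen]
    n_class = max(1, int(round(config.class_edge_fraction * m)))
    class_mask = np.zeros(m, dtype=bool)
    class_mask[rng.choice(m, size=n_class, replace=False)] = True
    return backbone, class_mask


def _subject_id(subject_index: int) -> str:
    return f"sub{subject_index:04d}"


def sample_latent_graph(
    config: SyntheticCohortConfig, subject_index: int, label: int
) -> WeightedBraingraph:
    """The subject's latent (noise-free) graph: true edges and mean fibers.

    Deterministic given ``(config.seed, subject_index)``.  Each backbone
    pair is included independently with ``subject_edge_prob``, shifted up
    by ``class_effect`` on the designated subset when ``label`` is +1
    (clipped at 1).  Latent mean fiber counts are log-normal with mean
    ``mean_fibers`` and log-scale dispersion ``fiber_dispersion``.  With
    ``class_effect = 0`` the label does not influence the draw.
    """
    if label not in (-1, 1):
        raise ValidationError(f"label must be +1 or -1, got {label}")
    backbone, class_mask = _backbone(config)
    rng = np.random.default_rng([config.seed, 1, subject_index])
    u = rng.random(len(backbone))
    sigma = config.fiber_dispersion
    mu = math.log(config.mean_fibers) - 0.5 * sigma**2
    means = rng.lognormal(mean=mu, sigma=sigma, size=len(backbone))
    probs = np.full(len(backbone), config.subject_edge_prob)
    if label == 1 and config.class_effect > 0:
        probs[class_mask] = np.minimum(1.0, probs[class_mask] + config.class_effect)
    present = u < probs
    edges = {
        (int(a), int(b)): float(w)
        for (a, b), w in zip(backbone[present], means[present])
    }
    return WeightedBraingraph(
        _subject_id(subject_index), config.parcellation.resolution_name,
        config.parcellation, edges,
    )


def _truncated_poisson(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Poisson draws conditioned to be >= 1, vectorized by rejection."""
    counts = rng.poisson(lam)
    zero = counts == 0
    guard = 0
    while zero.any():
        counts[zero] = rng.poisson(lam[zero])
        zero = counts == 0
        guard += 1
        if guard > 10_000:  # pragma: no cover - lam > 0 terminates a.s.
            counts[zero] = 1
            break
    return counts


def sample_run_ensemble(
    latent: WeightedBraingraph, config: SyntheticCohortConfig, subject_index: int
) -> RunEnsemble:
    """Simulate ``runs_per_subject`` tractography runs of a latent graph.

    Each latent edge appears in each run independently with
    ``detection_prob``; when detected, its fiber count is a
    zero-truncated Poisson around the latent mean.  Non-latent edges
    never appear.  Deterministic given ``(config.seed, subject_index)``.
    """
    rng = np.random.default_rng([config.seed, 2, subject_index])
    edge_list = sorted(latent.edges)
    lam = np.array([latent.edges[e] for e in edge_list], dtype=np.float64)
    runs = []
    for _ in range(config.runs_per_subject):
        if len(edge_list) == 0:
            runs.append(
                WeightedBraingraph(
                    latent.subject_id, latent.resolution_name, latent.parcellation, {}
                )
            )
            continue
        detected = rng.random(len(edge_list)) < config.detection_prob
        counts = _truncated_poisson(rng, lam)
        edges = {
            e: float(c) for e, c, d in zip(edge_list, counts, detected) if d
        }
        runs.append(
            WeightedBraingraph(
                latent.subject_id, latent.resolution_name, latent.parcellation, edges
            )
        )
    return RunEnsemble(
        latent.subject_id, latent.resolution_name, latent.parcellation, tuple(runs)
    )


def generate_cohort(config: SyntheticCohortConfig) -> LabeledCohort:
    """Generate a fully reproducible labeled cohort.

    The first ``ceil(class_fraction * n_subjects)`` subjects get label +1,
    the rest -1.  Per-subject randomness is keyed by subject index, so
    regenerating with the same config yields an identical cohort.
    """
    n = config.n_subjects
    n_pos = math.ceil(config.class_fraction * n)
    labels = [1] * n_pos + [-1] * (n - n_pos)
    ensembles = []
    for i in range(n):
        latent = sample_latent_graph(config, i, labels[i])
        ensembles.append(sample_run_ensemble(latent, config, i))
    return LabeledCohort(ensembles=ensembles, labels=labels)


def write_cohort(
    cohort: LabeledCohort, directory: str | Path, config: SyntheticCohortConfig
) -> Path:
    """Write a cohort directory: one subdirectory of run CSVs per subject.

    Layout: ``<dir>/parcellation.csv``, ``<dir>/labels.csv``
    (``subject_id,label``), ``<dir>/manifest.json`` (full config), and
    ``<dir>/<subject>/run_00.csv .. run_NN.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    parcellation = cohort.ensembles[0].parcellation
    graph_io.write_parcellation(parcellation, directory / "parcellation.csv")
    with (directory / "labels.csv").open("w") as fh:
        fh.write("subject_id,label\n")
        for ens, y in zip(cohort.ensembles, cohort.labels):
            fh.write(f"{ens.subject_id},{y:+d}\n")
    (directory / "manifest.json").write_text(
        json.dumps({"config": asdict(config)}, indent=2) + "\n"
    )
    for ens in cohort.ensembles:
        subdir = directory / ens.subject_id
        subdir.mkdir(exist_ok=True)
        for r, run in enumerate(ens.runs):
            graph_io.write_edgelist(run, subdir / f"run_{r:02d}.csv")
    return directory


def read_cohort(directory: str | Path) -> LabeledCohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    parcellation = graph_io.read_parcellation(directory / "parcellation.csv")
    labels: dict[str, int] = {}
    with (directory / "labels.csv").open() as fh:
        header = fh.readline()
        if not header.startswith("subject_id,label"):
            raise ValidationError(f"{directory}/labels.csv: unexpected header")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            sid, y = line.split(",")
            labels[sid] = int(y)
    ensembles = []
    label_list = []
    for sid in labels:
        subdir = directory / sid
        run_files = sorted(subdir.glob("run_*.csv"))
        if not run_files:
            raise ValidationError(f"{subdir}: no run_*.csv files")
        runs = tuple(
            graph_io.read_edgelist(p, parcellation, sid) for p in run_files
        )
        ensembles.append(
            RunEnsemble(sid, parcellation.resolution_name, parcellation, runs)
        )
        label_list.append(labels[sid])
    return LabeledCohort(ensembles=ensembles, labels=label_list)
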