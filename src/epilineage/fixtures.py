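"""Labelled lineage fixtures and small shared utilities.

The Markov fixture emulates cluster-to-cluster state dynamics with a
known row-stochastic transition matrix, producing forest edges, cluster
labels and the exact tally of the multinomial draws — the ground truth
against which the transition tally is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lineage import LineageForest
from .transitions import sort_clusters


@dataclass
class MarkovFixtureSpec:
    """Specification of a synthetic cluster-transition experiment."""

    clusters: list[str]
    matrix: np.ndarray  # row-stochastic, clusters x clusters
    cells_per_cluster: int | dict[str, int] = 100
    progeny_per_cell: int = 2
    origin_timepoint: str = "Day0"
    destination_timepoint: str = "Day5"
    seed: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.clusters)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix shape must match the cluster count")
        if (self.matrix < 0).any():
            raise ValueError("transition probabilities must be >= 0")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("matrix rows must sum to 1")
        if self.progeny_per_cell < 1:
            raise ValueError("progeny_per_cell must be >= 1")

    def n_cells(self, cluster: str) -> int:
        if isinstance(self.cells_per_cluster, dict):
            return int(self.cells_per_cluster.get(cluster, 0))
        return int(self.cells_per_cluster)


def make_markov_fixture(
    spec: MarkovFixtureSpec,
) -> tuple[LineageForest, dict[str, str], pd.DataFrame]:
    """Draw a labelled two-timepoint forest from a known transition matrix.

    Returns (forest, labels, truth_counts) where ``truth_counts`` is the
    exact per-(origin, destination) tally of the draws.
    """
    rng = np.random.default_rng(spec.seed)
    order = sort_clusters(spec.clusters)
    forest = LineageForest(
        timepoint_order=[spec.origin_timepoint, spec.destination_timepoint]
    )
    labels: dict[str, str] = {}
    truth = pd.DataFrame(0, index=order, columns=order, dtype=int)
    serial = 0
    for ci, cluster in enumerate(spec.clusters):
        for _ in range(spec.n_cells(cluster)):
            origin_id = f"o{serial}"
            serial += 1
            forest.add_node(origin_id, spec.origin_timepoint)
            labels[origin_id] = cluster
            dests = rng.choice(
                len(spec.clusters), size=spec.progeny_per_cell, p=spec.matrix[ci]
            )
            for d in dests:
                child_id = f"d{serial}"
                serial += 1
                dest_cluster = spec.clusters[int(d)]
                forest.add_node(child_id, spec.destination_timepoint)
                labels[child_id] = dest_cluster
                forest.add_edge(origin_id, child_id)
                truth.loc[cluster, dest_cluster] += 1
    return forest, labels, truth


def compute_functional_titre(
    cell_number: float, gfp_positive_fraction: float, volume_ul: float
) -> float:
    """Functional lentiviral titre in transducing units per microlitre.

    titre [TU/µl] = cell_number × GFP-positive fraction / volume [µl].
    The fraction is on [0, 1]; percentage readouts must be divided by
    100 before the call.
    """
    if volume_ul <= 0:
        raise ValueError("volume_ul must be > 0")
    if not 0.0 <= gfp_positive_fraction <= 1.0:
        raise ValueError("gfp_positive_fraction must be in [0, 1]")
    if cell_number < 0:
        raise ValueError("cell_number must be >= 0")
    return cell_number * gfp_positive_fraction / volume_ul


@dataclass
class MarkovLabeller:
    """Label a true division tree with Markov cluster dynamics.

    Origin-generation cells receive clusters uniformly at random; each
    sampled descendant draws its cluster from the matrix row of its
    origin-generation ancestor.  Used to attach synthetic transcriptome
    states to simulator output for end-to-end pipeline runs.
    """

    clusters: list[str]
    matrix: np.ndarray
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("matrix rows must sum to 1")
        self._rng = np.random.default_rng(self.seed)

    def label(
        self,
        origin_cells: list[str],
        descendant_ancestor: dict[str, str],
    ) -> dict[str, str]:
        labels: dict[str, str] = {}
        index = {c: i for i, c in enumerate(self.clusters)}
        for cell in sorted(origin_cells):
            labels[cell] = self.clusters[int(self._rng.integers(len(self.clusters)))]
        for cell in sorted(descendant_ancestor):
            anc = descendant_ancestor[cell]
            row = index[labels[anc]]
            labels[cell] = self.clusters[
                int(self._rng.choice(len(self.clusters), p=self.matrix[row]))
            ]
        return labels
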