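"""Transcriptome-state transition analysis over a lineage forest.

Given a directional lineage forest and per-cell gene-expression cluster
labels (produced upstream by an external single-cell pipeline), tallies
traced (ancestor, descendant) pairs into an origin-cluster ×
destination-cluster transition matrix, collapses it into row-normalised
chord tables for circular-layout visualisation, and derives each
origin state's restricted repertoire of reachable destination states.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .lineage import LineageForest


def cluster_sort_key(name: str) -> tuple:
    """Numeric-aware lexical sort key so that C2 orders before C10."""
    return tuple(
        int(part) if part.isdigit() else part for part in re.split(r"(\d+)", name) if part
    )


def sort_clusters(names) -> list[str]:
    return sorted(set(names), key=cluster_sort_key)


@dataclass
class TransitionMatrix:
    """Integer counts of traced pairs per (origin, destination) cluster."""

    counts: pd.DataFrame  # index = origin clusters, columns = destination clusters
    origin_timepoint: str
    destination_timepoint: str
    n_excluded: int = 0  # traced edges with an unlabelled endpoint

    @property
    def clusters(self) -> list[str]:
        return list(self.counts.index)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["row_total"] = self.row_totals
        col_totals = out.sum(axis=0)
        col_totals.name = "column_total"
        return pd.concat([out, col_totals.to_frame().T])

    def write_tsv(self, path) -> None:
        self.with_margins().to_csv(path, sep="\t", index_label="origin")


def transitions(
    forest: LineageForest,
    labels: dict[str, str],
    origin_timepoint: str,
    destination_timepoint: str,
    clusters: list[str] | None = None,
) -> TransitionMatrix:
    """Tally forest edges between two timepoints into a transition matrix.

    Edges with an unlabelled endpoint are excluded and counted in
    ``n_excluded``; the matrix total equals the number of fully
    labelled edges between the two timepoints.
    """
    order = forest.timepoint_order
    if origin_timepoint == destination_timepoint:
        raise ValueError("origin and destination timepoints must differ")
    if order.index(origin_timepoint) > order.index(destination_timepoint):
        raise ValueError("origin timepoint must precede destination timepoint")
    if clusters is None:
        clusters = sort_clusters(labels.values())
    else:
        clusters = sort_clusters(clusters)
    counts = pd.DataFrame(0, index=clusters, columns=clusters, dtype=int)
    n_excluded = 0
    for ancestor, child in forest.edges:
        if (
            forest.timepoint_of(ancestor) != origin_timepoint
            or forest.timepoint_of(child) != destination_timepoint
        ):
            continue
        la, lc = labels.get(ancestor), labels.get(child)
        if la is None or lc is None:
            n_excluded += 1
            continue
        counts.loc[la, lc] += 1
    return TransitionMatrix(
        counts=counts,
        origin_timepoint=origin_timepoint,
        destination_timepoint=destination_timepoint,
        n_excluded=n_excluded,
    )


def collapse_by_origin(matrix: TransitionMatrix) -> pd.DataFrame:
    """Row-normalise the matrix into a chord table.

    One row per nonzero (origin, destination) count with the fraction
    of the origin's traced progeny; origins with no traced progeny emit
    no rows; ordering is (origin, destination) with numeric-aware sort.
    """
    rows = []
    for origin in matrix.clusters:
        row_total = int(matrix.counts.loc[origin].sum())
        if row_total == 0:
            continue
        for dest in matrix.clusters:
            count = int(matrix.counts.loc[origin, dest])
            if count > 0:
                rows.append((origin, dest, count, count / row_total))
    return pd.DataFrame(rows, columns=["origin", "destination", "count", "fraction"])


def restricted_repertoire(
    matrix: TransitionMatrix, min_count: int = 1
) -> dict[str, dict[str, list[str]]]:
    """Per-origin reached / unreached destination-state sets.

    A destination is reached from an origin iff its pair count is at
    least ``min_count``; reached and unreached partition the declared
    cluster set for every origin.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    out: dict[str, dict[str, list[str]]] = {}
    for origin in matrix.clusters:
        reached = [
            dest
            for dest in matrix.clusters
            if int(matrix.counts.loc[origin, dest]) >= min_count
        ]
        unreached = [dest for dest in matrix.clusters if dest not in set(reached)]
        out[origin] = {"reached": reached, "unreached": unreached}
    return out


def export_chord(table: pd.DataFrame, path) -> None:
    """Write a chord table as deterministic TSV (origin, destination, count, fraction)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_chord(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_repertoire(repertoire: dict, path) -> None:
    Path(path).write_text(json.dumps(repertoire, indent=2, sort_keys=True) + "\n")


@dataclass
class ClusterLabels:
    """Per-cell cluster names with timepoints, loaded from a label TSV."""

    labels: dict[str, str] = field(default_factory=dict)
    timepoints: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "ClusterLabels":
        df = pd.read_csv(path, sep="\t")
        required = {"cell_id", "cluster", "timepoint"}
        if not required <= set(df.columns):
            raise ValueError(f"label table must have columns {sorted(required)}")
        if df["cell_id"].duplicated().any():
            raise ValueError("each cell may be labelled once")
        return cls(
            labels=dict(zip(df["cell_id"], df["cluster"])),
            timepoints=dict(zip(df["cell_id"], df["timepoint"])),
        )

    def to_tsv(self, path) -> None:
        rows = [
            (cell, self.labels[cell], self.timepoints.get(cell, ""))
            for cell in sorted(self.labels)
        ]
        pd.DataFrame(rows, columns=["cell_id", "cluster", "timepoint"]).to_csv(
            path, sep="\t", index=False
        )
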