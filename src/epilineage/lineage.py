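"""Directional ancestry deconvolution from shared-barcode fingerprints.

Because episomes are partitioned randomly at division and never gained,
a descendant's barcode set is (up to capture dropout) a subset of its
ancestor's.  Ancestry is therefore inferred by scoring barcode sharing
between cells of consecutive timepoints: each later-timepoint cell is
assigned the earlier-timepoint cell with the largest number of shared
barcodes (Jaccard as tie-break), subject to a minimum shared count and
a minimum margin over the runner-up.  Assignments across timepoint
pairs compose into a directional lineage forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CellFingerprint:
    """A cell's identity signal: its set of distinct lineage barcodes."""

    cell_id: str
    timepoint: str
    barcodes: frozenset[str]
    umi_counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "barcodes", frozenset(self.barcodes))


def fingerprints_from_table(
    table: pd.DataFrame, timepoints: dict[str, str]
) -> list[CellFingerprint]:
    """Build fingerprints from a (cell_id, barcode, umi_count) table.

    Cells absent from the timepoint map are skipped.
    """
    out = []
    for cell, group in table.groupby("cell_id", sort=True):
        tp = timepoints.get(cell)
        if tp is None:
            continue
        out.append(
            CellFingerprint(
                cell_id=cell,
                timepoint=tp,
                barcodes=frozenset(group["barcode"]),
                umi_counts=dict(zip(group["barcode"], group["umi_count"])),
            )
        )
    return out


@dataclass(frozen=True)
class SimilarityRecord:
    """Barcode-sharing statistics between an earlier cell A and later cell B."""

    cell_a: str
    cell_b: str
    shared: int
    jaccard: float
    containment_in_child: float
    size_a: int
    size_b: int


def pairwise_similarity(a: CellFingerprint, b: CellFingerprint) -> SimilarityRecord:
    """Shared count, Jaccard and child containment for a cell pair.

    ``b`` is treated as the later-timepoint (child) cell, so
    ``containment_in_child`` is |A ∩ B| / |B|.
    """
    if not a.barcodes or not b.barcodes:
        raise ValueError("fingerprints must be non-empty")
    shared = len(a.barcodes & b.barcodes)
    union = len(a.barcodes | b.barcodes)
    return SimilarityRecord(
        cell_a=a.cell_id,
        cell_b=b.cell_id,
        shared=shared,
        jaccard=shared / union,
        containment_in_child=shared / len(b.barcodes),
        size_a=len(a.barcodes),
        size_b=len(b.barcodes),
    )


@dataclass(frozen=True)
class AssignmentRecord:
    child: str
    ancestor: str | None
    shared: int
    jaccard: float
    containment: float
    margin: int
    status: str  # "assigned" | "below_threshold" | "ambiguous"
    size_ancestor: int
    size_child: int


@dataclass
class AncestryAssignment:
    """Child→ancestor mapping for one (earlier, later) timepoint pair."""

    earlier_timepoint: str
    later_timepoint: str
    records: dict[str, AssignmentRecord] = field(default_factory=dict)

    @property
    def assigned(self) -> dict[str, AssignmentRecord]:
        return {c: r for c, r in self.records.items() if r.status == "assigned"}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                r.child,
                r.ancestor if r.ancestor is not None else "",
                r.shared,
                r.jaccard,
                r.containment,
                r.margin,
                r.status,
            )
            for _, r in sorted(self.records.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["child", "ancestor", "shared", "jaccard", "containment", "margin", "status"],
        )


def assign_ancestors(
    earlier: list[CellFingerprint],
    later: list[CellFingerprint],
    min_shared: int = 3,
    min_margin: int = 1,
) -> AncestryAssignment:
    """Assign each later-timepoint cell its best-sharing earlier ancestor.

    The candidate maximising the shared-barcode count wins (Jaccard
    breaks shared-count ties); the assignment is kept only when
    ``shared >= min_shared`` and the shared-count margin over the
    runner-up is ``>= min_margin``.  Exact (shared, Jaccard) ties are
    recorded as ambiguous rather than broken arbitrarily.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    if not earlier or not later:
        raise ValueError("both fingerprint collections must be non-empty")
    tps_earlier = {f.timepoint for f in earlier}
    tps_later = {f.timepoint for f in later}
    if len(tps_earlier) != 1 or len(tps_later) != 1:
        raise ValueError("each collection must carry a single timepoint")
    tp_e, tp_l = tps_earlier.pop(), tps_later.pop()
    if tp_e == tp_l:
        raise ValueError("earlier and later timepoints must differ")

    assignment = AncestryAssignment(earlier_timepoint=tp_e, later_timepoint=tp_l)
    earlier_sorted = sorted(earlier, key=lambda f: f.cell_id)
    for child in sorted(later, key=lambda f: f.cell_id):
        sims = [pairwise_similarity(anc, child) for anc in earlier_sorted]
        ranked = sorted(sims, key=lambda s: (-s.shared, -s.jaccard, s.cell_a))
        best = ranked[0]
        runner_shared = ranked[1].shared if len(ranked) > 1 else 0
        margin = best.shared - runner_shared
        tie = (
            len(ranked) > 1
            and ranked[1].shared == best.shared
            and ranked[1].jaccard == best.jaccard
        )
        if best.shared < min_shared:
            status, ancestor = "below_threshold", None
        elif margin < min_margin or tie:
            status, ancestor = "ambiguous", None
        else:
            status, ancestor = "assigned", best.cell_a
        assignment.records[child.cell_id] = AssignmentRecord(
            child=child.cell_id,
            ancestor=ancestor,
            shared=best.shared,
            jaccard=best.jaccard,
            containment=best.containment_in_child,
            margin=margin,
            status=status,
            size_ancestor=best.size_a,
            size_child=best.size_b,
        )
    return assignment


@dataclass
class LineageForest:
    """Directional forest of inferred ancestry edges across timepoints."""

    timepoint_order: list[str]
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_node(self, cell_id: str, timepoint: str, **annotations) -> None:
        if timepoint not in self.timepoint_order:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        self.graph.add_node(cell_id, timepoint=timepoint, **annotations)

    def add_edge(self, ancestor: str, child: str) -> None:
        rank = {tp: i for i, tp in enumerate(self.timepoint_order)}
        tp_a = self.graph.nodes[ancestor]["timepoint"]
        tp_c = self.graph.nodes[child]["timepoint"]
        if rank[tp_a] >= rank[tp_c]:
            raise ValueError("edges must go from earlier to later timepoint")
        if self.graph.in_degree(child) > 0:
            existing = next(self.graph.predecessors(child))
            if existing != ancestor:
                raise ValueError(f"conflicting parents for {child!r}")
            return
        self.graph.add_edge(ancestor, child)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("edge would create a cycle")

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges())

    def timepoint_of(self, cell_id: str) -> str:
        return self.graph.nodes[cell_id]["timepoint"]

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            (a, c, self.timepoint_of(a), self.timepoint_of(c)) for a, c in self.edges
        ]
        return pd.DataFrame(
            rows, columns=["ancestor", "child", "ancestor_timepoint", "child_timepoint"]
        )

    def to_newick(self) -> list[str]:
        """One Newick string per root (earliest-timepoint tree component)."""
        roots = sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

        def render(node: str) -> str:
            children = sorted(self.graph.successors(node))
            if not children:
                return node
            return "(" + ",".join(render(c) for c in children) + ")" + node

        return [render(r) + ";" for r in roots if self.graph.out_degree(r) > 0]


def build_forest(
    assignments: list[AncestryAssignment],
    timepoint_order: list[str],
    fingerprints: list[CellFingerprint] | None = None,
) -> LineageForest:
    """Union per-pair assignments into one forest; unassigned cells stay isolated."""
    if len(set(timepoint_order)) != len(timepoint_order):
        raise ValueError("timepoints must be unique")
    forest = LineageForest(timepoint_order=list(timepoint_order))
    if fingerprints:
        for fp in fingerprints:
            forest.add_node(fp.cell_id, fp.timepoint, n_barcodes=len(fp.barcodes))
    for assignment in assignments:
        for child, record in sorted(assignment.records.items()):
            if child not in forest.graph:
                forest.add_node(child, assignment.later_timepoint)
            if record.ancestor is None:
                continue
            if record.ancestor not in forest.graph:
                forest.add_node(record.ancestor, assignment.earlier_timepoint)
            forest.add_edge(record.ancestor, child)
    return forest


def similarity_decay(
    assignments: list[AncestryAssignment],
    timepoint_order: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Export per-assigned-pair similarity records and per-gap summaries.

    Returns (records, summary): records holds one row per assigned pair
    sorted by (later timepoint, child); summary gives mean/median
    Jaccard and containment per timepoint pair.
    """
    rows = []
    for assignment in assignments:
        for child, r in sorted(assignment.assigned.items()):
            rows.append(
                (
                    assignment.earlier_timepoint,
                    assignment.later_timepoint,
                    child,
                    r.ancestor,
                    r.shared,
                    r.jaccard,
                    r.containment,
                    r.size_ancestor,
                    r.size_child,
                )
            )
    records = pd.DataFrame(
        rows,
        columns=[
            "earlier_timepoint",
            "later_timepoint",
            "child",
            "ancestor",
            "shared",
            "jaccard",
            "containment",
            "size_ancestor",
            "size_child",
        ],
    )
    if records.empty:
        summary = pd.DataFrame(
            columns=[
                "earlier_timepoint",
                "later_timepoint",
                "n_pairs",
                "mean_jaccard",
                "median_jaccard",
                "mean_containment",
            ]
        )
        return records, summary
    grouped = records.groupby(["earlier_timepoint", "later_timepoint"], sort=True)
    summary = grouped.agg(
        n_pairs=("child", "size"),
        mean_jaccard=("jaccard", "mean"),
        median_jaccard=("jaccard", "median"),
        mean_containment=("containment", "mean"),
    ).reset_index()
    return records, summary


def saturation_curve(
    table: pd.DataFrame,
    fractions: list[float],
    reps: int = 5,
    min_barcodes_per_cell: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Traced-cell count as a function of the barcode fraction analysed.

    For each fraction f, subsamples ``floor(f * U)`` of the U distinct
    barcodes (without replacement, seeded per rep) and counts cells
    still holding at least ``min_barcodes_per_cell`` barcodes; reports
    mean and sd over reps.
    """
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if list(fractions) != sorted(fractions):
        raise ValueError("fractions must be sorted ascending")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    unique = sorted(table["barcode"].unique())
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        k = int(np.floor(f * len(unique)))
        traced = []
        for _ in range(reps):
            if k == len(unique):
                kept = set(unique)
            else:
                kept = set(rng.choice(unique, size=k, replace=False))
            sub = table[table["barcode"].isin(kept)]
            per_cell = sub.groupby("cell_id")["barcode"].nunique()
            traced.append(int((per_cell >= min_barcodes_per_cell).sum()))
        rows.append((f, float(np.mean(traced)), float(np.std(traced, ddof=0))))
    return pd.DataFrame(rows, columns=["fraction", "mean_traced_cells", "sd_traced_cells"])
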