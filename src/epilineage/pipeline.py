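"""End-to-end orchestration: simulate → extract → lineage → transitions.

Runs the full tracing workflow from one seeded configuration, writing
every stage's tabular outputs plus a manifest of content hashes so that
identical configurations are verifiably reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .extract import count_per_cell, iter_read_pairs
from .fixtures import MarkovLabeller
from .lineage import (
    LineageForest,
    assign_ancestors,
    build_forest,
    fingerprints_from_table,
    saturation_curve,
    similarity_decay,
)
from .simulate import DEFAULT_FLANK3, DEFAULT_FLANK5, SimLineage, simulate_experiment
from .transitions import (
    collapse_by_origin,
    export_chord,
    restricted_repertoire,
    transitions,
    write_repertoire,
)

log = logging.getLogger("epilineage")

# Sticky-diagonal default state dynamics for demo labels: progeny mostly
# keep the ancestor state, the rest diverge into a restricted repertoire.
DEFAULT_DEMO_CLUSTERS = ["C0", "C1", "C2", "C3"]
DEFAULT_DEMO_MATRIX = [
    [0.70, 0.15, 0.15, 0.00],
    [0.10, 0.70, 0.10, 0.10],
    [0.20, 0.00, 0.70, 0.10],
    [0.00, 0.15, 0.15, 0.70],
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _ancestor_at_generation(lineage: SimLineage, cell_id: str, generation: int) -> str:
    cell = lineage.cells[cell_id]
    while cell.generation > generation:
        cell = lineage.cells[cell.parent_id]
    return cell.cell_id


def forest_from_edge_tsv(path, timepoint_order: list[str]) -> LineageForest:
    """Rebuild a lineage forest from its edge-list TSV."""
    df = pd.read_csv(path, sep="\t")
    forest = LineageForest(timepoint_order=list(timepoint_order))
    for _, row in df.iterrows():
        for cell, tp in (
            (row["ancestor"], row["ancestor_timepoint"]),
            (row["child"], row["child_timepoint"]),
        ):
            if cell not in forest.graph:
                forest.add_node(cell, tp)
        forest.add_edge(row["ancestor"], row["child"])
    return forest


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the output manifest.

    Re-running with an identical configuration reproduces identical
    output bytes (and therefore identical manifest hashes).
    """
    report = config.validate()
    if not report.valid:
        raise ValueError("invalid configuration: " + "; ".join(report.errors))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name):
        log.info("stage %s", name)

    # --- simulate -----------------------------------------------------
    stage("simulate")
    sim_config = config.sim_config()
    lineage, observations, sampled_generation, batch = simulate_experiment(
        sim_config, config.n_generations, list(config.sample_generations)
    )
    gen_to_tp = dict(zip(config.sample_generations, config.timepoints))
    r1 = out_dir / "reads_R1.fastq.gz"
    r2 = out_dir / "reads_R2.fastq.gz"
    batch.write_fastq(r1, r2)
    outputs["reads_R1.fastq.gz"], outputs["reads_R2.fastq.gz"] = r1, r2
    truth_reads = out_dir / "truth_reads.tsv"
    batch.truth.to_csv(truth_reads, sep="\t", index=False)
    outputs["truth_reads.tsv"] = truth_reads
    truth_tree = out_dir / "truth_tree.tsv"
    lineage.edge_frame().to_csv(truth_tree, sep="\t", index=False)
    outputs["truth_tree.tsv"] = truth_tree
    cells_tsv = out_dir / "cells.tsv"
    cell_rows = [
        (
            cid,
            batch.cell_barcodes[cid],
            gen_to_tp[sampled_generation[cid]],
            sampled_generation[cid],
        )
        for cid in sorted(observations)
    ]
    pd.DataFrame(
        cell_rows, columns=["sim_cell_id", "cell_id", "timepoint", "generation"]
    ).to_csv(cells_tsv, sep="\t", index=False)
    outputs["cells.tsv"] = cells_tsv
    whitelist_path = out_dir / "whitelist.txt"
    whitelist = sorted(batch.cell_barcodes.values())
    whitelist_path.write_text("\n".join(whitelist) + "\n")
    outputs["whitelist.txt"] = whitelist_path

    # --- extract ------------------------------------------------------
    stage("extract")
    ex = config.extract
    table, summary = count_per_cell(
        iter_read_pairs(r1, r2),
        whitelist,
        flank5=ex.get("flank5", DEFAULT_FLANK5),
        flank3=ex.get("flank3", DEFAULT_FLANK3),
        max_flank_mismatch=ex.get("max_flank_mismatch", 1),
        max_spacer_mismatch=ex.get("max_spacer_mismatch", 0),
        min_umi=ex.get("min_umi", 1),
        umi_hamming=ex.get("umi_hamming", 1),
        barcode_hamming=ex.get("barcode_hamming", 0),
    )
    table_path = out_dir / "cell_barcode_table.tsv"
    table.to_csv(table_path, sep="\t", index=False)
    outputs["cell_barcode_table.tsv"] = table_path
    summary_path = out_dir / "extraction_summary.json"
    summary.write_json(summary_path)
    outputs["extraction_summary.json"] = summary_path

    # --- lineage ------------------------------------------------------
    stage("lineage")
    droplet_tp = {
        batch.cell_barcodes[cid]: gen_to_tp[gen]
        for cid, gen in sampled_generation.items()
    }
    fingerprints = fingerprints_from_table(table, droplet_tp)
    by_tp = {
        tp: [f for f in fingerprints if f.timepoint == tp] for tp in config.timepoints
    }
    ln = config.lineage
    assignments = []
    for tp_e, tp_l in zip(config.timepoints, config.timepoints[1:]):
        if by_tp[tp_e] and by_tp[tp_l]:
            assignments.append(
                assign_ancestors(
                    by_tp[tp_e],
                    by_tp[tp_l],
                    min_shared=ln.get("min_shared", 3),
                    min_margin=ln.get("min_margin", 1),
                )
            )
    forest = build_forest(assignments, list(config.timepoints), fingerprints)
    assignment_path = out_dir / "assignments.tsv"
    if assignments:
        assignment_frame = pd.concat(
            [a.to_frame() for a in assignments], ignore_index=True
        )
    else:
        assignment_frame = pd.DataFrame(
            columns=["child", "ancestor", "shared", "jaccard", "containment", "margin", "status"]
        )
    assignment_frame.to_csv(assignment_path, sep="\t", index=False)
    outputs["assignments.tsv"] = assignment_path
    forest_path = out_dir / "forest_edges.tsv"
    forest.edge_frame().to_csv(forest_path, sep="\t", index=False)
    outputs["forest_edges.tsv"] = forest_path
    decay_records, decay_summary = similarity_decay(assignments)
    decay_path = out_dir / "similarity_decay.tsv"
    decay_records.to_csv(decay_path, sep="\t", index=False, float_format="%.10g")
    outputs["similarity_decay.tsv"] = decay_path
    decay_summary_path = out_dir / "similarity_decay_summary.tsv"
    decay_summary.to_csv(decay_summary_path, sep="\t", index=False, float_format="%.10g")
    outputs["similarity_decay_summary.tsv"] = decay_summary_path
    saturation = saturation_curve(
        table,
        fractions=ln.get("saturation_fractions", [0.25, 0.5, 0.75, 1.0]),
        reps=ln.get("saturation_reps", 3),
        min_barcodes_per_cell=ln.get("min_barcodes_per_cell", 1),
        seed=config.stage_seed(4),
    )
    saturation_path = out_dir / "saturation.tsv"
    saturation.to_csv(saturation_path, sep="\t", index=False, float_format="%.10g")
    outputs["saturation.tsv"] = saturation_path

    # --- transitions --------------------------------------------------
    stage("transitions")
    tr = config.transitions
    markov = tr.get("markov_labels", {})
    labeller = MarkovLabeller(
        clusters=markov.get("clusters", DEFAULT_DEMO_CLUSTERS),
        matrix=np.asarray(markov.get("matrix", DEFAULT_DEMO_MATRIX)),
        seed=config.stage_seed(5),
    )
    origin_gen = config.sample_generations[0]
    origin_cells = [
        batch.cell_barcodes[cid]
        for cid, gen in sampled_generation.items()
        if gen == origin_gen
    ]
    descendant_ancestor = {
        batch.cell_barcodes[cid]: batch.cell_barcodes[
            _ancestor_at_generation(lineage, cid, origin_gen)
        ]
        for cid, gen in sampled_generation.items()
        if gen != origin_gen
    }
    labels = labeller.label(origin_cells, descendant_ancestor)
    labels_path = out_dir / "cluster_labels.tsv"
    pd.DataFrame(
        [(c, labels[c], droplet_tp[c]) for c in sorted(labels)],
        columns=["cell_id", "cluster", "timepoint"],
    ).to_csv(labels_path, sep="\t", index=False)
    outputs["cluster_labels.tsv"] = labels_path
    for tp_e, tp_l in zip(config.timepoints, config.timepoints[1:]):
        matrix = transitions(forest, labels, tp_e, tp_l, clusters=labeller.clusters)
        tag = f"{tp_e}_{tp_l}"
        matrix_path = out_dir / f"transition_matrix_{tag}.tsv"
        matrix.write_tsv(matrix_path)
        outputs[matrix_path.name] = matrix_path
        chord = collapse_by_origin(matrix)
        chord_path = out_dir / f"chord_{tag}.tsv"
        export_chord(chord, chord_path)
        outputs[chord_path.name] = chord_path
        repertoire = restricted_repertoire(matrix, min_count=tr.get("min_count", 1))
        repertoire_path = out_dir / f"repertoire_{tag}.json"
        write_repertoire(repertoire, repertoire_path)
        outputs[repertoire_path.name] = repertoire_path

    # --- manifest -----------------------------------------------------
    stage("manifest")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "timepoints": list(config.timepoints),
            "sample_generations": list(config.sample_generations),
            "n_generations": config.n_generations,
            "sim": dict(config.sim),
            "extract": dict(config.extract),
            "lineage": dict(config.lineage),
            "transitions": {k: v for k, v in config.transitions.items()},
        },
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
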