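"""Generative simulator of episome inheritance and barcoded sequencing reads.

Models the life cycle of barcoded episomes in a dividing cell population:

* founders are transfected with a set of uniquely barcoded single-copy
  episomes drawn uniformly from the 4**12 barcode space;
* each cell cycle, every episome copy may duplicate (scheduled
  replication, Bernoulli per copy with probability ``r``) and is then
  partitioned independently to one of the two daughters with
  probability 1/2 — the random inheritance that drives barcode decay;
* an initial high-loss phase (Phase I) destroys copies outright with an
  extra per-cycle probability before the process stabilises (Phase II);
* at sequencing time each distinct barcode in a cell is captured with
  probability ``capture_efficiency`` and, if captured, yields a
  zero-truncated-Poisson number of UMIs, which are serialised as
  paired-end reads (read 1 = 16-nt cell barcode + 12-nt UMI, read 2 =
  flank + template instance + flank) with uniform per-base substitution
  errors.

Every stochastic operation takes an explicit ``numpy.random.Generator``
so full runs are reproducible from a single seed, and the complete
ground-truth division tree is retained for downstream validation.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .barcode import (
    ALPHABET,
    BARCODE_LENGTH,
    DEFAULT_TEMPLATE,
    BarcodeTemplate,
    random_distinct_seqs,
    random_seqs,
)

CELL_BARCODE_LENGTH = 16
UMI_LENGTH = 12
READ1_LENGTH = CELL_BARCODE_LENGTH + UMI_LENGTH  # 28 nt, 10x v3.1 geometry
READ2_LENGTH = 90

# Arbitrary fixed amplicon context so that flank5 + template + flank3 = 90 nt.
DEFAULT_FLANK5 = "ACTGAGCTAGCTACGATCGATTACGCGTAGCTAGGT"
DEFAULT_FLANK3 = "CCGATCGTTAGCATCGATCCATGGATCGTTACGCAT"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated tracing experiment.

    Attributes
    ----------
    n_founders
        Number of independently barcoded founder cells (generation 0).
    episomes_per_founder
        Single-copy episomes transfected into each founder.
    replication_prob
        Per-copy probability of duplication each cell cycle (``r``).
        Kept below 1 by default so partitioning loss dominates and the
        distinct-barcode count decays along lineages.
    phase1_generations
        Number of initial generations with elevated outright copy loss.
    phase1_loss_prob
        Per-copy destruction probability per cycle during Phase I.
    capture_efficiency
        Probability a distinct barcode present in a cell is observed at
        sequencing (the dropout parameter).
    reads_per_cell
        Target sequencing depth per cell; at least one read is emitted
        per captured UMI, extra reads are duplicates.
    sequencing_error_rate
        Per-base substitution probability applied to emitted reads.
    umi_mean
        Poisson rate of the zero-truncated per-barcode UMI count model.
    seed
        Mandatory base seed for all randomness in the run.
    """

    n_founders: int = 4
    episomes_per_founder: int = 30
    replication_prob: float = 0.2
    phase1_generations: int = 0
    phase1_loss_prob: float = 0.0
    capture_efficiency: float = 1.0
    reads_per_cell: int = 200
    sequencing_error_rate: float = 0.0
    umi_mean: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if self.episomes_per_founder < 1:
            raise ValueError("episomes_per_founder must be >= 1")
        if self.phase1_generations < 0:
            raise ValueError("phase1_generations must be >= 0")
        if self.reads_per_cell < 1:
            raise ValueError("reads_per_cell must be >= 1")
        if self.umi_mean <= 0:
            raise ValueError("umi_mean must be > 0")
        for name in (
            "replication_prob",
            "phase1_loss_prob",
            "capture_efficiency",
            "sequencing_error_rate",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Deterministic per-stream generator derived from the base seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass
class SimCell:
    """One simulated cell: identity, tree position and episome content."""

    cell_id: str
    generation: int
    parent_id: str | None
    episomes: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.episomes.values()):
            raise ValueError("episome copy counts must be >= 1")

    @property
    def n_copies(self) -> int:
        return sum(self.episomes.values())

    @property
    def barcode_set(self) -> frozenset[str]:
        return frozenset(self.episomes)


@dataclass
class SimLineage:
    """Ground-truth division forest of simulated cells."""

    cells: dict[str, SimCell] = field(default_factory=dict)
    edges: list[tuple[str, str]] = field(default_factory=list)
    founders: list[str] = field(default_factory=list)
    barcode_collisions: int = 0  # founder barcode draws that collided

    def add_cell(self, cell: SimCell) -> None:
        if cell.cell_id in self.cells:
            raise ValueError(f"duplicate cell_id {cell.cell_id!r}")
        if cell.parent_id is not None:
            parent = self.cells[cell.parent_id]
            if cell.generation != parent.generation + 1:
                raise ValueError("child generation must be parent generation + 1")
            self.edges.append((cell.parent_id, cell.cell_id))
        else:
            self.founders.append(cell.cell_id)
        self.cells[cell.cell_id] = cell

    def leaves(self) -> list[SimCell]:
        parents = {p for p, _ in self.edges}
        return [c for c in self.cells.values() if c.cell_id not in parents]

    def at_generation(self, generation: int) -> list[SimCell]:
        return [c for c in self.cells.values() if c.generation == generation]

    def founder_of(self, cell_id: str) -> str:
        cell = self.cells[cell_id]
        while cell.parent_id is not None:
            cell = self.cells[cell.parent_id]
        return cell.cell_id

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            (p, c, self.cells[c].generation)
            for p, c in sorted(self.edges)
        ]
        return pd.DataFrame(rows, columns=["parent_id", "child_id", "generation"])


def init_population(config: SimConfig, rng: np.random.Generator | None = None) -> SimLineage:
    """Create generation-0 founders with freshly drawn single-copy episomes.

    Barcodes are drawn uniformly (with replacement) from the 4**12
    space; a within-founder duplicate draw becomes a copy count of 2 and
    any collision is recorded on the lineage.
    """
    rng = config.rng(0) if rng is None else rng
    lineage = SimLineage()
    draws = random_seqs(rng, config.n_founders * config.episomes_per_founder, BARCODE_LENGTH)
    seen: set[str] = set()
    for i in range(config.n_founders):
        block = draws[i * config.episomes_per_founder : (i + 1) * config.episomes_per_founder]
        episomes: dict[str, int] = {}
        for bc in block:
            episomes[bc] = episomes.get(bc, 0) + 1
            if bc in seen:
                lineage.barcode_collisions += 1
            seen.add(bc)
        lineage.add_cell(SimCell(f"F{i}", 0, None, episomes))
    return lineage


def replicate_episomes(cell: SimCell, r: float, rng: np.random.Generator) -> SimCell:
    """Duplicate each episome copy independently with probability ``r``."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("replication probability must be in [0, 1]")
    if not cell.episomes:
        return replace(cell, episomes={})
    barcodes = list(cell.episomes)
    counts = np.array([cell.episomes[b] for b in barcodes], dtype=np.int64)
    new_counts = counts + rng.binomial(counts, r)
    return replace(cell, episomes=dict(zip(barcodes, new_counts.tolist())))


def divide_cell(cell: SimCell, rng: np.random.Generator) -> tuple[SimCell, SimCell]:
    """Partition every episome copy to one of two daughters with p = 1/2.

    Daughter copy counts sum to the parent's count barcode-by-barcode;
    barcodes with zero copies in a daughter are dropped from its map.
    """
    barcodes = list(cell.episomes)
    counts = np.array([cell.episomes[b] for b in barcodes], dtype=np.int64)
    to_a = rng.binomial(counts, 0.5) if len(counts) else np.array([], dtype=np.int64)
    to_b = counts - to_a
    ep_a = {b: int(n) for b, n in zip(barcodes, to_a) if n > 0}
    ep_b = {b: int(n) for b, n in zip(barcodes, to_b) if n > 0}
    gen = cell.generation + 1
    return (
        SimCell(f"{cell.cell_id}.0", gen, cell.cell_id, ep_a),
        SimCell(f"{cell.cell_id}.1", gen, cell.cell_id, ep_b),
    )


def _thin_copies(cell: SimCell, loss_prob: float, rng: np.random.Generator) -> SimCell:
    """Destroy each copy independently with probability ``loss_prob`` (Phase I)."""
    if loss_prob == 0.0 or not cell.episomes:
        return cell
    barcodes = list(cell.episomes)
    counts = np.array([cell.episomes[b] for b in barcodes], dtype=np.int64)
    surviving = rng.binomial(counts, 1.0 - loss_prob)
    return replace(
        cell, episomes={b: int(n) for b, n in zip(barcodes, surviving) if n > 0}
    )


def simulate_generations(
    lineage: SimLineage,
    n_generations: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimLineage:
    """Advance every leaf ``n_generations`` synchronous division cycles.

    Each cycle applies Phase-I loss (while the leaf's generation is
    below ``phase1_generations``), then replication, then binomial
    partitioning into two daughters.  The full truth tree is retained.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    rng = config.rng(1) if rng is None else rng
    for _ in range(n_generations):
        for cell in lineage.leaves():
            staged = cell
            if staged.generation < config.phase1_generations:
                staged = _thin_copies(staged, config.phase1_loss_prob, rng)
            staged = replicate_episomes(staged, config.replication_prob, rng)
            for daughter in divide_cell(staged, rng):
                lineage.add_cell(daughter)
    return lineage


def _zero_truncated_poisson(
    rng: np.random.Generator, mean: float, size: int
) -> np.ndarray:
    counts = rng.poisson(mean, size)
    zero = counts == 0
    while zero.any():
        counts[zero] = rng.poisson(mean, int(zero.sum()))
        zero = counts == 0
    return counts


def sample_observation(
    cell: SimCell, config: SimConfig, rng: np.random.Generator
) -> dict[str, int]:
    """Observe a cell's fingerprint through capture and UMI counting.

    Each distinct barcode is seen with probability ``capture_efficiency``
    and an observed barcode receives a zero-truncated Poisson
    (rate ``umi_mean``) UMI count.
    """
    if not 0.0 < config.capture_efficiency <= 1.0:
        raise ValueError("capture_efficiency must be in (0, 1] for observation")
    barcodes = sorted(cell.episomes)
    if not barcodes:
        return {}
    captured = rng.random(len(barcodes)) < config.capture_efficiency
    kept = [b for b, keep in zip(barcodes, captured) if keep]
    if not kept:
        return {}
    umis = _zero_truncated_poisson(rng, config.umi_mean, len(kept))
    return dict(zip(kept, umis.tolist()))


@dataclass
class ReadBatch:
    """Emitted paired-end reads plus the per-read provenance (truth) table."""

    read_ids: list[str]
    read1: list[str]
    read2: list[str]
    qual1: list[str]
    qual2: list[str]
    truth: pd.DataFrame  # columns: read_id, cell_id, barcode, umi
    cell_barcodes: dict[str, str]  # cell_id -> 16-nt droplet barcode

    def __len__(self) -> int:
        return len(self.read_ids)

    def write_fastq(self, r1_path, r2_path) -> None:
        """Write the pair as deterministic gzipped FASTQ (mtime pinned to 0)."""
        for path, seqs, quals in (
            (r1_path, self.read1, self.qual1),
            (r2_path, self.read2, self.qual2),
        ):
            with open(path, "wb") as raw, gzip.GzipFile(
                filename="", mode="wb", fileobj=raw, mtime=0
            ) as gz:
                for rid, seq, qual in zip(self.read_ids, seqs, quals):
                    gz.write(f"@{rid}\n{seq}\n+\n{qual}\n".encode())


def _inject_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0.0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in ALPHABET if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def emit_fastq(
    observations: dict[str, dict[str, int]],
    config: SimConfig,
    rng: np.random.Generator,
    template: BarcodeTemplate = DEFAULT_TEMPLATE,
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
    cell_barcodes: dict[str, str] | None = None,
) -> ReadBatch:
    """Serialise observed fingerprints as paired-end reads with a truth table.

    One read is guaranteed per (cell, barcode, UMI) molecule; if
    ``reads_per_cell`` exceeds a cell's molecule count the remainder are
    duplicate reads of uniformly chosen molecules.  Substitution errors
    are injected at ``sequencing_error_rate`` per base on both mates.
    """
    for name, flank in (("flank5", flank5), ("flank3", flank3)):
        if not flank:
            raise ValueError(f"{name} must be non-empty")
        if set(flank) - set(ALPHABET):
            raise ValueError(f"{name} must contain only ACGT characters")

    cell_ids = list(observations)
    if cell_barcodes is None:
        cbs = random_distinct_seqs(rng, len(cell_ids), CELL_BARCODE_LENGTH)
        cell_barcodes = dict(zip(cell_ids, cbs))

    read_ids: list[str] = []
    read1: list[str] = []
    read2: list[str] = []
    truth_rows: list[tuple[str, str, str, str]] = []
    serial = 0
    for cell_id in cell_ids:
        fingerprint = observations[cell_id]
        molecules: list[tuple[str, str]] = []  # (barcode, umi)
        for bc in sorted(fingerprint):
            n_umis = fingerprint[bc]
            for umi in random_distinct_seqs(rng, n_umis, UMI_LENGTH):
                molecules.append((bc, umi))
        if not molecules:
            continue
        extra = max(0, config.reads_per_cell - len(molecules))
        order = list(range(len(molecules)))
        if extra:
            order += rng.integers(0, len(molecules), size=extra).tolist()
        cb = cell_barcodes[cell_id]
        for idx in order:
            bc, umi = molecules[idx]
            rid = f"read{serial}"
            serial += 1
            r1 = _inject_errors(cb + umi, config.sequencing_error_rate, rng)
            r2 = _inject_errors(
                flank5 + template.instantiate(bc) + flank3,
                config.sequencing_error_rate,
                rng,
            )
            read_ids.append(rid)
            read1.append(r1)
            read2.append(r2)
            truth_rows.append((rid, cell_id, bc, umi))

    truth = pd.DataFrame(truth_rows, columns=["read_id", "cell_id", "barcode", "umi"])
    return ReadBatch(
        read_ids=read_ids,
        read1=read1,
        read2=read2,
        qual1=["I" * len(s) for s in read1],
        qual2=["I" * len(s) for s in read2],
        truth=truth,
        cell_barcodes=cell_barcodes,
    )


def simulate_experiment(
    config: SimConfig,
    n_generations: int,
    sample_generations: list[int] | None = None,
    template: BarcodeTemplate = DEFAULT_TEMPLATE,
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
) -> tuple[SimLineage, dict[str, dict[str, int]], dict[str, int], ReadBatch]:
    """Run a full simulation: grow, observe sampled generations, emit reads.

    Returns the truth lineage, the observed fingerprints per cell, the
    cell→generation sampling map, and the emitted read batch.
    """
    if sample_generations is None:
        sample_generations = [n_generations]
    if any(g < 0 or g > n_generations for g in sample_generations):
        raise ValueError("sample_generations must lie within [0, n_generations]")
    lineage = init_population(config, config.rng(0))
    simulate_generations(lineage, n_generations, config, config.rng(1))
    obs_rng = config.rng(2)
    observations: dict[str, dict[str, int]] = {}
    sampled_generation: dict[str, int] = {}
    for gen in sample_generations:
        for cell in sorted(lineage.at_generation(gen), key=lambda c: c.cell_id):
            observations[cell.cell_id] = sample_observation(cell, config, obs_rng)
            sampled_generation[cell.cell_id] = gen
    batch = emit_fastq(
        observations, config, config.rng(3), template=template, flank5=flank5, flank3=flank3
    )
    return lineage, observations, sampled_generation, batch
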