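"""Lineage-barcode extraction from paired-end reads.

Read 1 carries the 16-nt droplet cell barcode and 12-nt UMI; read 2
carries the barcoded amplicon.  Extraction removes the flanking
sequences (substitution-tolerant sliding-window match), reads the
barcode off the degenerate template, rescues cell barcodes against a
whitelist at Hamming distance 1, deduplicates UMIs with a directional
collapse, and emits per-cell (cell, barcode, umi_count) tables plus a
run summary that partitions every input read into exactly one category.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .barcode import ALPHABET, BarcodeTemplate, DEFAULT_TEMPLATE, hamming
from .simulate import CELL_BARCODE_LENGTH, READ1_LENGTH, ReadBatch, UMI_LENGTH


def find_flank(sequence: str, flank: str, max_mismatch: int, start: int = 0) -> int | None:
    """Leftmost position of the best (fewest-substitution) flank match.

    Scans every window of ``len(flank)`` from ``start``; returns the
    position of the window with the fewest mismatches provided it is
    ``<= max_mismatch``, preferring the leftmost on ties; None otherwise.
    """
    best_pos: int | None = None
    best_mm = max_mismatch + 1
    for pos in range(start, len(sequence) - len(flank) + 1):
        mm = 0
        window = sequence[pos : pos + len(flank)]
        for a, b in zip(window, flank):
            if a != b:
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_mm = mm
            best_pos = pos
            if mm == 0:
                break
    return best_pos if best_mm <= max_mismatch else None


def trim_flanks(
    read2_sequence: str, flank5: str, flank3: str, max_mismatch: int = 1
) -> str | None:
    """Return the candidate barcode region between the two flanks, or None."""
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    p5 = find_flank(read2_sequence, flank5, max_mismatch)
    if p5 is None:
        return None
    region_start = p5 + len(flank5)
    p3 = find_flank(read2_sequence, flank3, max_mismatch, start=region_start)
    if p3 is None:
        return None
    return read2_sequence[region_start:p3]


def match_template(
    candidate: str,
    template: BarcodeTemplate = DEFAULT_TEMPLATE,
    max_spacer_mismatch: int = 0,
) -> str | None:
    """Read the lineage barcode off a template-length candidate region.

    Requires the candidate to have template length, the fixed spacer
    positions to match with at most ``max_spacer_mismatch`` total
    substitutions, and every degenerate position to be A/C/G/T; returns
    the concatenated degenerate positions (the 12-nt barcode) or None.
    """
    if max_spacer_mismatch < 0:
        raise ValueError("max_spacer_mismatch must be >= 0")
    if len(candidate) != len(template):
        return None
    mismatches = sum(
        1 for pos in template.spacer_positions if candidate[pos] != template.pattern[pos]
    )
    if mismatches > max_spacer_mismatch:
        return None
    barcode = "".join(candidate[pos] for pos in template.random_positions)
    if set(barcode) - set(ALPHABET):
        return None
    return barcode


def collapse_barcodes(counts: dict[str, int], max_hamming: int = 1) -> dict[str, int]:
    """Directional error collapse of a barcode count map.

    Barcodes are processed in (count descending, sequence ascending)
    order; a barcode ``b`` is absorbed into an already-kept neighbour
    ``a`` when ``hamming(a, b) <= max_hamming`` and
    ``count(a) >= 2 * count(b) - 1`` (counts as originally observed).
    Total counts are conserved and the distinct-barcode count never
    increases.
    """
    if max_hamming not in (0, 1):
        raise ValueError("max_hamming must be 0 or 1")
    if max_hamming == 0:
        return dict(counts)
    order = sorted(counts, key=lambda b: (-counts[b], b))
    collapsed: dict[str, int] = {}
    for b in order:
        absorber = None
        for a in collapsed:
            if counts[a] >= 2 * counts[b] - 1 and hamming(a, b) <= max_hamming:
                absorber = a
                break  # kept order is (count desc, seq asc): first hit is best
        if absorber is None:
            collapsed[b] = counts[b]
        else:
            collapsed[absorber] += counts[b]
    return collapsed


def _whitelist_lookup(whitelist: Iterable[str]) -> dict[str, str | None]:
    """Map observed cell barcodes to whitelist entries with 1-mismatch rescue.

    Exact entries map to themselves; a Hamming-1 neighbour of exactly
    one whitelist entry maps to that entry; a neighbour of several maps
    to None (ambiguous rescue drops the read).
    """
    exact = set(whitelist)
    lookup: dict[str, str | None] = {wl: wl for wl in exact}
    for wl in sorted(exact):
        for pos in range(len(wl)):
            for base in ALPHABET:
                if base == wl[pos]:
                    continue
                neighbour = wl[:pos] + base + wl[pos + 1 :]
                if neighbour in exact:
                    continue
                if neighbour in lookup and lookup[neighbour] != wl:
                    lookup[neighbour] = None
                else:
                    lookup[neighbour] = wl
    return lookup


def iter_read_pairs(r1_path, r2_path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, read1_seq, read2_seq) from (optionally gzipped) FASTQ."""

    def _open(path):
        path = Path(path)
        if path.suffix == ".gz":
            return gzip.open(path, "rt")
        return open(path)

    with _open(r1_path) as h1, _open(r2_path) as h2:
        for (t1, s1, _q1), (_t2, s2, _q2) in zip(
            FastqGeneralIterator(h1), FastqGeneralIterator(h2)
        ):
            yield t1.split()[0], s1, s2


@dataclass
class ExtractionSummary:
    """Per-category read tally; categories partition the input exactly."""

    total: int = 0
    assigned: int = 0
    off_whitelist: int = 0
    unmatched_flank: int = 0
    unmatched_template: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "assigned": self.assigned,
            "off_whitelist": self.off_whitelist,
            "unmatched_flank": self.unmatched_flank,
            "unmatched_template": self.unmatched_template,
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


def count_per_cell(
    reads: ReadBatch | Iterable[tuple[str, str, str]],
    whitelist: Iterable[str],
    template: BarcodeTemplate = DEFAULT_TEMPLATE,
    flank5: str | None = None,
    flank3: str | None = None,
    max_flank_mismatch: int = 1,
    max_spacer_mismatch: int = 0,
    min_umi: int = 1,
    umi_hamming: int = 1,
    barcode_hamming: int = 0,
) -> tuple[pd.DataFrame, ExtractionSummary]:
    """Build the per-cell barcode table from paired reads.

    Returns a DataFrame with columns (cell_id, barcode, umi_count),
    sorted by (cell_id, barcode), plus the read-category summary.
    ``cell_id`` is the (possibly rescued) whitelist cell barcode.
    """
    from .simulate import DEFAULT_FLANK5, DEFAULT_FLANK3

    whitelist = list(whitelist)
    if not whitelist:
        raise ValueError("whitelist must be non-empty")
    flank5 = DEFAULT_FLANK5 if flank5 is None else flank5
    flank3 = DEFAULT_FLANK3 if flank3 is None else flank3

    if isinstance(reads, ReadBatch):
        pairs: Iterable[tuple[str, str, str]] = zip(reads.read_ids, reads.read1, reads.read2)
    else:
        pairs = reads

    lookup = _whitelist_lookup(whitelist)
    summary = ExtractionSummary()
    # (cell, lineage barcode) -> raw UMI -> read count
    umi_counts: dict[tuple[str, str], dict[str, int]] = {}
    for _rid, r1, r2 in pairs:
        summary.total += 1
        cb = r1[:CELL_BARCODE_LENGTH]
        umi = r1[CELL_BARCODE_LENGTH:READ1_LENGTH]
        cell = lookup.get(cb)
        if cell is None:
            summary.off_whitelist += 1
            continue
        region = trim_flanks(r2, flank5, flank3, max_flank_mismatch)
        if region is None:
            summary.unmatched_flank += 1
            continue
        barcode = match_template(region, template, max_spacer_mismatch)
        if barcode is None or len(umi) != UMI_LENGTH:
            summary.unmatched_template += 1
            continue
        summary.assigned += 1
        bucket = umi_counts.setdefault((cell, barcode), {})
        bucket[umi] = bucket.get(umi, 0) + 1

    per_cell: dict[str, dict[str, int]] = {}
    for (cell, barcode), bucket in umi_counts.items():
        n_umis = len(collapse_barcodes(bucket, umi_hamming))
        per_cell.setdefault(cell, {})[barcode] = n_umis

    rows: list[tuple[str, str, int]] = []
    for cell in sorted(per_cell):
        counts = per_cell[cell]
        if barcode_hamming:
            counts = collapse_barcodes(counts, barcode_hamming)
        for barcode in sorted(counts):
            if counts[barcode] >= min_umi:
                rows.append((cell, barcode, counts[barcode]))
    table = pd.DataFrame(rows, columns=["cell_id", "barcode", "umi_count"])
    return table, summary


def assign_variant(
    table: pd.DataFrame,
    variant_map: dict[str, str],
    min_fraction: float = 0.8,
) -> dict[str, str]:
    """Demultiplex cells onto variants by their variant-barcode UMI share.

    A cell is assigned the variant whose barcode holds at least
    ``min_fraction`` of the cell's UMIs over variant-map barcodes;
    cells with variant barcodes but no winner are "ambiguous", cells
    with none are "unassigned".
    """
    if not variant_map:
        raise ValueError("variant map must be non-empty")
    out: dict[str, str] = {}
    for cell, group in table.groupby("cell_id", sort=True):
        hits = group[group["barcode"].isin(variant_map)]
        if hits.empty:
            out[cell] = "unassigned"
            continue
        shares = hits.groupby(hits["barcode"].map(variant_map))["umi_count"].sum()
        shares = shares / shares.sum()
        best = shares.sort_values(ascending=False)
        if best.iloc[0] >= min_fraction:
            out[cell] = best.index[0]
        else:
            out[cell] = "ambiguous"
    return out


def bulk_unique_barcodes(
    barcodes: Iterable[str],
    normalize_to_reads: int,
    seed: int,
) -> tuple[int, int, bool]:
    """Distinct barcodes per fixed sequencing depth (seeded subsampling).

    Subsamples the barcode stream without replacement to exactly
    ``normalize_to_reads`` when deeper, else uses all reads and flags
    the shortfall.  Returns (unique_barcodes, reads_used, subsampled).
    """
    if normalize_to_reads < 1:
        raise ValueError("normalize_to_reads must be >= 1")
    barcodes = list(barcodes)
    if len(barcodes) > normalize_to_reads:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(barcodes), size=normalize_to_reads, replace=False)
        sample = [barcodes[i] for i in idx]
        return len(set(sample)), normalize_to_reads, True
    return len(set(barcodes)), len(barcodes), False


def read_whitelist(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_variant_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "variant"])
    if df["barcode"].duplicated().any():
        raise ValueError("variant map barcodes must be unique")
    return dict(zip(df["barcode"], df["variant"]))
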