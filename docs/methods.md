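# Methods

## The inheritance model

A cell carries a multiset of episomes, each identified by a 12-nt
barcode drawn from the 4¹² space defined by the degenerate template
`NNNNGCGNNNNTGANNNN`.  One synchronous cell cycle applies, in order:

1. **Phase-I loss** (only while the cell's generation is below
   `phase1_generations`): each copy is destroyed independently with
   probability `phase1_loss_prob`.  This models the rapid episome
   loss seen in the first days after transfection, before retention
   stabilises; the stabilised regime (Phase II) is simply the plain
   replicate/partition process.
2. **Scheduled replication**: each surviving copy duplicates
   independently with probability `r` (`replication_prob`).  EBNA1/OriP
   episomes replicate at most once per cycle, so a Bernoulli per copy
   is the simplest faithful model; the default `r = 0.2` keeps
   replication below the loss rate so the distinct-barcode count
   decays, matching the observed dominance of decay over replication.
3. **Random partitioning**: each copy moves to daughter A or B
   independently with probability ½.  Copy counts are conserved
   barcode-by-barcode; a barcode absent from a daughter is lost to
   that sub-lineage forever (no horizontal transfer, no re-gain).

For a single-copy barcode with `r = 0` the survival probability to
depth *d* is exactly 2⁻ᵈ, giving the halving law E[unique] = N₀·2⁻ᵈ
used as a closed-form oracle; with replication the per-cycle factor is
(1 + r)/2 in expectation.  With `r = 1` survival follows the branching
chain c → Binomial(2c, ½), which the tests enumerate exhaustively as
an independent oracle — even full replication does not guarantee
retention, because both post-replication copies can segregate away.

All divisions are generation-synchronous.  Cell-cycle heterogeneity,
asymmetric partitioning, cGAS/STING-mediated degradation and promoter
silencing are not modelled; the process treats net decay empirically.

### Default simulation parameters

| parameter | default | meaning |
|---|---|---|
| `episomes_per_founder` | 30 | initial episomes per transfected cell; not directly measured in the assay this emulates, chosen as a realistic transfection copy number |
| `replication_prob` r | 0.2 | per-copy duplication probability per cycle; keeps decay dominant |
| `phase1_generations` / `phase1_loss_prob` | 0 / 0.0 | elevated early loss; off by default because tracing experiments start in the stabilised phase |
| `capture_efficiency` | 1.0 | probability a present barcode yields ≥1 molecule at sequencing |
| `umi_mean` | 4.0 | rate of the zero-truncated Poisson UMI count per captured barcode |
| `reads_per_cell` | 200 | target depth; ≥1 read per molecule is guaranteed, extras are duplicates |
| `sequencing_error_rate` | 0.0 | uniform per-base substitution probability on both mates |

The read geometry is fixed at R1 = 16-nt cell barcode + 12-nt UMI
(28 cycles) and R2 = 90 nt (36-nt flank + 18-nt template instance +
36-nt flank), the droplet v3.1 layout.  UMIs are drawn distinct within
a (cell, barcode) molecule set so that UMI counts are exact ground
truth; duplicate reads are sampled uniformly from a cell's molecules
so deduplication is exercised without breaking losslessness.

## What the simulator does and does not emulate

It reproduces the statistical structure the downstream method relies
on: combinatorial fingerprints, subset decay along lineages, capture
dropout, UMI duplication and substitution errors.  It does not emulate
amplicon indels, chimeric reads, PCR jackpotting, barcode-dependent
amplification bias, ambient barcodes or doublets.  Passing tests
therefore validate the pipeline's logic and its statistical behaviour
under the assumed error model, not robustness to every artefact of
real libraries.

## Extraction

Flank matching is a sliding-window Hamming scan (substitutions only,
leftmost best window wins); indel-tolerant alignment is out of scope
and unnecessary under the substitution error model.  Spacer mismatch
tolerance defaults to 0 because the `GCG`/`TGA` spacers are short and
tolerance risks conflating distinct barcodes.  Cell barcodes are
rescued against the whitelist at Hamming 1 only when the rescue is
unambiguous.  UMI deduplication and optional barcode collapse share
one directional algorithm: processing in (count desc, sequence asc)
order, `b` is absorbed into a kept neighbour `a` when
`Hamming(a,b) ≤ 1` and `count(a) ≥ 2·count(b) − 1`; counts are
conserved and the procedure is deterministic.  `min_umi` defaults to 1
to preserve sensitivity — stringency belongs to the lineage stage.
Depth normalisation for bulk unique-barcode counts is seeded
subsampling without replacement, not linear scaling, because distinct
counts are nonlinear in depth.

## Ancestry assignment

The score ranks candidate ancestors by the shared-barcode count, the
natural statistic for subset decay; Jaccard breaks ties and the child
containment |A∩B|/|B| is reported as a diagnostic but never reorients
edges — direction comes from the declared timepoint order.  Defaults
`min_shared = 3`, `min_margin = 2` in the reference analyses: three
shared 12-nt barcodes are essentially impossible by chance
(P ≈ (n/4¹²)·shared for any realistic barcode budget), and the margin
guards against splits where two related ancestors both overlap the
child.  Exact ties yield no assignment: a false lineage edge corrupts
every downstream transition count, whereas a missing edge only costs
power.  Each child takes at most one ancestor (clonal division has a
unique parent); doublet fingerprints are not modelled.

## Transitions

Each traced edge with both endpoints cluster-labelled contributes one
(origin, destination) count — cell-pair counting, not clone-collapsed.
Edges with unlabelled endpoints are excluded and reported rather than
imputed, since labels come from an external expression pipeline.
Chord tables are row-normalised over origins with at least one traced
pair; repertoire claims use `min_count = 1` (presence/absence) by
default.  Cluster ordering is numeric-aware lexical (C2 before C10).

## Reproducibility and numerics

Every stochastic routine takes a `numpy` Generator; the pipeline
derives per-stage child seeds from the global seed via
`SeedSequence(seed, spawn_key=(stage,))`, so stages are independently
reproducible and no stream is reused.  Gzipped FASTQ is written with
`mtime=0` and no embedded filename, making full runs byte-identical.
Statistical tests use 3-standard-error bands around exact or
closed-form expectations (binomial, hypergeometric, occupancy,
branching-chain enumeration); problem sizes (e.g. 256 founders × 200
episomes for the decay law, 2,000 traced pairs for transition
recovery) were chosen so those bands are tight enough to be
informative while a full suite run stays interactive.

## Known limitations

* Replication and loss rates are not inferred from data; calibrating
  `r` and the Phase-I parameters per dataset (and hence reading
  division counts off decay rates) is future work.
* The similarity score family (shared count + Jaccard + containment)
  and its thresholds are a declared reimplementation surface validated
  by simulation, not against any external script.
* Multi-parent structures, fingerprint merging (doublets) and
  indel-aware amplicon alignment are out of scope.
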