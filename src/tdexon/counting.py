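"""Assign uniquely mapped fragments to exonic regions.

Two counting schemes per exonic region i and sample j:

* inclusion counts (lambda): fragments with at least one aligned block
  overlapping region i by >= 1 base;
* skipping counts (rho): fragments with a splice gap that fully contains
  region i while also having blocks in regions of the same gene strictly
  upstream and strictly downstream of i — the read-level evidence that a
  transcript spliced the region out.

The rest-of-gene counts (epsilon) used by the exon-usage GLM are derived
at fragment level: for region i, the fragments of the gene that do NOT
touch region i.  Paired-end mates are merged into a single fragment
before counting; a fragment whose blocks touch more than one gene group
is ambiguous and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import FlattenedGeneModel

__all__ = [
    "FragmentAlignment",
    "CountTables",
    "CountingStats",
    "count_fragments",
    "count_inclusion",
    "count_skipping",
    "build_reuc_pairs",
    "read_fragments_sam",
    "read_fragments_tsv",
    "write_fragments_tsv",
]


@dataclass(frozen=True)
class FragmentAlignment:
    """A sequenced fragment as a chain of aligned blocks.

    ``blocks`` are half-open 0-based intervals, sorted and non-overlapping;
    gaps between consecutive blocks are splice gaps.
    """

    sample_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    unique: bool = True

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("fragment must have >= 1 block")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError("fragment blocks must be sorted and disjoint")

    @property
    def gaps(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_s1, e1), (s2, _e2) in zip(self.blocks, self.blocks[1:])
        ]


@dataclass
class CountingStats:
    n_fragments: int = 0
    n_counted: int = 0
    n_nonunique: int = 0
    n_ambiguous: int = 0
    n_no_region: int = 0
    n_unknown_chrom: int = 0


@dataclass
class CountTables:
    """Per-region x per-sample count matrices.

    ``inclusion``/``skipping`` are DataFrames indexed by region key
    (``gene_id:region_id``), columns = sample ids.  ``gene_totals`` holds
    the number of distinct fragments assigned to each gene group, which
    defines the fragment-level rest-of-gene counts ``rest = gene_total -
    inclusion`` (a fragment belongs either to the lambda group of region i
    or to its epsilon group, never both).
    """

    inclusion: pd.DataFrame
    skipping: pd.DataFrame
    gene_totals: pd.DataFrame
    rest: pd.DataFrame | None = None
    stats: CountingStats = field(default_factory=CountingStats)

    @property
    def samples(self) -> list[str]:
        return list(self.inclusion.columns)

    def validate(self) -> None:
        for m in (self.inclusion, self.skipping, self.gene_totals):
            v = m.to_numpy()
            if (v < 0).any() or not np.issubdtype(v.dtype, np.integer):
                raise ValueError("count matrices must hold non-negative integers")


def _region_lookup(model: FlattenedGeneModel) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, r in enumerate(model.regions):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, idx)
    return trees


def count_fragments(
    fragments: Iterable[FragmentAlignment],
    model: FlattenedGeneModel,
    samples: list[str] | None = None,
) -> CountTables:
    """Count inclusion, skipping and per-gene fragment totals in one pass.

    Order-independent: permuting the fragment stream yields identical
    matrices.
    """
    trees = _region_lookup(model)
    regions = model.regions
    keys = model.region_keys()
    key_pos = {k: i for i, k in enumerate(keys)}
    genes = model.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}

    sample_pos: dict[str, int] = {}
    if samples is not None:
        sample_pos = {s: i for i, s in enumerate(samples)}
    incl: dict[tuple[int, int], int] = {}
    skip: dict[tuple[int, int], int] = {}
    gtot: dict[tuple[int, int], int] = {}
    stats = CountingStats()

    for frag in fragments:
        stats.n_fragments += 1
        if not frag.unique:
            stats.n_nonunique += 1
            continue
        if frag.sample_id not in sample_pos:
            if samples is not None:
                raise ValueError(f"sample {frag.sample_id!r} not in sample list")
            sample_pos[frag.sample_id] = len(sample_pos)
        j = sample_pos[frag.sample_id]
        tree = trees.get(frag.chrom)
        if tree is None:
            stats.n_unknown_chrom += 1
            continue
        hit_idx: set[int] = set()
        for s, e in frag.blocks:
            for iv in tree.overlap(s, e):
                hit_idx.add(iv.data)
        if not hit_idx:
            stats.n_no_region += 1
            continue
        hit_genes = {regions[i].gene_id for i in hit_idx}
        if len(hit_genes) > 1:
            stats.n_ambiguous += 1
            continue
        gene = hit_genes.pop()
        stats.n_counted += 1
        gtot[(gene_pos[gene], j)] = gtot.get((gene_pos[gene], j), 0) + 1
        for i in hit_idx:
            incl[(i, j)] = incl.get((i, j), 0) + 1
        # skipping: gap fully containing a region of this gene, with hit
        # regions strictly upstream and strictly downstream
        gene_regs = model.regions_of(gene)
        if len(frag.blocks) > 1 and len(gene_regs) > 2:
            hit_regions = [regions[i] for i in hit_idx]
            for gs, ge in frag.gaps:
                for r in gene_regs:
                    if r.start >= gs and r.end <= ge:
                        up = any(h.end <= r.start for h in hit_regions)
                        down = any(h.start >= r.end for h in hit_regions)
                        if up and down:
                            i = key_pos[r.key]
                            skip[(i, j)] = skip.get((i, j), 0) + 1

    ordered_samples = (
        samples if samples is not None
        else [s for s, _ in sorted(sample_pos.items(), key=lambda kv: kv[1])]
    )
    n_s = len(ordered_samples)

    def densify(d: dict[tuple[int, int], int], nrow: int) -> np.ndarray:
        m = np.zeros((nrow, n_s), dtype=np.int64)
        for (i, j), v in d.items():
            m[i, j] = v
        return m

    inclusion = pd.DataFrame(densify(incl, len(keys)), index=keys, columns=ordered_samples)
    skipping = pd.DataFrame(densify(skip, len(keys)), index=keys, columns=ordered_samples)
    gene_totals = pd.DataFrame(densify(gtot, len(genes)), index=genes, columns=ordered_samples)
    tables = CountTables(
        inclusion=inclusion, skipping=skipping, gene_totals=gene_totals, stats=stats
    )
    tables.rest = build_reuc_pairs(tables, model)
    return tables


def count_inclusion(fragments, model, samples=None) -> pd.DataFrame:
    return count_fragments(fragments, model, samples).inclusion


def count_skipping(fragments, model, samples=None) -> pd.DataFrame:
    return count_fragments(fragments, model, samples).skipping


def build_reuc_pairs(
    tables: CountTables, model: FlattenedGeneModel
) -> pd.DataFrame:
    """Rest-of-gene counts: k0[i, j] = fragments of the gene not touching i.

    Uses the fragment-level gene totals, so fragments spanning several
    regions are counted once per gene.  Single-region genes get k0 = 0
    (nothing to compare against; excluded from modelling downstream).
    """
    gene_of = pd.Series(
        [r.gene_id for r in model.regions], index=model.region_keys()
    )
    missing = set(tables.inclusion.index) - set(gene_of.index)
    if missing:
        raise ValueError(f"regions without gene assignment: {sorted(missing)[:5]}")
    totals = tables.gene_totals.loc[gene_of.loc[tables.inclusion.index]].to_numpy()
    rest = totals - tables.inclusion.to_numpy()
    if (rest < 0).any():
        raise ValueError("inclusion counts exceed gene totals")
    return pd.DataFrame(rest, index=tables.inclusion.index, columns=tables.inclusion.columns)


# ---------------------------------------------------------------------------
# Fragment I/O
# ---------------------------------------------------------------------------


def read_fragments_sam(
    path, sample_id: str, *, min_mapq: int = 0
) -> Iterator[FragmentAlignment]:
    """Read a SAM/BAM file into fragments, merging paired mates by name.

    A fragment is unique when none of its reads is secondary or
    supplementary, the NH tag (if present) equals 1, and all mapping
    qualities are >= ``min_mapq``.
    """
    import pysam

    pending: dict[str, tuple[list[tuple[int, int]], str, bool]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            unique = not (read.is_secondary or read.is_supplementary)
            if read.has_tag("NH") and read.get_tag("NH") != 1:
                unique = False
            if read.mapping_quality < min_mapq:
                unique = False
            blocks = read.get_blocks()
            chrom = read.reference_name
            if read.is_paired:
                if read.query_name in pending:
                    pblocks, pchrom, puniq = pending.pop(read.query_name)
                    if pchrom == chrom:
                        merged = _merge_blocks(pblocks + list(blocks))
                        yield FragmentAlignment(
                            sample_id, chrom, tuple(merged), puniq and unique
                        )
                    else:  # discordant pair: emit separately
                        yield FragmentAlignment(sample_id, pchrom, tuple(pblocks), puniq)
                        yield FragmentAlignment(sample_id, chrom, tuple(blocks), unique)
                else:
                    pending[read.query_name] = (list(blocks), chrom, unique)
            else:
                yield FragmentAlignment(sample_id, chrom, tuple(blocks), unique)
    for _name, (blocks, chrom, unique) in sorted(pending.items()):
        yield FragmentAlignment(sample_id, chrom, tuple(blocks), unique)


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


_TSV_COLS = ["sample", "chrom", "block_starts", "block_ends", "strand", "unique"]


def write_fragments_tsv(fragments: Iterable[FragmentAlignment], path) -> None:
    """Write fragments as 6-column TSV (block lists comma-joined, 0-based)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLS) + "\n")
        for f in fragments:
            fh.write(
                "\t".join(
                    [
                        f.sample_id,
                        f.chrom,
                        ",".join(str(s) for s, _ in f.blocks),
                        ",".join(str(e) for _, e in f.blocks),
                        "*",
                        "1" if f.unique else "0",
                    ]
                )
                + "\n"
            )


def read_fragments_tsv(path) -> Iterator[FragmentAlignment]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLS:
            raise ValueError(f"unexpected fragment TSV header: {header}")
        for line in fh:
            sample, chrom, bs, be, _strand, uniq = line.rstrip("\n").split("\t")
            starts = [int(x) for x in bs.split(",")]
            ends = [int(x) for x in be.split(",")]
            yield FragmentAlignment(
                sample, chrom, tuple(zip(starts, ends)), uniq == "1"
            )
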