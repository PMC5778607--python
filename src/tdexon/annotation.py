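"""Reduced gene models: disjoint exonic regions from transcript annotation.

Transcript annotations describe each gene as a set of (usually overlapping)
exons, one set per transcript isoform.  For counting, overlapping exons are
unusable: a read landing in the shared part of two isoform exons cannot be
assigned to either.  The standard remedy is to *flatten* each gene into
non-overlapping exonic regions: the base-level union of all its exons, cut
at every exon boundary that occurs in any transcript.  Each resulting region
is then either fully inside or fully outside every annotated transcript, so
fragments can be assigned unambiguously.

Genes whose exon unions overlap on the same strand are merged into a single
aggregate gene group (reads in the shared span cannot be attributed to one
gene); alternatively they can be dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "ExonicRegion",
    "FlattenedGeneModel",
    "flatten_gene_models",
    "read_gtf_exons",
    "write_flattened_gff",
    "read_flattened_gff",
]


class AnnotationError(ValueError):
    """Malformed annotation input."""


_VALID_STRANDS = {"+", "-", "*"}


@dataclass(frozen=True)
class ExonicRegion:
    """One disjoint exonic region of a (possibly aggregate) gene.

    Coordinates are half-open 0-based internally; GTF/GFF I/O converts
    to and from 1-based inclusive.
    """

    region_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"region {self.region_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in _VALID_STRANDS:
            raise AnnotationError(f"unknown strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> str:
        """Globally unique identifier, ``gene_id:region_id``."""
        return f"{self.gene_id}:{self.region_id}"


@dataclass
class FlattenedGeneModel:
    """Ordered collection of disjoint exonic regions grouped by gene.

    ``aggregate_map`` maps every original gene_id to the id of the
    (possibly merged) gene group its regions belong to.
    """

    regions: list[ExonicRegion] = field(default_factory=list)
    aggregate_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[str, list[ExonicRegion]] = {}
        for r in self.regions:
            self._index.setdefault(r.gene_id, []).append(r)
        for gid, regs in self._index.items():
            regs.sort(key=lambda r: (r.chrom, r.start))
            for a, b in zip(regs, regs[1:]):
                if b.start < a.end and a.chrom == b.chrom:
                    raise AnnotationError(f"gene {gid}: overlapping regions")

    @property
    def gene_index(self) -> dict[str, list[ExonicRegion]]:
        return self._index

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self._index)

    def regions_of(self, gene_id: str) -> list[ExonicRegion]:
        return self._index[gene_id]

    def region_keys(self) -> list[str]:
        return [r.key for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FlattenedGeneModel):
            return NotImplemented
        return (
            self.regions == other.regions and self.aggregate_map == other.aggregate_map
        )


# ---------------------------------------------------------------------------
# GTF / GFF3 exon reading
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]*)")


def _parse_attributes(attr: str) -> dict[str, str]:
    if "=" in attr and '"' not in attr:
        return {k: v for k, v in _GFF3_ATTR.findall(attr)}
    return {k: v for k, v in _GTF_ATTR.findall(attr)}


def read_gtf_exons(path) -> list[tuple[str, str, str, int, int, str]]:
    """Read exon records from a GTF or GFF3 file.

    Returns tuples ``(gene_id, transcript_id, chrom, start, end, strand)``
    with coordinates converted to half-open 0-based.
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise AnnotationError(f"{path}:{ln}: expected 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature.lower() != "exon":
                continue
            a = _parse_attributes(attrs)
            gene = a.get("gene_id") or a.get("gene") or a.get("Parent")
            tx = a.get("transcript_id") or a.get("Parent") or gene
            if gene is None:
                raise AnnotationError(f"{path}:{ln}: exon without gene_id")
            s, e = int(start), int(end)
            if e < s:
                raise AnnotationError(f"{path}:{ln}: exon end < start")
            out.append((gene, tx, chrom, s - 1, e, strand))
    return out


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open intervals into a disjoint sorted union."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def flatten_gene_models(
    exons: Iterable[tuple[str, str, str, int, int, str]],
    *,
    aggregate: bool = True,
    merge_unstranded: bool = False,
) -> FlattenedGeneModel:
    """Build a reduced gene model of disjoint exonic regions.

    Parameters
    ----------
    exons
        Exon records ``(gene_id, transcript_id, chrom, start, end, strand)``
        with half-open 0-based coordinates (as returned by
        :func:`read_gtf_exons`).
    aggregate
        Merge genes whose exon unions overlap on the same chromosome and
        strand into one aggregate gene group (ids joined with ``+``).
        When False such genes are dropped entirely.
    merge_unstranded
        Treat strand ``*`` as compatible with both strands when testing
        for gene overlap.  Off by default: merging is strand-specific.

    Per (aggregate) gene, each transcript's exons are first collapsed to
    their base-level union, then the gene's exon union is cut at every
    distinct boundary of those per-transcript unions — i.e. at every base
    where the set of covering transcripts changes.  Region ids
    ``E001, E002, ...`` are assigned by ascending genomic start.
    """
    by_gene: dict[str, dict] = {}
    tx_iv: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for gene, tx, chrom, s, e, strand in exons:
        if e <= s:
            raise AnnotationError(f"gene {gene}: exon end <= start ({s}, {e})")
        if strand not in _VALID_STRANDS:
            raise AnnotationError(f"gene {gene}: unknown strand {strand!r}")
        g = by_gene.setdefault(gene, {"chrom": chrom, "strand": strand, "iv": []})
        if g["chrom"] != chrom:
            raise AnnotationError(f"gene {gene}: exons on multiple chromosomes")
        if g["strand"] != strand:
            g["strand"] = "*"
        tx_iv.setdefault((gene, tx), []).append((s, e))

    for (gene, _tx), ivs in tx_iv.items():
        by_gene[gene]["iv"].extend(_union(ivs))

    for g in by_gene.values():
        g["union"] = _union(g["iv"])

    # group genes whose unions overlap (same chrom, compatible strand)
    groups = _overlap_groups(by_gene, merge_unstranded=merge_unstranded)

    regions: list[ExonicRegion] = []
    aggregate_map: dict[str, str] = {}
    for members in groups:
        if len(members) > 1 and not aggregate:
            continue  # drop-overlaps mode
        gid = "+".join(sorted(members))
        chrom = by_gene[members[0]]["chrom"]
        strands = {by_gene[m]["strand"] for m in members}
        strand = strands.pop() if len(strands) == 1 else "*"
        pooled = [iv for m in members for iv in by_gene[m]["iv"]]
        for m in members:
            aggregate_map[m] = gid
        cuts = sorted({x for iv in pooled for x in iv})
        covered = _union(pooled)
        pieces: list[tuple[int, int]] = []
        for us, ue in covered:
            inner = [c for c in cuts if us < c < ue]
            bounds = [us, *inner, ue]
            pieces.extend(zip(bounds, bounds[1:]))
        for k, (s, e) in enumerate(sorted(pieces), start=1):
            regions.append(
                ExonicRegion(
                    region_id=f"E{k:03d}",
                    gene_id=gid,
                    chrom=chrom,
                    start=s,
                    end=e,
                    strand=strand,
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start, r.gene_id, r.region_id))
    return FlattenedGeneModel(regions=regions, aggregate_map=aggregate_map)


def _overlap_groups(by_gene: dict[str, dict], *, merge_unstranded: bool) -> list[list[str]]:
    """Connected components of genes under exon-union overlap."""
    parent = {g: g for g in by_gene}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def join(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    def compatible(sa: str, sb: str) -> bool:
        if sa == sb:
            return True
        if merge_unstranded and ("*" in (sa, sb)):
            return True
        return False

    # sweep per chromosome over union intervals
    events: dict[str, list[tuple[int, int, str]]] = {}
    for g, d in by_gene.items():
        for s, e in d["union"]:
            events.setdefault(d["chrom"], []).append((s, e, g))
    for chrom_events in events.values():
        chrom_events.sort()
        active: list[tuple[int, str]] = []  # (end, gene)
        for s, e, g in chrom_events:
            active = [(ae, ag) for ae, ag in active if ae > s]
            for _ae, ag in active:
                if compatible(by_gene[g]["strand"], by_gene[ag]["strand"]):
                    join(g, ag)
            active.append((e, g))

    comps: dict[str, list[str]] = {}
    for g in by_gene:
        comps.setdefault(find(g), []).append(g)
    return [sorted(v) for v in comps.values()]


# ---------------------------------------------------------------------------
# Flattened GFF I/O
# ---------------------------------------------------------------------------

_GFF_HEADER = "##gff-version 3"


def write_flattened_gff(model: FlattenedGeneModel, path) -> None:
    """Write the reduced gene model as GFF3 (1-based inclusive coordinates).

    One ``aggregate_gene`` feature per gene group plus one
    ``exonic_part`` feature per region.  Deterministic: identical models
    produce byte-identical files.
    """
    lines = [_GFF_HEADER]
    for gid in model.gene_ids:
        regs = model.regions_of(gid)
        chrom = regs[0].chrom
        strand = regs[0].strand if regs[0].strand != "*" else "."
        gs = min(r.start for r in regs) + 1
        ge = max(r.end for r in regs)
        members = ",".join(
            sorted(m for m, a in model.aggregate_map.items() if a == gid)
        ) or gid
        lines.append(
            "\t".join(
                [chrom, "tdexon", "aggregate_gene", str(gs), str(ge), ".", strand,
                 ".", f"ID={gid};members={members}"]
            )
        )
        for r in regs:
            lines.append(
                "\t".join(
                    [chrom, "tdexon", "exonic_part", str(r.start + 1), str(r.end),
                     ".", strand, ".", f"ID={r.key};Parent={gid};exonic_part={r.region_id}"]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_flattened_gff(path) -> FlattenedGeneModel:
    """Read a reduced gene model written by :func:`write_flattened_gff`."""
    regions: list[ExonicRegion] = []
    aggregate_map: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise AnnotationError(f"{path}:{ln}: expected 9 GFF columns")
            chrom, _src, feature, start, end, _score, strand, _fr, attrs = parts
            a = _parse_attributes(attrs)
            if feature == "aggregate_gene":
                gid = a["ID"]
                for m in a.get("members", gid).split(","):
                    aggregate_map[m] = gid
            elif feature == "exonic_part":
                regions.append(
                    ExonicRegion(
                        region_id=a["exonic_part"],
                        gene_id=a["Parent"],
                        chrom=chrom,
                        start=int(start) - 1,
                        end=int(end),
                        strand=strand if strand in "+-" else "*",
                    )
                )
            else:
                raise AnnotationError(f"{path}:{ln}: unknown feature {feature!r}")
    regions.sort(key=lambda r: (r.chrom, r.start, r.gene_id, r.region_id))
    return FlattenedGeneModel(regions=regions, aggregate_map=aggregate_map)
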