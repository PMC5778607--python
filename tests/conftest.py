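"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tdexon.glm import DesignTable, SizeFactors


def make_design(n_individuals: int, n_tissues: int, *, sexes: bool = True) -> DesignTable:
    """Fully crossed design with alternating sexes."""
    rows = []
    for i in range(1, n_individuals + 1):
        sex = "M" if i % 2 else "F"
        for t in range(1, n_tissues + 1):
            rows.append(
                {
                    "sample": f"I{i:02d}.T{t}",
                    "individual": f"I{i:02d}",
                    "tissue": f"T{t}",
                    "sex": sex if sexes else 0.0,
                }
            )
    return DesignTable(pd.DataFrame(rows))


def unit_size_factors(design: DesignTable) -> SizeFactors:
    return SizeFactors(pd.Series(1.0, index=design.samples))


@pytest.fixture
def design_2x2() -> DesignTable:
    return make_design(2, 2)


@pytest.fixture
def design_3x2() -> DesignTable:
    return make_design(3, 2)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def perbase_partition(exons) -> dict:
    """Per-base flattening oracle.

    ``exons``: records (gene, tx, chrom, start, end, strand), half-open.
    Labels every base with the set of transcripts covering it and returns,
    per same-strand overlap group of genes, the maximal runs of constant
    non-empty label as sorted (start, end) pairs keyed by the sorted tuple
    of member genes.
    """
    genes = sorted({g for g, *_ in exons})
    # union-find over genes by same-strand base sharing
    parent = {g: g for g in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cover_by_strand: dict[tuple, dict[int, set]] = {}
    for g, _tx, chrom, s, e, strand in exons:
        d = cover_by_strand.setdefault((chrom, strand), {})
        for b in range(s, e):
            d.setdefault(b, set()).add(g)
    for d in cover_by_strand.values():
        for gs in d.values():
            gs = sorted(gs)
            for other in gs[1:]:
                ra, rb = find(gs[0]), find(other)
                if ra != rb:
                    parent[rb] = ra

    groups: dict[str, list[str]] = {}
    for g in genes:
        groups.setdefault(find(g), []).append(g)

    out = {}
    for members in groups.values():
        members = sorted(members)
        mem = set(members)
        label: dict[int, frozenset] = {}
        for g, tx, chrom, s, e, strand in exons:
            if g in mem:
                for b in range(s, e):
                    label[b] = label.get(b, frozenset()) | {(g, tx)}
        runs = []
        cur_start = None
        prev_lab = None
        for b in sorted(label):
            if cur_start is None:
                cur_start, cur_end, prev_lab = b, b + 1, label[b]
            elif b == cur_end and label[b] == prev_lab:
                cur_end = b + 1
            else:
                runs.append((cur_start, cur_end))
                cur_start, cur_end, prev_lab = b, b + 1, label[b]
        if cur_start is not None:
            runs.append((cur_start, cur_end))
        out[tuple(members)] = runs
    return out


def random_annotation(rng: np.random.Generator, *, span: int = 10_000):
    """Random small multi-gene annotation within ``span`` bases."""
    exons = []
    n_genes = int(rng.integers(1, 5))
    for g in range(n_genes):
        gid = f"g{g}"
        strand = "+" if rng.random() < 0.5 else "-"
        anchor = int(rng.integers(0, span - 1500))
        for tx in range(int(rng.integers(1, 4))):
            txid = f"{gid}.t{tx}"
            pos = anchor + int(rng.integers(0, 300))
            for _ in range(int(rng.integers(1, 5))):
                start = pos + int(rng.integers(1, 200))
                end = start + int(rng.integers(1, 250))
                exons.append((gid, txid, "chr1", start, min(end, span), strand))
                pos = end
    return exons
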