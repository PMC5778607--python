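"""Fragment counting: containment, junctions, skipping, fragment-level rest."""

import numpy as np
import pandas as pd
import pytest

from tdexon.annotation import ExonicRegion, FlattenedGeneModel
from tdexon.counting import (
    CountTables,
    FragmentAlignment,
    build_reuc_pairs,
    count_fragments,
    read_fragments_sam,
    read_fragments_tsv,
    write_fragments_tsv,
)


def region(gene, rid, start, end, chrom="chr1"):
    return ExonicRegion(rid, gene, chrom, start, end, "+")


@pytest.fixture
def gene_model():
    """One 3-region gene plus a second distant gene."""
    regs = [
        region("gA", "E001", 100, 200),
        region("gA", "E002", 300, 400),
        region("gA", "E003", 500, 600),
        region("gB", "E001", 5000, 5100),
    ]
    return FlattenedGeneModel(regs, {"gA": "gA", "gB": "gB"})


def frag(blocks, sample="s1", chrom="chr1", unique=True):
    return FragmentAlignment(sample, chrom, tuple(blocks), unique)


class TestInclusion:
    def test_contained_fragment_counts_once(self, gene_model):
        t = count_fragments([frag([(310, 360)])], gene_model, samples=["s1"])
        assert t.inclusion.loc["gA:E002", "s1"] == 1
        assert t.inclusion.drop("gA:E002").to_numpy().sum() == 0

    def test_junction_fragment_counts_each_touched_region(self, gene_model):
        t = count_fragments([frag([(150, 200), (500, 550)])], gene_model, samples=["s1"])
        assert t.inclusion.loc["gA:E001", "s1"] == 1
        assert t.inclusion.loc["gA:E003", "s1"] == 1
        assert t.gene_totals.loc["gA", "s1"] == 1  # one fragment, one gene

    def test_fragment_outside_regions_ignored(self, gene_model):
        t = count_fragments([frag([(250, 280)])], gene_model, samples=["s1"])
        assert t.inclusion.to_numpy().sum() == 0
        assert t.stats.n_no_region == 1

    def test_unknown_chromosome_skipped_not_error(self, gene_model):
        t = count_fragments([frag([(100, 150)], chrom="chrZ")], gene_model, samples=["s1"])
        assert t.stats.n_unknown_chrom == 1
        assert t.inclusion.to_numpy().sum() == 0

    def test_nonunique_fragment_discarded(self, gene_model):
        t = count_fragments([frag([(310, 360)], unique=False)], gene_model, samples=["s1"])
        assert t.inclusion.to_numpy().sum() == 0
        assert t.stats.n_nonunique == 1

    def test_two_gene_fragment_is_ambiguous(self):
        regs = [region("gA", "E001", 100, 200), region("gB", "E001", 150, 260)]
        # different strands so the genes are not merged at flatten time
        regs[1] = ExonicRegion("E001", "gB", "chr1", 150, 260, "-")
        model = FlattenedGeneModel(regs, {"gA": "gA", "gB": "gB"})
        t = count_fragments([frag([(160, 190)])], model, samples=["s1"])
        assert t.stats.n_ambiguous == 1
        assert t.inclusion.to_numpy().sum() == 0


class TestSkipping:
    def test_gap_containing_region_with_both_anchors(self, gene_model):
        t = count_fragments([frag([(150, 200), (500, 550)])], gene_model, samples=["s1"])
        assert t.skipping.loc["gA:E002", "s1"] == 1

    def test_ungapped_fragment_never_skips(self, gene_model):
        t = count_fragments([frag([(150, 550)])], gene_model, samples=["s1"])
        assert t.skipping.to_numpy().sum() == 0

    def test_gap_partially_overlapping_region_does_not_count(self, gene_model):
        # gap (200, 350) clips E002 but does not contain it
        t = count_fragments([frag([(150, 200), (350, 380)])], gene_model, samples=["s1"])
        assert t.skipping.loc["gA:E002", "s1"] == 0

    def test_anchor_on_one_side_only_does_not_count(self, gene_model):
        # second block in the intron: downstream anchor misses all regions
        t = count_fragments([frag([(150, 200), (420, 450)])], gene_model, samples=["s1"])
        assert t.skipping.loc["gA:E002", "s1"] == 0


class TestReucPairs:
    def test_disjoint_fragments_rest_is_gene_total_minus_region(self, gene_model):
        frags = (
            [frag([(110, 160)]) for _ in range(5)]
            + [frag([(310, 360)]) for _ in range(3)]
            + [frag([(510, 560)]) for _ in range(2)]
        )
        t = count_fragments(frags, gene_model, samples=["s1"])
        rest = t.rest
        assert t.inclusion.loc["gA:E001", "s1"] == 5
        assert rest.loc["gA:E001", "s1"] == 5  # 3 + 2
        assert rest.loc["gA:E002", "s1"] == 7
        assert rest.loc["gA:E003", "s1"] == 8

    def test_single_region_gene_rest_is_zero(self, gene_model):
        t = count_fragments([frag([(5010, 5060)])], gene_model, samples=["s1"])
        assert t.inclusion.loc["gB:E001", "s1"] == 1
        assert t.rest.loc["gB:E001", "s1"] == 0

    def test_spanning_fragments_match_fragment_level_recount(self, gene_model):
        frags = [
            frag([(110, 160), (310, 360)]),  # touches E001+E002
            frag([(150, 200), (500, 550)]),  # touches E001+E003, skips E002
            frag([(310, 360)]),
        ]
        t = count_fragments(frags, gene_model, samples=["s1"])
        # brute-force fragment-level rest oracle
        regions = {r.key: (r.start, r.end) for r in gene_model.regions_of("gA")}
        for key, (rs, re_) in regions.items():
            touching = sum(
                any(b < re_ and e > rs for b, e in f.blocks) for f in frags
            )
            assert t.rest.loc[key, "s1"] == len(frags) - touching


class TestProperties:
    def test_order_independence(self, gene_model):
        rng = np.random.default_rng(0)
        frags = []
        for _ in range(200):
            s = int(rng.integers(100, 600))
            frags.append(frag([(s, s + 40)], sample=f"s{rng.integers(1, 4)}"))
        t1 = count_fragments(frags, gene_model, samples=["s1", "s2", "s3"])
        shuffled = list(frags)
        rng.shuffle(shuffled)
        t2 = count_fragments(shuffled, gene_model, samples=["s1", "s2", "s3"])
        assert t1.inclusion.equals(t2.inclusion)
        assert t1.skipping.equals(t2.skipping)
        assert t1.gene_totals.equals(t2.gene_totals)

    def test_conservation_inclusion_plus_rest(self, gene_model):
        rng = np.random.default_rng(1)
        frags = [
            frag([(int(s), int(s) + 30)])
            for s in rng.integers(100, 600, size=100)
        ]
        t = count_fragments(frags, gene_model, samples=["s1"])
        for key in t.inclusion.index:
            gene = key.split(":")[0]
            assert (
                t.inclusion.loc[key, "s1"] + t.rest.loc[key, "s1"]
                == t.gene_totals.loc[gene, "s1"]
            )


class TestFragmentIO:
    def test_tsv_roundtrip(self, tmp_path):
        frags = [
            frag([(10, 50), (100, 140)], sample="a"),
            frag([(5, 25)], sample="b", unique=False),
        ]
        p = tmp_path / "frags.tsv"
        write_fragments_tsv(frags, p)
        back = list(read_fragments_tsv(p))
        assert back == frags

    def test_sam_reading_merges_mates_and_flags_nonunique(self, tmp_path, gene_model):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"
            "p1\t99\tchr1\t111\t60\t40M\t=\t321\t0\t*\t*\tNH:i:1\n"
            "p1\t147\tchr1\t321\t60\t40M\t=\t111\t0\t*\t*\tNH:i:1\n"
            "m1\t0\tchr1\t511\t60\t30M\t*\t0\t0\t*\t*\tNH:i:5\n"
        )
        frags = list(read_fragments_sam(sam, "s1"))
        paired = [f for f in frags if len(f.blocks) == 2]
        assert len(paired) == 1 and paired[0].unique
        assert paired[0].blocks == ((110, 150), (320, 360))
        multi = [f for f in frags if f.blocks == ((510, 540),)]
        assert len(multi) == 1 and not multi[0].unique


def test_count_tables_validation(gene_model):
    t = count_fragments([frag([(310, 360)])], gene_model, samples=["s1"])
    t.validate()
    bad = CountTables(
        inclusion=t.inclusion.astype(float) - 0.5,
        skipping=t.skipping,
        gene_totals=t.gene_totals,
    )
    with pytest.raises(ValueError):
        bad.validate()
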