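"""Tag-to-neighborhood assignment: windows, midpoint rule, oracle parity."""

import numpy as np
import pandas as pd
import pytest

from retroscan.io import GeneRecord, GenomicInterval
from retroscan.tags import (
    NeighborhoodSpec,
    count_tags,
    flatten_intervals,
    gene_neighborhood,
)


@pytest.mark.parametrize(
    "tss,strand,spec,expected",
    [
        (100_000, "+", NeighborhoodSpec(), (95_000, 105_000)),
        (3_000, "+", NeighborhoodSpec(), (0, 8_000)),  # clipped at chromosome start
        (100_000, "-", NeighborhoodSpec(6000, 4000), (96_000, 106_000)),  # strand flip
    ],
)
def test_gene_neighborhood_windows(tss, strand, spec, expected):
    gene = GeneRecord("G", "chr1", tss, strand)
    nb = gene_neighborhood(gene, spec)
    assert (nb.start, nb.end) == expected


def test_neighborhood_spec_rejects_zero_window():
    with pytest.raises(ValueError):
        NeighborhoodSpec(0, 0)


def _gene_frame(records):
    return pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand) for g in records],
        columns=["gene_id", "chrom", "tss", "strand"],
    )


def test_count_tags_no_tags():
    genes = _gene_frame([GeneRecord("G1", "chr1", 10_000, "+")])
    out = count_tags(genes, [], [], "K562")
    assert out.loc[0, "re_tags"] == 0 and out.loc[0, "total_tags"] == 0


def test_count_tags_hand_worked_fixture():
    """Gene TSS 10 kb (+): midpoints 9200/9400 on the RE, 12000 off it,
    20001 outside the [5000, 15000) window entirely."""
    genes = _gene_frame([GeneRecord("G1", "chr1", 10_000, "+")])
    res = [GenomicInterval("chr1", 9_000, 9_500)]
    tags = [
        GenomicInterval("chr1", 9_150, 9_250),
        GenomicInterval("chr1", 9_350, 9_450),
        GenomicInterval("chr1", 11_950, 12_050),
        GenomicInterval("chr1", 19_951, 20_051),
    ]
    out = count_tags(genes, res, tags, "K562")
    assert (out.loc[0, "re_tags"], out.loc[0, "total_tags"]) == (2, 3)


def test_count_tags_saturation_when_all_midpoints_on_res():
    genes = _gene_frame([GeneRecord("G1", "chr1", 10_000, "+")])
    res = [GenomicInterval("chr1", 5_000, 15_000)]
    tags = [GenomicInterval("chr1", 6_000 + i * 100, 6_050 + i * 100) for i in range(10)]
    out = count_tags(genes, res, tags, "K562")
    assert out.loc[0, "re_tags"] == out.loc[0, "total_tags"] == 10


def test_midpoint_at_window_end_is_outside():
    genes = _gene_frame([GeneRecord("G1", "chr1", 10_000, "+")])
    tags = [GenomicInterval("chr1", 14_950, 15_050)]  # midpoint exactly 15000
    out = count_tags(genes, [], tags, "K562")
    assert out.loc[0, "total_tags"] == 0


def test_tag_in_two_neighborhoods_counts_for_both():
    genes = _gene_frame(
        [GeneRecord("G1", "chr1", 10_000, "+"), GeneRecord("G2", "chr1", 12_000, "+")]
    )
    tags = [GenomicInterval("chr1", 10_950, 11_050)]
    out = count_tags(genes, [], tags, "K562").set_index("gene_id")
    assert out.loc["G1", "total_tags"] == 1 and out.loc["G2", "total_tags"] == 1


def _brute_force(genes, res, tags, spec):
    """O(genes x tags x REs) reference implementation."""
    rows = []
    for g in genes.itertuples(index=False):
        if g.strand == "+":
            lo, hi = g.tss - spec.upstream, g.tss + spec.downstream
        else:
            lo, hi = g.tss - spec.downstream, g.tss + spec.upstream
        lo = max(0, lo)
        re_n = tot = 0
        for t in tags:
            mid = (t.start + t.end) // 2
            if t.chrom == g.chrom and lo <= mid < hi:
                tot += 1
                if any(r.chrom == t.chrom and r.start <= mid < r.end for r in res):
                    re_n += 1
        rows.append((g.gene_id, re_n, tot))
    return rows


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_count_tags_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n_genes = int(rng.integers(5, 50))
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(n_genes)],
            "chrom": rng.choice(["chr1", "chr2"], n_genes),
            "tss": rng.integers(0, 60_000, n_genes),
            "strand": rng.choice(["+", "-"], n_genes),
        }
    )
    res = [
        GenomicInterval(c, int(s), int(s + w))
        for c, s, w in zip(
            rng.choice(["chr1", "chr2"], 30),
            rng.integers(0, 70_000, 30),
            rng.integers(50, 2_000, 30),
        )
    ]
    tags = [
        GenomicInterval(c, int(s), int(s + w))
        for c, s, w in zip(
            rng.choice(["chr1", "chr2", "chr3"], 500),
            rng.integers(0, 70_000, 500),
            rng.integers(1, 300, 500),
        )
    ]
    spec = NeighborhoodSpec(int(rng.integers(0, 8_000)), int(rng.integers(1, 8_000)))
    out = count_tags(genes, res, tags, "L", spec)
    expected = _brute_force(genes, res, tags, spec)
    got = list(zip(out["gene_id"], out["re_tags"], out["total_tags"]))
    assert got == expected
    # partition invariant: RE-linked plus RE-free equals total
    assert ((out["total_tags"] - out["re_tags"]) >= 0).all()


def test_adding_out_of_window_tag_changes_nothing():
    genes = _gene_frame([GeneRecord("G1", "chr1", 10_000, "+")])
    res = [GenomicInterval("chr1", 9_000, 9_500)]
    tags = [GenomicInterval("chr1", 9_150, 9_250)]
    base = count_tags(genes, res, tags, "L")
    extra = tags + [GenomicInterval("chr1", 40_000, 40_100), GenomicInterval("chr9", 9_150, 9_250)]
    again = count_tags(genes, res, extra, "L")
    pd.testing.assert_frame_equal(base, again)


def test_flatten_merges_nested_and_overlapping_intervals():
    ivs = [
        GenomicInterval("chr1", 0, 100),
        GenomicInterval("chr1", 50, 80),  # nested
        GenomicInterval("chr1", 90, 150),  # overlapping
        GenomicInterval("chr1", 200, 250),
    ]
    starts, ends = flatten_intervals(ivs)["chr1"]
    assert starts.tolist() == [0, 200] and ends.tolist() == [150, 250]
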