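"""Synthetic-data generator: determinism, geometry and planted structure."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import retroscan as rs
from retroscan.errors import ConfigError
from retroscan.tags import flatten_intervals, points_in_track


def test_config_invariants_enforced():
    with pytest.raises(ConfigError):
        rs.SimulationConfig(background_re_tag_prob=0.9, planted_re_tag_prob=0.2)
    with pytest.raises(ConfigError):
        rs.SimulationConfig(planted_fraction=0.7)
    with pytest.raises(ConfigError):
        rs.SimulationConfig(re_density=1.5)


def test_infeasible_geometry_rejected():
    with pytest.raises(ConfigError, match="do not fit"):
        rs.simulate(rs.SimulationConfig(n_genes=5000, n_chromosomes=1, chrom_length=1_000_000))


def test_same_seed_regenerates_byte_identical_files(tmp_path, small_dataset):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    paths1 = small_dataset.write(d1)
    paths2 = rs.simulate(small_dataset.config).write(d2)
    assert set(paths1) == set(paths2)
    for key in paths1:
        assert filecmp.cmp(paths1[key], paths2[key], shallow=False), key


def test_different_seeds_differ(small_dataset):
    cfg = small_dataset.config
    other = rs.simulate(rs.SimulationConfig(**{**cfg.__dict__, "seed": cfg.seed + 1}))
    assert set(other.ground_truth.planted_gene_ids) != set(small_dataset.ground_truth.planted_gene_ids)


def test_planted_count_and_manifest(small_dataset):
    cfg = small_dataset.config
    truth = small_dataset.ground_truth
    assert len(truth.planted_gene_ids) == round(cfg.planted_fraction * cfg.n_genes)
    assert set(truth.planted_gene_ids) <= set(small_dataset.genes["gene_id"])
    assert set(truth.planted_pathway_ids) <= set(small_dataset.pathways)
    assert set(truth.planted_term_ids) <= set(small_dataset.terms)
    for term in truth.planted_term_ids:
        assert set(small_dataset.terms[term]) <= set(truth.planted_gene_ids)


def test_neighborhoods_do_not_overlap(small_dataset):
    cfg = small_dataset.config
    for _, grp in small_dataset.genes.groupby("chrom"):
        starts = np.sort(grp["tss"].to_numpy() - cfg.upstream)
        assert (np.diff(starts) >= cfg.window).all()


def _neighborhood_coverage(dataset):
    cfg = dataset.config
    flat = flatten_intervals(dataset.res)
    covered = 0
    for g in dataset.genes.itertuples():
        lo = g.tss - (cfg.upstream if g.strand == "+" else cfg.downstream)
        starts, ends = flat[g.chrom]
        j0 = np.searchsorted(ends, lo, side="right")
        j1 = np.searchsorted(starts, lo + cfg.window, side="left")
        covered += (np.clip(ends[j0:j1], lo, lo + cfg.window) - np.clip(starts[j0:j1], lo, lo + cfg.window)).sum()
    return covered / (len(dataset.genes) * cfg.window)


def test_realized_re_coverage_near_target(small_dataset):
    cov = _neighborhood_coverage(small_dataset)
    assert abs(cov - small_dataset.config.re_density) < 0.05


def test_tag_midpoints_respect_re_assignment_probabilities(small_dataset):
    """Planted genes' tags hit the RE track at ~p1, background at ~p0."""
    ds = small_dataset
    flat = flatten_intervals(ds.res)
    planted = set(ds.ground_truth.planted_gene_ids)
    counts = pd.concat(
        [rs.count_tags(ds.genes, ds.res, t, line) for line, t in ds.tags.items()],
        ignore_index=True,
    )
    grouped = counts.groupby("gene_id")[["re_tags", "total_tags"]].sum()
    frac_planted = grouped.loc[sorted(planted & set(grouped.index))].sum()
    frac_bg = grouped.drop(index=sorted(planted), errors="ignore").sum()
    assert frac_planted["re_tags"] / frac_planted["total_tags"] == pytest.approx(
        ds.config.planted_re_tag_prob, abs=0.05
    )
    assert frac_bg["re_tags"] / frac_bg["total_tags"] == pytest.approx(
        ds.config.background_re_tag_prob, abs=0.03
    )
    # sanity on the track itself: every tag lies inside some neighborhood
    for line, tags in ds.tags.items():
        mids = ((tags["start"] + tags["end"]) // 2).to_numpy()
        assert (mids > 0).all()


def test_planted_ngre_exceeds_background(small_dataset, small_scores):
    planted = sorted(set(small_dataset.ground_truth.planted_gene_ids))
    agg = small_scores.set_index("gene_id")
    planted_vals = agg.loc[planted, "ngre"].dropna()
    bg_vals = agg.drop(index=planted)["ngre"].dropna()
    stat, p = sps.mannwhitneyu(planted_vals, bg_vals, alternative="greater")
    assert p < 1e-6


def test_null_construction_when_probs_equal():
    cfg = rs.SimulationConfig(
        seed=5, n_chromosomes=2, chrom_length=2_000_000, n_genes=300,
        n_cell_lines=2, background_re_tag_prob=0.3, planted_re_tag_prob=0.3,
        n_pathways=10, n_terms=10, n_planted_pathways=0, n_planted_terms=0,
    )
    ds = rs.simulate(cfg)
    counts = pd.concat(
        [rs.count_tags(ds.genes, ds.res, t, line) for line, t in ds.tags.items()],
        ignore_index=True,
    )
    agg = rs.aggregate_cell_lines(rs.compute_gene_scores(counts))
    planted = sorted(set(ds.ground_truth.planted_gene_ids))
    pl = agg.set_index("gene_id").loc[planted, "ngre"].dropna()
    bg = agg.set_index("gene_id").drop(index=planted)["ngre"].dropna()
    _, p = sps.mannwhitneyu(pl, bg, alternative="two-sided")
    assert p > 1e-3  # no planted signal under the null construction


def test_separation_limit_pushes_ngre_to_extremes():
    cfg = rs.SimulationConfig(
        seed=6, n_chromosomes=1, chrom_length=2_000_000, n_genes=150,
        n_cell_lines=1, background_re_tag_prob=0.0, planted_re_tag_prob=1.0,
        mean_tags_per_neighborhood=60.0,
        n_pathways=10, n_terms=10, n_planted_pathways=0, n_planted_terms=0,
    )
    ds = rs.simulate(cfg)
    line = cfg.cell_lines[0]
    scores = rs.compute_gene_scores(rs.count_tags(ds.genes, ds.res, ds.tags[line], line))
    planted = set(ds.ground_truth.planted_gene_ids)
    s = scores.set_index("gene_id")["ngre"].dropna()
    assert (s.loc[s.index.isin(planted)] == 1.0).all()
    assert (s.loc[~s.index.isin(planted)] == 0.0).all()


def test_outputs_readable_by_io_layer(tmp_path, small_dataset):
    paths = small_dataset.write(tmp_path / "sim")
    genes = rs.read_gene_table(paths["genes"])
    assert len(genes) == small_dataset.config.n_genes
    res = rs.read_repeatmasker(paths["res"])
    assert len(res) > 0
    line = small_dataset.config.cell_lines[0]
    tags = rs.read_bed(paths[f"tags_{line}"])
    assert len(tags) == len(small_dataset.tags[line])
    assert len(rs.read_gmt(paths["pathways"])) == small_dataset.config.n_pathways


# ---------------------------------------------------------------------------
# Null-universe sampler


def test_null_universe_all_class():
    ks = rs.simulate_null_universe(M=20, N=20, n=7, reps=50, seed=0)
    assert (ks == 7).all()


def test_null_universe_mean_matches_expectation():
    M, N, n, reps = 300, 60, 40, 4000
    ks = rs.simulate_null_universe(M, N, n, reps, seed=1)
    expected = n * N / M
    sd = np.sqrt(n * (N / M) * (1 - N / M) * (M - n) / (M - 1))
    assert abs(ks.mean() - expected) < 3 * sd / np.sqrt(reps)


def test_null_universe_tail_matches_hypergeometric_test():
    M, N, n, reps = 500, 50, 60, 4000
    ks = rs.simulate_null_universe(M, N, n, reps, seed=2)
    for k0 in (4, 6, 8):
        emp = (ks > k0).mean()
        model = rs.over_under_test(M=M, n=n, N=N, k=k0).p_over
        se = np.sqrt(model * (1 - model) / reps)
        assert abs(emp - model) <= 3 * se + 1e-9
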