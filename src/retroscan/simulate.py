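"""Synthetic epigenome generator with known ground truth.

The generator emulates the pipeline's real inputs at desk scale: a genome of
a few chromosomes carrying gene TSSs with non-overlapping 10-kb
neighborhoods, a retroelement track covering ~40% of each neighborhood (the
genomic RE share), per-cell-line H3K4me1 tag tracks, pathway/term GMT
collections and ncRNA class labels.

A planted subset of genes is made RRE-enriched *in composition*: every
gene's expected RE-linked tag count is the same (``lambda * p0`` per cell
line), but planted genes draw their total tag count from
``Poisson(lambda * p0 / p1)`` and place each tag on the RE track with
probability ``p1 > p0``, so their expected RE fraction (NGRE) rises to p1
while their expected absolute score (GRE) stays at the background level.
This plants the signal exactly along the axis the trend classification
measures — relative versus absolute RE-linked signal — instead of inflating
total signal; with ``p0 = p1`` the construction degenerates to the exact
null (every gene Poisson(lambda), RE probability p0).

ncRNA class labels are drawn per gene, with the odds of the lncRNA and
miRNA classes multiplied by ``ncrna_bias`` for planted genes. The first
``n_planted_pathways``/``n_planted_terms`` gene sets are composed entirely
of planted genes. The same seed regenerates byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import GeneSetCollection, write_bed, write_gene_table, write_gmt
from .tags import flatten_intervals

_RE_NAMES = ("SINE/Alu", "LINE/L1", "LTR/ERVL", "Retroposon/SVA")
_CELL_LINE_NAMES = ("K562", "HepG2", "GM12878", "MCF7", "HeLaS3")
_MARGIN = 1000  # keeps neighborhoods and tag intervals clear of position 0


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic epigenome; defaults are the study conditions.

    ``mean_tags_per_neighborhood`` is the Poisson mean per background gene
    and cell line; ``background_re_tag_prob``/``planted_re_tag_prob`` are
    the per-tag probabilities of landing on the RE track; ``re_density`` is
    the target RE coverage fraction inside neighborhoods (~0.4, the RE share
    of the human genome); ``ncrna_fraction`` mirrors the real class rates
    (1479 lncRNA and 1799 miRNA among 24,070 genes).
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 6_000_000
    n_genes: int = 2000
    re_density: float = 0.4
    mean_tags_per_neighborhood: float = 30.0
    n_cell_lines: int = 5
    planted_fraction: float = 0.05
    background_re_tag_prob: float = 0.25
    planted_re_tag_prob: float = 0.8
    n_pathways: int = 200
    pathway_size: int = 20
    n_terms: int = 200
    term_size: int = 20
    n_planted_pathways: int = 5
    n_planted_terms: int = 5
    lncrna_fraction: float = 0.0614
    mirna_fraction: float = 0.0747
    other_fraction: float = 0.02
    ncrna_bias: float = 3.0
    tag_width: int = 150
    upstream: int = 5000
    downstream: int = 5000

    def __post_init__(self):
        p0, p1 = self.background_re_tag_prob, self.planted_re_tag_prob
        if not 0 <= p0 <= p1 <= 1 or p1 == 0:
            raise ConfigError(f"need 0 <= p0 <= p1 <= 1 with p1 > 0, got p0={p0}, p1={p1}")
        if not 0 < self.planted_fraction < 0.5:
            raise ConfigError("planted_fraction must be in (0, 0.5)")
        if not 0 < self.re_density < 1:
            raise ConfigError("re_density must be in (0, 1)")
        if self.lncrna_fraction + self.mirna_fraction + self.other_fraction >= 1:
            raise ConfigError("class fractions must sum below 1")
        if min(self.n_genes, self.n_cell_lines, self.n_chromosomes) < 1:
            raise ConfigError("counts must be positive")
        if self.tag_width < 1 or self.tag_width > _MARGIN:
            raise ConfigError("tag_width must be in [1, 1000]")

    @property
    def window(self) -> int:
        return self.upstream + self.downstream

    @property
    def cell_lines(self) -> tuple[str, ...]:
        base = list(_CELL_LINE_NAMES[: self.n_cell_lines])
        base += [f"CL{i + 1}" for i in range(len(base), self.n_cell_lines)]
        return tuple(base)


@dataclass
class GroundTruth:
    planted_gene_ids: list[str]
    planted_pathway_ids: list[str]
    planted_term_ids: list[str]
    gene_classes: dict[str, str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulatedDataset:
    """In-memory synthetic inputs plus the ground-truth manifest."""

    config: SimulationConfig
    genes: pd.DataFrame  # chrom, txStart, txEnd, strand, gene_id, gene_class (+ tss)
    res: pd.DataFrame  # chrom, start, end, name, strand
    tags: dict[str, pd.DataFrame]  # cell line -> chrom, start, end, name, strand
    pathways: GeneSetCollection
    terms: GeneSetCollection
    ground_truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every input file plus the ground-truth manifest; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"genes": out / "genes.tsv", "res": out / "res.bed",
                 "pathways": out / "pathways.gmt", "terms": out / "terms.gmt",
                 "ground_truth": out / "ground_truth.json"}
        write_gene_table(self.genes, paths["genes"])
        write_bed(self.res, paths["res"])
        for line, frame in self.tags.items():
            paths[f"tags_{line}"] = out / f"tags_{line}.bed"
            write_bed(frame, paths[f"tags_{line}"])
        write_gmt(self.pathways, paths["pathways"])
        write_gmt(self.terms, paths["terms"])
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def simulate(config: SimulationConfig = SimulationConfig()) -> SimulatedDataset:
    """Generate a complete synthetic dataset under *config*."""
    cfg = config
    spacing = cfg.window + 1000
    cap_per_chrom = (cfg.chrom_length - 2 * _MARGIN) // spacing
    if cap_per_chrom * cfg.n_chromosomes < cfg.n_genes:
        raise ConfigError(
            f"{cfg.n_genes} gene neighborhoods of {cfg.window} bp do not fit "
            f"{cfg.n_chromosomes} chromosomes of {cfg.chrom_length} bp"
        )

    r_layout = _rng(cfg.seed, 0)
    r_class = _rng(cfg.seed, 1)
    r_re = _rng(cfg.seed, 2)
    r_sets = _rng(cfg.seed, 3)

    # --- gene layout: one slot per gene, neighborhoods never overlap
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1
    rows = []
    nb_starts = []
    gi = 0
    for ci, count in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        jitter = r_layout.integers(0, spacing - cfg.window + 1, size=count)
        strands = r_layout.choice(["+", "-"], size=count)
        for j in range(count):
            nb_start = _MARGIN + j * spacing + int(jitter[j])
            strand = strands[j]
            tss = nb_start + (cfg.upstream if strand == "+" else cfg.downstream)
            body = min(900, cfg.chrom_length - tss - 1)
            if strand == "+":
                tx_start, tx_end = tss, tss + body
            else:
                tx_start, tx_end = tss + 1 - body, tss + 1
            rows.append(
                {
                    "chrom": chrom,
                    "txStart": tx_start,
                    "txEnd": tx_end,
                    "strand": strand,
                    "gene_id": f"G{gi:05d}",
                    "tss": tss,
                }
            )
            nb_starts.append(nb_start)
            gi += 1
    genes = pd.DataFrame(rows)
    nb_starts = np.asarray(nb_starts)

    # --- planted subset and gene classes
    n_planted = int(round(cfg.planted_fraction * cfg.n_genes))
    planted_idx = np.sort(r_layout.choice(cfg.n_genes, size=n_planted, replace=False))
    planted_mask = np.zeros(cfg.n_genes, dtype=bool)
    planted_mask[planted_idx] = True

    base = np.array([cfg.lncrna_fraction, cfg.mirna_fraction, cfg.other_fraction,
                     1 - cfg.lncrna_fraction - cfg.mirna_fraction - cfg.other_fraction])
    # ncrna_bias multiplies each ncRNA class's odds for planted genes; the
    # non-ncRNA classes shrink proportionally to fill the remainder
    def _odds_boost(p: float, b: float) -> float:
        odds = b * p / (1 - p)
        return odds / (1 + odds)

    lnc_b = _odds_boost(base[0], cfg.ncrna_bias)
    mir_b = _odds_boost(base[1], cfg.ncrna_bias)
    rest = 1.0 - lnc_b - mir_b
    if rest <= 0:
        raise ConfigError("ncrna_bias pushes class probabilities past 1")
    scale = rest / (base[2] + base[3])
    biased = np.array([lnc_b, mir_b, base[2] * scale, base[3] * scale])
    class_names = np.array(["lncRNA", "miRNA", "other", "protein_coding"])
    draws = r_class.random(cfg.n_genes)
    classes = np.empty(cfg.n_genes, dtype=object)
    for i in range(cfg.n_genes):
        probs = biased if planted_mask[i] else base
        classes[i] = class_names[np.searchsorted(np.cumsum(probs), draws[i])]
    genes["gene_class"] = classes

    # --- retroelement track: blocks inside neighborhoods + background scatter
    block = 500
    n_blocks = max(1, cfg.window // block)
    re_rows = []
    block_mask = r_re.random((cfg.n_genes, n_blocks)) < cfg.re_density
    name_pick = r_re.integers(0, len(_RE_NAMES), size=(cfg.n_genes, n_blocks))
    for i in range(cfg.n_genes):
        chrom = genes.at[i, "chrom"]
        for b in np.flatnonzero(block_mask[i]):
            s = int(nb_starts[i] + b * block)
            re_rows.append((chrom, s, s + block, _RE_NAMES[name_pick[i, b]], "."))
    n_scatter = max(1, cfg.chrom_length // 120_000)
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = np.sort(r_re.integers(0, cfg.chrom_length - 300, size=n_scatter))
        for p in pos:
            re_rows.append((chrom, int(p), int(p) + 300, _RE_NAMES[int(r_re.integers(0, 4))], "."))
    res = pd.DataFrame(re_rows, columns=["chrom", "start", "end", "name", "strand"])
    res = res.sort_values(["chrom", "start", "end"], kind="stable", ignore_index=True)

    # --- per-gene RE geometry from the flattened track
    flat = flatten_intervals(res)
    covered: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(cfg.n_genes):
        starts, ends = flat[genes.at[i, "chrom"]]
        lo, hi = nb_starts[i], nb_starts[i] + cfg.window
        j0 = np.searchsorted(ends, lo, side="right")
        j1 = np.searchsorted(starts, hi, side="left")
        seg_s = np.clip(starts[j0:j1], lo, hi)
        seg_e = np.clip(ends[j0:j1], lo, hi)
        covered.append((seg_s, seg_e))

    # --- tags per cell line
    p0, p1 = cfg.background_re_tag_prob, cfg.planted_re_tag_prob
    lam_bg = cfg.mean_tags_per_neighborhood
    lam_planted = lam_bg * (p0 / p1 if p0 > 0 else 1.0)
    half = cfg.tag_width // 2
    tag_tracks: dict[str, pd.DataFrame] = {}
    for li, line in enumerate(cfg.cell_lines):
        r_t = _rng(cfg.seed, 100 + li)
        chroms, starts_out = [], []
        for i in range(cfg.n_genes):
            lam = lam_planted if planted_mask[i] else lam_bg
            p_re = p1 if planted_mask[i] else p0
            total = int(r_t.poisson(lam))
            if total == 0:
                continue
            seg_s, seg_e = covered[i]
            lo, hi = nb_starts[i], nb_starts[i] + cfg.window
            cov_len = int((seg_e - seg_s).sum())
            free_len = cfg.window - cov_len
            n_re = int(r_t.binomial(total, p_re))
            if cov_len == 0:
                n_re = 0
            if free_len == 0:
                n_re = total
            mids = np.empty(total, dtype=np.int64)
            if n_re:
                offs = r_t.integers(0, cov_len, size=n_re)
                mids[:n_re] = _offsets_to_positions(offs, seg_s, seg_e)
            if total - n_re:
                offs = r_t.integers(0, free_len, size=total - n_re)
                gap_s, gap_e = _complement(seg_s, seg_e, lo, hi)
                mids[n_re:] = _offsets_to_positions(offs, gap_s, gap_e)
            chroms.extend([genes.at[i, "chrom"]] * total)
            starts_out.append(mids - half)
        starts_arr = np.concatenate(starts_out) if starts_out else np.empty(0, np.int64)
        track = pd.DataFrame(
            {
                "chrom": chroms,
                "start": starts_arr,
                "end": starts_arr + cfg.tag_width,
            }
        )
        track["name"] = [f"tag{j:06d}" for j in range(len(track))]
        track["strand"] = "."
        tag_tracks[line] = track

    # --- gene sets
    gene_ids = genes["gene_id"].to_numpy()
    planted_ids = [str(g) for g in gene_ids[planted_mask]]
    pathways, planted_pw = _make_sets(
        r_sets, "PW", cfg.n_pathways, cfg.pathway_size, gene_ids, planted_ids,
        cfg.n_planted_pathways,
    )
    terms, planted_terms = _make_sets(
        r_sets, "GO", cfg.n_terms, cfg.term_size, gene_ids, planted_ids,
        cfg.n_planted_terms,
    )

    truth = GroundTruth(
        planted_gene_ids=planted_ids,
        planted_pathway_ids=planted_pw,
        planted_term_ids=planted_terms,
        gene_classes={str(g): str(c) for g, c in zip(gene_ids, classes)},
    )
    return SimulatedDataset(
        config=cfg,
        genes=genes,
        res=res,
        tags=tag_tracks,
        pathways=pathways,
        terms=terms,
        ground_truth=truth,
    )


def _offsets_to_positions(offsets: np.ndarray, seg_s: np.ndarray, seg_e: np.ndarray) -> np.ndarray:
    """Map uniform offsets into the concatenated segment lengths."""
    lengths = seg_e - seg_s
    cum = np.concatenate([[0], np.cumsum(lengths)])
    seg_idx = np.searchsorted(cum, offsets, side="right") - 1
    return seg_s[seg_idx] + (offsets - cum[seg_idx])


def _complement(seg_s: np.ndarray, seg_e: np.ndarray, lo: int, hi: int):
    """Gaps of [lo, hi) not covered by the disjoint sorted segments."""
    inner = np.ravel(np.column_stack([seg_s, seg_e])) if len(seg_s) else np.empty(0, np.int64)
    bounds = np.concatenate([[lo], inner, [hi]]).astype(np.int64)
    gap_s = bounds[0::2]
    gap_e = bounds[1::2]
    keep = gap_e > gap_s
    return gap_s[keep], gap_e[keep]


def _make_sets(rng, prefix, n_sets, set_size, gene_ids, planted_ids, n_planted_sets):
    sets: dict[str, list[str]] = {}
    planted_names: list[str] = []
    width = max(4, len(str(n_sets)))
    for s in range(n_sets):
        name = f"{prefix}{s + 1:0{width}d}"
        if s < n_planted_sets and len(planted_ids) >= set_size:
            members = rng.choice(np.asarray(planted_ids, dtype=object), size=set_size, replace=False)
            planted_names.append(name)
        else:
            members = rng.choice(gene_ids, size=min(set_size, len(gene_ids)), replace=False)
        sets[name] = [str(g) for g in members]
    collection = GeneSetCollection(sets, {n: f"synthetic {prefix} set" for n in sets})
    return collection, planted_names


def simulate_null_universe(M: int, N: int, n: int, reps: int, seed: int = 0) -> np.ndarray:
    """Class counts from repeated random sampling without replacement.

    Draws *n* genes from a universe of *M* genes whose first *N* belong to
    the class, *reps* times; returns the per-draw class counts k. Serves as
    a Monte-Carlo check of the hypergeometric tails.
    """
    if not (0 <= N <= M and 0 <= n <= M):
        raise ValueError("need 0 <= N <= M and 0 <= n <= M")
    rng = np.random.default_rng(seed)
    ks = np.empty(reps, dtype=np.int64)
    for i in range(reps):
        sample = rng.choice(M, size=n, replace=False)
        ks[i] = int((sample < N).sum())
    return ks
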