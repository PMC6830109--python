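"""End-to-end orchestration: count -> score -> aggregate -> classify ->
ncRNA enrichment -> term enrichment -> permutation control -> concordance.

Every stage writes a TSV/JSON artifact into the output directory and the
run finishes with a machine-readable ``report.json`` carrying input hashes,
the seed, the package version and every summary statistic. A stage failure
aborts the run with the stage name and removes partial outputs. Two runs
with the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, PipelineError
from .io import (
    DEFAULT_RE_CLASSES,
    read_bed,
    read_gene_table,
    read_gmt,
    read_repeatmasker,
)
from .permutation import permutation_null
from .scoring import (
    aggregate_cell_lines,
    compute_gene_scores,
    compute_pathway_scores,
    correlation_matrix,
)
from .stats import (
    NEITHER,
    ConfusionTable2x2,
    over_under_test,
    term_enrichment,
)
from .tags import NeighborhoodSpec, count_tags
from .trend import LABEL_DEFICIENT, LABEL_ENRICHED, TrendFit, classify_extremes

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for a full run.

    All analysis thresholds (window, 5% fraction, 0.05 significance, B=500
    permutations, top 100 terms) are configuration with the published
    defaults, never constants inside the algorithms.
    """

    genes: Path
    res: Path
    tags: dict[str, Path]  # cell line -> tag BED
    pathways: Path
    terms: Path
    out_dir: Path
    upstream: int = 5000
    downstream: int = 5000
    fraction: float = 0.05
    re_classes: tuple[str, ...] = tuple(sorted(DEFAULT_RE_CLASSES))
    alpha: float = 0.05
    confident_negative: float = 0.95
    n_permutations: int = 500
    top_terms: int = 100
    seed: int = 0
    pii_statistic: str = "mean"
    term_variant: str = "standard"
    ncrna_classes: tuple[str, ...] = ("lncRNA", "miRNA")
    bins: int = 50

    def __post_init__(self):
        for name in ("genes", "res", "pathways", "terms", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        self.tags = {line: Path(p) for line, p in self.tags.items()}
        if not 0 < self.alpha < 1 or not 0 < self.confident_negative < 1:
            raise ConfigError("thresholds must lie in (0, 1)")
        if not self.tags:
            raise ConfigError("at least one cell-line tag track is required")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def input_paths(self) -> dict[str, Path]:
        paths = {"genes": self.genes, "res": self.res, "pathways": self.pathways, "terms": self.terms}
        for line, p in self.tags.items():
            paths[f"tags_{line}"] = p
        return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    written.append(path)


def _trend_tsv(fit: TrendFit) -> pd.DataFrame:
    out = fit.frame.rename(columns={fit.id_col: "item_id"})
    return out.loc[:, ["item_id", fit.x_col, fit.y_col, "residual", "label"]]


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    for name, path in config.input_paths().items():
        if not path.exists():
            raise PipelineError("validate_inputs", f"missing input file {path} ({name})")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        report: dict = {
            "version": __version__,
            "seed": config.seed,
            "inputs": {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in sorted(config.input_paths().items())
            },
            "parameters": {
                "upstream": config.upstream,
                "downstream": config.downstream,
                "fraction": config.fraction,
                "alpha": config.alpha,
                "n_permutations": config.n_permutations,
                "top_terms": config.top_terms,
                "pii_statistic": config.pii_statistic,
                "term_variant": config.term_variant,
            },
        }

        stage = "read_inputs"
        t0 = time.perf_counter()
        genes = read_gene_table(config.genes)
        res = read_repeatmasker(config.res, config.re_classes)
        pathways = read_gmt(config.pathways)
        terms = read_gmt(config.terms)
        logger.info("read %d genes, %d REs, %d pathways, %d terms [%.1fs]",
                    len(genes), len(res), len(pathways), len(terms), time.perf_counter() - t0)
        report["n_genes"] = len(genes)
        report["cell_lines"] = sorted(config.tags)

        stage = "count_and_score"
        spec = NeighborhoodSpec(config.upstream, config.downstream)
        per_line = []
        for line in sorted(config.tags):
            t0 = time.perf_counter()
            tag_ivs = read_bed(config.tags[line])
            counts = count_tags(genes, res, tag_ivs, line, spec)
            per_line.append(compute_gene_scores(counts))
            logger.info("counted %d tags for %s [%.1fs]", len(tag_ivs), line,
                        time.perf_counter() - t0)
        gene_scores = pd.concat(per_line, ignore_index=True)
        _write_tsv(gene_scores, config.out_dir / "gene_scores.tsv", written)

        stage = "correlations"
        if len(config.tags) >= 2:
            for value in ("gre", "ngre"):
                mat = correlation_matrix(gene_scores, value)
                mat.to_csv(config.out_dir / f"correlation_{value}.tsv", sep="\t",
                           float_format=_FLOAT_FORMAT)
                written.append(config.out_dir / f"correlation_{value}.tsv")

        stage = "aggregate"
        agg = aggregate_cell_lines(gene_scores)
        _write_tsv(agg, config.out_dir / "gene_scores_aggregate.tsv", written)

        stage = "pathway_scores"
        pw_scores = compute_pathway_scores(agg, pathways, config.pii_statistic)
        _write_tsv(pw_scores, config.out_dir / "pathway_scores.tsv", written)

        stage = "classify_genes"
        gene_fit = classify_extremes(agg, config.fraction)
        _write_tsv(_trend_tsv(gene_fit), config.out_dir / "gene_labels.tsv", written)
        report["gene_trend"] = {
            "slope": gene_fit.slope,
            "n_classified": len(gene_fit.frame),
            "n_excluded": gene_fit.n_excluded,
            "extreme_set_size": gene_fit.m,
        }

        stage = "classify_pathways"
        pw_fit = classify_extremes(
            pw_scores, config.fraction, id_col="pathway_id", x_col="pii", y_col="npii"
        )
        _write_tsv(_trend_tsv(pw_fit), config.out_dir / "pathway_labels.tsv", written)
        report["pathway_trend"] = {
            "slope": pw_fit.slope,
            "n_classified": len(pw_fit.frame),
            "n_excluded": pw_fit.n_excluded,
            "extreme_set_size": pw_fit.m,
        }

        stage = "ncrna_enrichment"
        class_of = genes.set_index("gene_id")["gene_class"]
        universe_ids = gene_fit.frame[gene_fit.id_col]
        uni_classes = class_of.loc[universe_ids]
        M = len(universe_ids)
        ncrna_rows = []
        for group, ids in (("enriched", gene_fit.enriched_ids), ("deficient", gene_fit.deficient_ids)):
            for cls in config.ncrna_classes:
                N = int((uni_classes == cls).sum())
                k = int((class_of.loc[ids] == cls).sum())
                result = over_under_test(M=M, n=len(ids), N=N, k=k, alpha=config.alpha)
                ncrna_rows.append(
                    {
                        "group": group,
                        "gene_class": cls,
                        "k": k,
                        "N": N,
                        "n": len(ids),
                        "M": M,
                        "expected": result.expected,
                        "p_over": result.p_over,
                        "p_under": result.p_under,
                        "conclusion": result.conclusion,
                    }
                )
        ncrna = pd.DataFrame(ncrna_rows)
        _write_tsv(ncrna, config.out_dir / "ncrna_enrichment.tsv", written)
        report["ncrna"] = ncrna_rows

        stage = "term_enrichment"
        universe = set(universe_ids)
        term_hits = {}
        for group, ids in (("enriched", gene_fit.enriched_ids), ("deficient", gene_fit.deficient_ids)):
            tbl = term_enrichment(set(ids), universe, terms, config.term_variant)
            _write_tsv(tbl, config.out_dir / f"term_enrichment_{group}.tsv", written)
            term_hits[group] = int((tbl["p"] < config.alpha).sum())
        report["significant_terms"] = term_hits

        stage = "permutation_control"
        t0 = time.perf_counter()
        summary = permutation_null(
            agg,
            terms,
            fraction=config.fraction,
            B=config.n_permutations,
            top_terms=config.top_terms,
            seed=config.seed,
            variant=config.term_variant,
            bins=config.bins,
        )
        logger.info("permutation control B=%d [%.1fs]", config.n_permutations,
                    time.perf_counter() - t0)
        null_minima = pd.DataFrame(
            {
                "permutation": range(config.n_permutations),
                "min_p_enriched": summary.groups["enriched"].null_p_values[:, 0],
                "min_p_deficient": summary.groups["deficient"].null_p_values[:, 0],
            }
        )
        _write_tsv(null_minima, config.out_dir / "permutation_null_minima.tsv", written)
        with open(config.out_dir / "permutation_summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(config.out_dir / "permutation_summary.json")
        report["permutation"] = {g: r.to_dict() for g, r in summary.groups.items()}

        stage = "concordance"
        report["concordance"] = concordance_mcc(
            pw_fit, gene_fit, pathways, universe, config.alpha, config.term_variant
        )

        stage = "write_report"
        report["outputs"] = sorted(p.name for p in written)
        with open(config.out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    except PipelineError:
        _cleanup(written)
        raise
    except Exception as exc:
        _cleanup(written)
        raise PipelineError(stage, str(exc)) from exc


def _cleanup(written: list[Path]) -> None:
    for path in written:
        try:
            path.unlink(missing_ok=True)
        except OSError:  # pragma: no cover - best effort
            pass


def concordance_mcc(
    pathway_fit: TrendFit,
    gene_fit: TrendFit,
    pathways,
    universe: set[str],
    alpha: float,
    variant: str = "standard",
) -> dict:
    """Agreement between the two ways of calling a pathway's RRE status.

    Scheme 1 labels pathways by their own NPII-vs-PII trend position;
    scheme 2 labels a pathway enriched (deficient) when it is significantly
    overrepresented among the RRE-enriched (RRE-deficient) genes. The MCC is
    computed over pathways called non-intermediate by both schemes.
    """
    enr = term_enrichment(set(gene_fit.enriched_ids), universe, pathways, variant).set_index("term")["p"]
    def_ = term_enrichment(set(gene_fit.deficient_ids), universe, pathways, variant).set_index("term")["p"]
    scheme2 = {}
    for pw in enr.index.union(def_.index):
        p_e = float(enr.get(pw, 1.0))
        p_d = float(def_.get(pw, 1.0))
        if p_e < alpha and p_e <= p_d:
            scheme2[pw] = LABEL_ENRICHED
        elif p_d < alpha:
            scheme2[pw] = LABEL_DEFICIENT
        else:
            scheme2[pw] = NEITHER
    labels1 = pathway_fit.frame.set_index(pathway_fit.id_col)["label"]
    a = b = c = d = 0
    for pw, lab1 in labels1.items():
        lab2 = scheme2.get(pw, NEITHER)
        if lab1 == LABEL_ENRICHED and lab2 == LABEL_ENRICHED:
            a += 1
        elif lab1 == LABEL_ENRICHED and lab2 == LABEL_DEFICIENT:
            b += 1
        elif lab1 == LABEL_DEFICIENT and lab2 == LABEL_ENRICHED:
            c += 1
        elif lab1 == LABEL_DEFICIENT and lab2 == LABEL_DEFICIENT:
            d += 1
    table = {"a": a, "b": b, "c": c, "d": d}
    value = ConfusionTable2x2(a, b, c, d).mcc if a + b + c + d >= 1 else 0.0
    return {"table": table, "mcc": value, "n_pathways_compared": a + b + c + d}
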