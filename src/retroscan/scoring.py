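"""Gene-level (GRE/NGRE) and pathway-level (PII/NPII) enrichment scores.

GRE is the absolute score: the number of H3K4me1 tags on retroelement loci
in the TSS neighborhood. NGRE is the relative score: the RE-linked fraction
of all neighborhood tags, undefined for genes with zero tags (such genes are
excluded from NGRE-based analyses rather than scored 0, to avoid spurious
"deficient" calls). Pathway scores are arithmetic means of member-gene
scores; per-cell-line scores are averaged gene-by-gene across cell lines.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

AGGREGATE_LABEL = "aggregate"


def compute_gene_scores(counts: pd.DataFrame) -> pd.DataFrame:
    """GRE/NGRE per gene and cell line from tag counts.

    ``gre = re_tags``; ``ngre = re_tags / total_tags`` when the gene has any
    neighborhood tags, NaN otherwise.
    """
    if ((counts["re_tags"] < 0) | (counts["re_tags"] > counts["total_tags"])).any():
        raise DataError("tag counts violate 0 <= re_tags <= total_tags")
    out = counts.loc[:, ["gene_id", "cell_line"]].copy()
    total = counts["total_tags"].to_numpy(dtype=float)
    re_t = counts["re_tags"].to_numpy(dtype=float)
    out["gre"] = re_t
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ngre"] = np.where(total > 0, re_t / total, np.nan)
    out["total_tags"] = counts["total_tags"].to_numpy()
    return out


def aggregate_cell_lines(scores: pd.DataFrame, lines=None) -> pd.DataFrame:
    """Average scores gene-by-gene across cell lines.

    Aggregate GRE is the arithmetic mean of per-line GRE; aggregate NGRE the
    mean over the cell lines where NGRE is defined (NaN if none).
    Every gene must be present exactly once in every cell line.
    """
    df = scores if lines is None else scores[scores["cell_line"].isin(lines)]
    if lines is not None and set(lines) - set(df["cell_line"].unique()):
        raise DataError("requested cell lines missing from score table")
    n_lines = df["cell_line"].nunique()
    per_gene = df.groupby("gene_id", sort=False)["cell_line"]
    if (per_gene.count() != n_lines).any() or (per_gene.nunique() != n_lines).any():
        raise DataError("gene universes differ across cell lines")
    agg = (
        df.groupby("gene_id", sort=False)
        .agg(gre=("gre", "mean"), ngre=("ngre", "mean"), total_tags=("total_tags", "mean"))
        .reset_index()
    )
    agg.insert(1, "cell_line", AGGREGATE_LABEL)
    n_undef = int(agg["ngre"].isna().sum())
    if n_undef:
        logger.info("aggregate NGRE undefined for %d genes (no tags in any cell line)", n_undef)
    return agg


def compute_pathway_scores(
    gene_scores: pd.DataFrame,
    pathways: GeneSetCollection,
    statistic: str = "mean",
) -> pd.DataFrame:
    """PII/NPII per pathway from aggregate gene scores.

    PII aggregates member genes' GRE (arithmetic mean by default; ``sum`` is
    accepted for the absolute score), NPII is the mean of members' defined
    NGRE. Pathways with no member in the scored universe, or none with a
    defined NGRE, are omitted and logged.
    """
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    gre = gene_scores.set_index("gene_id")["gre"]
    ngre = gene_scores.set_index("gene_id")["ngre"]
    rows = []
    n_skipped = 0
    for name in pathways:
        members = [g for g in pathways[name] if g in gre.index]
        if not members:
            n_skipped += 1
            continue
        member_ngre = ngre.loc[members].dropna()
        if member_ngre.empty:
            n_skipped += 1
            continue
        member_gre = gre.loc[members]
        pii = float(member_gre.sum() if statistic == "sum" else member_gre.mean())
        rows.append(
            {
                "pathway_id": name,
                "pii": pii,
                "npii": float(member_ngre.mean()),
                "n_genes_scored": len(members),
            }
        )
    if n_skipped:
        logger.info("omitted %d pathways with no scorable member genes", n_skipped)
    return pd.DataFrame(rows, columns=["pathway_id", "pii", "npii", "n_genes_scored"])


def correlate_score_vectors(a, b) -> tuple[float, float]:
    """Pearson correlation of two gene-indexed vectors.

    Pairs are aligned on the index intersection and restricted to entries
    defined in both; requires >=3 such pairs with nonzero variance on each
    side. Returns (r, two-sided p) from the t transform.
    """
    a = pd.Series(a, dtype=float)
    b = pd.Series(b, dtype=float)
    joined = pd.concat({"a": a, "b": b}, axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise DataError(f"need >=3 shared defined entries, got {len(joined)}")
    x, y = joined["a"].to_numpy(), joined["b"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def correlation_matrix(scores: pd.DataFrame, value: str = "gre") -> pd.DataFrame:
    """Pairwise Pearson correlations of one score across cell lines."""
    wide = scores.pivot(index="gene_id", columns="cell_line", values=value)
    return wide.corr(method="pearson")
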