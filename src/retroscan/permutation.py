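"""Permutation control for the functional annotation of score extremes.

Gene names are randomly rearranged over the (GRE, NGRE) score table — the
multiset of score pairs is untouched — and the whole downstream chain
(extreme-set extraction, term enrichment) is re-run on each of B permuted
tables. For each permutation the ``top_terms`` smallest term p-values are
recorded. The test statistic is the minimum term p-value: with r the number
of permutations whose minimum is at or below the real minimum, the empirical
q-value is ``(r + 1) / (B + 1)``, so r = 0 at B = 500 gives q = 1/501 <
0.002. The retained top-p lists also support comparing the real and null
p-value distributions by their modes on the -log10 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .stats import term_pvalues
from .trend import classify_extremes

GROUPS = ("enriched", "deficient")


def empirical_q(r: int, B: int) -> float:
    """Positively-biased empirical q-value (r + 1) / (B + 1)."""
    if not 0 <= r <= B:
        raise ValueError(f"need 0 <= r <= B, got r={r}, B={B}")
    return (r + 1) / (B + 1)


def permute_gene_labels(scores: pd.DataFrame, seed) -> pd.DataFrame:
    """Randomly rearrange gene ids over score rows.

    Rows keep their (gre, ngre, ...) values jointly; only the gene_id
    assignment is permuted. *seed* may be an int or a numpy Generator; the
    same seed yields the identical permutation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = scores.copy()
    out["gene_id"] = rng.permutation(out["gene_id"].to_numpy())
    return out


def distribution_mode(p_values, bins: int = 50, value_range=None) -> float:
    """Mode of a p-value distribution on the -log10 scale.

    Builds an equal-width histogram of -log10(p) (over *value_range* when
    given, else the data range) and returns the midpoint of the densest bin;
    ties go to the smaller -log10 value.
    """
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value list")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    neglog = -np.log10(np.clip(p, np.finfo(float).tiny, 1.0))
    lo, hi = value_range if value_range is not None else (neglog.min(), neglog.max())
    if lo == hi:
        return float(lo)
    counts, edges = np.histogram(neglog, bins=bins, range=(lo, hi))
    best = int(np.argmax(counts))  # argmax takes the first (smallest) densest bin
    return float((edges[best] + edges[best + 1]) / 2)


@dataclass
class GroupPermutationResult:
    """Null-vs-real comparison for one extreme-gene group."""

    group: str
    real_p_values: np.ndarray
    null_p_values: np.ndarray  # shape (B, top_terms)
    real_min_p: float
    r: int
    q: float
    mode_real: float
    mode_null: float

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "real_min_p": self.real_min_p,
            "r": self.r,
            "q": self.q,
            "mode_real": self.mode_real,
            "mode_null": self.mode_null,
        }


@dataclass
class PermutationSummary:
    n_permutations: int
    top_terms: int
    fraction: float
    seed: int
    groups: dict[str, GroupPermutationResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "top_terms": self.top_terms,
            "fraction": self.fraction,
            "seed": self.seed,
            "groups": {g: res.to_dict() for g, res in self.groups.items()},
        }


def _top_pvalues(p: np.ndarray, top_terms: int) -> np.ndarray:
    """The top_terms smallest p-values, padded with 1.0 when fewer exist."""
    p = np.sort(p)[:top_terms]
    if len(p) < top_terms:
        p = np.concatenate([p, np.ones(top_terms - len(p))])
    return p


def permutation_null(
    scores: pd.DataFrame,
    terms: GeneSetCollection,
    fraction: float = 0.05,
    B: int = 500,
    top_terms: int = 100,
    seed: int = 0,
    variant: str = "standard",
    bins: int = 50,
) -> PermutationSummary:
    """Empirical significance control for the extreme-set annotations.

    Per-permutation seeds derive from the master *seed* by counter
    (SeedSequence spawn keys), so results are reproducible and independent
    of execution order.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(terms) == 0:
        raise ValueError("terms collection is empty")

    fit = classify_extremes(scores, fraction)
    universe = fit.frame[fit.id_col].tolist()
    uni_index = {g: i for i, g in enumerate(universe)}
    M = len(universe)

    restricted = terms.restricted_to(universe)
    term_names = list(restricted)
    membership = np.zeros((len(term_names), M), dtype=np.int8)
    for ti, name in enumerate(term_names):
        for g in restricted[name]:
            membership[ti, uni_index[g]] = 1
    K = membership.sum(axis=1)

    def group_pvalues(selected_ids) -> np.ndarray:
        sel = np.zeros(M, dtype=np.int8)
        for g in selected_ids:
            sel[uni_index[g]] = 1
        k = membership @ sel
        return term_pvalues(k, K, M, int(sel.sum()), variant)

    real = {
        "enriched": group_pvalues(fit.enriched_ids),
        "deficient": group_pvalues(fit.deficient_ids),
    }
    null_tops = {g: np.empty((B, top_terms)) for g in GROUPS}
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(b,)))
        permuted = permute_gene_labels(scores, rng)
        pfit = classify_extremes(permuted, fraction)
        null_tops["enriched"][b] = _top_pvalues(group_pvalues(pfit.enriched_ids), top_terms)
        null_tops["deficient"][b] = _top_pvalues(group_pvalues(pfit.deficient_ids), top_terms)

    summary = PermutationSummary(
        n_permutations=B, top_terms=top_terms, fraction=fraction, seed=seed
    )
    for g in GROUPS:
        real_top = _top_pvalues(real[g], top_terms)
        real_min = float(real_top[0])
        null_min = null_tops[g][:, 0]
        r = int((null_min <= real_min).sum())
        pooled = np.concatenate([real_top, null_tops[g].ravel()])
        neglog = -np.log10(np.clip(pooled, np.finfo(float).tiny, 1.0))
        rng_pool = (float(neglog.min()), float(neglog.max()))
        summary.groups[g] = GroupPermutationResult(
            group=g,
            real_p_values=real_top,
            null_p_values=null_tops[g],
            real_min_p=real_min,
            r=r,
            q=empirical_q(r, B),
            mode_real=distribution_mode(real_top, bins, rng_pool),
            mode_null=distribution_mode(null_tops[g].ravel(), bins, rng_pool),
        )
    return summary
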