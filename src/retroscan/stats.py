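"""Hypergeometric over/under-representation tests, term enrichment and the
Matthews correlation concordance measure.

The sampling model: drawing ``n`` genes without replacement from a universe
of ``M`` genes containing ``N`` genes of a class (e.g. lncRNA), the chance
of seeing exactly ``k`` class genes is

    p(k) = C(n, k) * C(M - n, N - k) / C(M, N).

The overrepresentation p-value sums the strictly-greater tail, i = k+1..n;
the underrepresentation p-value sums i = 1..k. Both tails exclude i = 0, so
``p_over + p_under + p(0) = 1``. A class is called overrepresented when
p_over < 0.05 and underrepresented when p_under < 0.05.

Term enrichment replaces an external annotation service with the same
machinery: the ``standard`` variant is the one-sided tail P(X >= k); the
``ease`` variant evaluates that tail at k - 1 (the conservative "modified
Fisher" used by annotation tools), so ease p >= standard p always.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control
from scipy.stats import hypergeom as _hg

from .errors import DataError
from .io import GeneSetCollection

OVERREPRESENTED = "overrepresented"
UNDERREPRESENTED = "underrepresented"
NEITHER = "neither"


@dataclass(frozen=True)
class HypergeomParams:
    """(M, N, n, k): universe size, class size, sample size, observed count."""

    M: int
    N: int
    n: int
    k: int

    def __post_init__(self):
        if not (0 <= self.N <= self.M and 0 <= self.n <= self.M):
            raise ValueError(f"need 0 <= N, n <= M; got {self}")
        if not 0 <= self.k <= min(self.n, self.N):
            raise ValueError(f"k={self.k} outside [0, min(n, N)] for {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    params: HypergeomParams
    expected: float
    p_over: float
    p_under: float
    conclusion: str


def hypergeom_pmf(k: int, M: int, n: int, N: int) -> float:
    """p(k): probability of exactly k class genes in a sample of n.

    Returns 0 for k outside the support (not an error). Evaluated in log
    space by scipy, so large (M, n, N) are safe.
    """
    if M <= 0 or not (0 <= N <= M and 0 <= n <= M):
        raise ValueError(f"invalid hypergeometric parameters M={M}, n={n}, N={N}")
    if k < max(0, n + N - M) or k > min(n, N):
        return 0.0
    # scipy's parameter order: (k, M=universe, n=class size, N=sample size)
    return float(_hg.pmf(k, M, N, n))


def expected_count(M: int, n: int, N: int) -> float:
    """Expected class count in the sample under random sampling: n*N/M."""
    if M <= 0:
        raise ValueError("M must be positive")
    return n * N / M


def over_under_test(M: int, n: int, N: int, k: int, alpha: float = 0.05) -> EnrichmentResult:
    """Over/under-representation test for a class count in a gene sample.

    ``p_over = P(X > k)`` and ``p_under = P(1 <= X <= k)``; the conclusion
    applies the *alpha* threshold to each tail (when both tails fall below
    alpha — possible only for degenerate parameters with most mass at 0 —
    the smaller p wins).
    """
    params = HypergeomParams(M=M, N=N, n=n, k=k)
    p_over = float(_hg.sf(k, M, N, n))
    p_under = float(np.clip(_hg.cdf(k, M, N, n) - _hg.pmf(0, M, N, n), 0.0, 1.0))
    if p_over < alpha and p_over <= p_under:
        conclusion = OVERREPRESENTED
    elif p_under < alpha:
        conclusion = UNDERREPRESENTED
    else:
        conclusion = NEITHER
    return EnrichmentResult(
        params=params,
        expected=expected_count(M, n, N),
        p_over=p_over,
        p_under=p_under,
        conclusion=conclusion,
    )


# ---------------------------------------------------------------------------
# Term enrichment


def term_pvalues(
    k: np.ndarray, K: np.ndarray, M: int, n: int, variant: str = "standard"
) -> np.ndarray:
    """Vectorized one-sided overrepresentation tails for term counts.

    ``standard``: P(X >= k). ``ease``: P(X >= k - 1). Terms with k = 0 get
    p = 1 under both variants.
    """
    if variant not in ("standard", "ease"):
        raise ValueError("variant must be 'standard' or 'ease'")
    k = np.asarray(k, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    shift = 1 if variant == "standard" else 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = _hg.sf(k - shift, M, K, n)
    return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)


def term_enrichment(
    selected,
    universe,
    terms: GeneSetCollection,
    variant: str = "standard",
) -> pd.DataFrame:
    """Per-term overrepresentation of *selected* genes within *universe*.

    Terms are intersected with the universe first; terms that empty out are
    dropped. Returns a frame with term, k (selected members), K (universe
    members), fold (observed/expected), p and Benjamini-Hochberg fdr, sorted
    by p then term name.
    """
    universe = set(universe)
    selected = set(selected)
    if not selected <= universe:
        raise DataError("selected genes must be a subset of the universe")
    M, n = len(universe), len(selected)
    names, ks, Ks = [], [], []
    for name in terms:
        members = [g for g in terms[name] if g in universe]
        if not members:
            continue
        names.append(name)
        Ks.append(len(members))
        ks.append(sum(g in selected for g in members))
    k_arr = np.asarray(ks, dtype=np.int64)
    K_arr = np.asarray(Ks, dtype=np.int64)
    p = term_pvalues(k_arr, K_arr, M, n, variant)
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where(
            (n > 0) & (K_arr > 0), (k_arr / max(n, 1)) / (K_arr / M), np.nan
        )
    out = pd.DataFrame({"term": names, "k": k_arr, "K": K_arr, "fold": fold, "p": p})
    out["fdr"] = false_discovery_control(out["p"].to_numpy(), method="bh") if len(out) else []
    return out.sort_values(["p", "term"], kind="stable", ignore_index=True)


# ---------------------------------------------------------------------------
# Concordance


@dataclass(frozen=True)
class ConfusionTable2x2:
    """Agreement table between two binary classifications.

    a: both positive; b: first positive only; c: second positive only;
    d: both negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("confusion table must contain at least one item")

    @property
    def mcc(self) -> float:
        return mcc(self.a, self.b, self.c, self.d)


def mcc(a: int, b: int, c: int, d: int) -> float:
    """Matthews correlation coefficient of a 2x2 agreement table.

    ``(a*d - b*c) / sqrt((a+b)(a+c)(d+b)(d+c))``, defined as 0 when any
    marginal is zero.
    """
    ConfusionTable2x2(a, b, c, d)  # validate
    denom2 = (a + b) * (a + c) * (d + b) * (d + c)
    if denom2 == 0:
        return 0.0
    return (a * d - b * c) / math.sqrt(denom2)
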