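"""Zero-intercept trend fit and extraction of the score extremes.

The relative score (NGRE or NPII) is regressed on the absolute score
(GRE or PII) through the origin by least squares. Items far above the trend
line carry disproportionately retroelement-linked regulatory signal
(RRE-enriched); items far below are RRE-deficient. The extremes are the
``fraction`` (default 5%) of items with the largest positive and most
negative vertical residuals, taken separately above and below the line.
Distance is the vertical residual, not perpendicular distance: the model is
the relative score as a function of the absolute one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

LABEL_ENRICHED = "enriched"
LABEL_DEFICIENT = "deficient"
LABEL_INTERMEDIATE = "intermediate"


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    This is the sizing rule for the extreme sets: it maps 5% of 24,070 to
    1204 and 5% of 3,095 to 155, consistently with both printed set sizes.
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def fit_zero_intercept(x, y) -> float:
    """Least-squares slope of ``y = beta * x`` (intercept fixed at zero).

    ``beta = sum(x*y) / sum(x**2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise DataError("need at least 2 points to fit")
    sx2 = float(x @ x)
    if sx2 == 0.0:
        raise DataError("degenerate fit: all x are zero")
    return float(x @ y) / sx2


@dataclass
class TrendFit:
    """Zero-intercept trend fit with extreme-set labels.

    ``frame`` holds one row per classified item: item_id, the x/y scores,
    the signed vertical residual and the label. Items whose relative score
    was undefined were excluded before fitting (``n_excluded``).
    """

    slope: float
    fraction: float
    m: int
    frame: pd.DataFrame
    n_excluded: int
    x_col: str = "gre"
    y_col: str = "ngre"
    id_col: str = field(default="gene_id")

    @property
    def enriched_ids(self) -> list[str]:
        return self.frame.loc[self.frame["label"] == LABEL_ENRICHED, self.id_col].tolist()

    @property
    def deficient_ids(self) -> list[str]:
        return self.frame.loc[self.frame["label"] == LABEL_DEFICIENT, self.id_col].tolist()


def classify_extremes(
    scores: pd.DataFrame,
    fraction: float = 0.05,
    *,
    id_col: str = "gene_id",
    x_col: str = "gre",
    y_col: str = "ngre",
) -> TrendFit:
    """Fit the trend line and label the extreme items.

    Items with undefined (NaN) scores are excluded before fitting. The
    ``m = round_half_away(fraction * N)`` items with the largest residuals
    are labelled enriched and the ``m`` most negative ones deficient;
    everything else is intermediate. Ties are broken deterministically by
    item id under a single (residual, id) ordering, so repeated runs yield
    identical labels.
    """
    if not 0 < fraction <= 0.5:
        raise ConfigError(f"fraction must be in (0, 0.5], got {fraction}")
    df = scores.loc[:, [id_col, x_col, y_col]].copy()
    defined = df[x_col].notna() & df[y_col].notna()
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.info("excluded %d items with undefined %s before fitting", n_excluded, y_col)
    df = df.loc[defined].reset_index(drop=True)
    n = len(df)
    if n < 2 / fraction:
        raise DataError(f"need at least {math.ceil(2 / fraction)} defined items, got {n}")
    slope = fit_zero_intercept(df[x_col], df[y_col])
    df["residual"] = df[y_col] - slope * df[x_col]
    m = round_half_away(fraction * n)
    if 2 * m > n:
        raise DataError(f"extreme sets of size {m} overlap on {n} items")

    order = df.sort_values(["residual", id_col], ascending=[True, True], kind="stable")
    labels = pd.Series(LABEL_INTERMEDIATE, index=df.index)
    labels.loc[order.index[:m]] = LABEL_DEFICIENT
    labels.loc[order.index[n - m:]] = LABEL_ENRICHED
    df["label"] = labels
    return TrendFit(
        slope=slope,
        fraction=fraction,
        m=m,
        frame=df,
        n_excluded=n_excluded,
        x_col=x_col,
        y_col=y_col,
        id_col=id_col,
    )
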