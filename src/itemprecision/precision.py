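"""Per-item precision, the decile SE cutoff, and stopping-rule checks.

The precision quantity controlled throughout is the item standard error,
SE = SD / sqrt(n), with the sample SD on the n−1 denominator.  The cutoff
is an empirical quantile of the pilot items' SEs (the 4th decile by
default): items whose SE falls below it count as well measured, and the
same value doubles as the stopping rule for adaptive data collection.

The heterogeneity summary carried into the sample-size correction is the
proportion of possible variance: the SD of the item SDs divided by half
the scale range (the largest SD a bounded scale admits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ScaleSpec, ScoreTable

__all__ = [
    "ItemPrecision",
    "CutoffResult",
    "item_precision",
    "decile_cutoff",
    "proportion_of_variance",
    "calculate_cutoff",
    "check_stop",
]


@dataclass(frozen=True)
class ItemPrecision:
    """Precision summary of one item: n, mean, SD, and SE = SD/sqrt(n)."""

    item: str
    n: int
    mean: float
    sd: float
    se: float


@dataclass(frozen=True)
class CutoffResult:
    """Outputs of the cutoff step.

    Attributes
    ----------
    per_item : list of ItemPrecision
    decile : float
        Quantile level used for the cutoff (default 0.4).
    se_cutoff : float
        SE at that quantile of the per-item SEs — the cutoff and stopping rule.
    sd_item_sd : float
        SD (n−1 denominator) of the per-item sample SDs.
    prop_var : float
        sd_item_sd divided by half the scale range.
    pilot_n : int
        Representative pilot size: ceiling of the mean per-item n.
    scale : ScaleSpec
    """

    per_item: list[ItemPrecision]
    decile: float
    se_cutoff: float
    sd_item_sd: float
    prop_var: float
    pilot_n: int
    scale: ScaleSpec = field(repr=False, default=None)

    @property
    def ses(self) -> np.ndarray:
        return np.array([p.se for p in self.per_item])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.per_item])

    def to_dict(self) -> dict:
        return {
            "decile": self.decile,
            "se_cutoff": self.se_cutoff,
            "sd_item_sd": self.sd_item_sd,
            "prop_var": self.prop_var,
            "pilot_n": self.pilot_n,
            "n_items": len(self.per_item),
        }


def item_precision(data: ScoreTable) -> list[ItemPrecision]:
    """Per-item n, mean, sample SD (n−1), and SE for every retained item."""
    out = []
    for item, scores in data.scores_by_item().items():
        n = scores.size
        if n < 2:  # ScoreTable already drops these; belt and braces
            continue
        sd = float(np.std(scores, ddof=1))
        out.append(
            ItemPrecision(
                item=item, n=int(n), mean=float(np.mean(scores)),
                sd=sd, se=sd / math.sqrt(n),
            )
        )
    return out


def decile_cutoff(ses, decile: float = 0.4) -> float:
    """Empirical quantile of the SE values by order-statistic interpolation.

    Uses the position h = (n−1)·q + 1 on the sorted values with linear
    interpolation between the bracketing order statistics (the common
    "type 7" convention).
    """
    ses = np.asarray(ses, dtype=float)
    if ses.size < 2:
        raise ValueError("need at least 2 SE values for a quantile cutoff")
    if not 0 < decile < 1:
        raise ValueError("decile must lie strictly between 0 and 1")
    x = np.sort(ses)
    h = (x.size - 1) * decile  # 0-based fractional index
    lo = int(np.floor(h))
    frac = h - lo
    if frac == 0:
        return float(x[lo])
    return float(x[lo] + frac * (x[lo + 1] - x[lo]))


def proportion_of_variance(sd_item_sd: float, scale: ScaleSpec) -> float:
    """SD of item SDs as a proportion of the scale's largest possible SD.

    Computed as sd_item_sd / sqrt((max − min)² / 4), i.e. divided by half
    the range.  Dimensionless and invariant to rescaling scores and bounds
    together.
    """
    if sd_item_sd < 0:
        raise ValueError("sd_item_sd must be non-negative")
    half = scale.half_range
    if half <= 0:
        raise ValueError("scale range must be positive")
    return sd_item_sd / half


def calculate_cutoff(
    data: ScoreTable,
    scale: ScaleSpec | None = None,
    decile: float = 0.4,
) -> CutoffResult:
    """Bundle the whole cutoff step for a pilot table.

    Computes per-item precision, the decile SE cutoff, the SD of item SDs
    and its proportion of possible variance, and the representative pilot n
    (ceiling of the mean per-item n).  When ``scale`` is omitted it is taken
    from the table or inferred from the data.
    """
    if scale is None:
        scale = data.scale or ScaleSpec.infer(data.data["score"])
    per_item = item_precision(data)
    ses = np.array([p.se for p in per_item])
    sds = np.array([p.sd for p in per_item])
    ns = np.array([p.n for p in per_item])
    sd_item_sd = float(np.std(sds, ddof=1)) if sds.size > 1 else 0.0
    return CutoffResult(
        per_item=per_item,
        decile=decile,
        se_cutoff=decile_cutoff(ses, decile),
        sd_item_sd=sd_item_sd,
        prop_var=proportion_of_variance(sd_item_sd, scale),
        pilot_n=int(math.ceil(ns.mean())),
        scale=scale,
    )


def check_stop(current: ScoreTable, cutoff: float) -> tuple[pd.Series, bool]:
    """Stopping-rule check for adaptive designs.

    An item has stopped when its current SE is strictly below the cutoff;
    the overall flag is true when every item has stopped.

    Returns
    -------
    (per_item, all_stopped) : (pandas.Series of bool indexed by item, bool)
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    per_item = item_precision(current)
    flags = pd.Series(
        {p.item: p.se < cutoff for p in per_item}, name="stopped", dtype=bool
    )
    return flags, bool(flags.all())
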