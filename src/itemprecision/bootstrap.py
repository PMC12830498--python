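"""Bootstrap projection of item SEs across a sample-size grid.

For each candidate sample size n, each item's pilot scores are resampled
with replacement (per item — pilot items may have unequal n) and the SE of
each resample recorded.  Averaging the fraction of items whose SE falls
below the cutoff over replicates gives the percent-below curve, and the
first grid size crossing a target level is the projected sample size for
that level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data import ScoreTable

__all__ = [
    "SampleGrid",
    "SimulatedSEs",
    "ProportionSummary",
    "simulate_samples",
    "calculate_proportion",
    "projected_n",
    "NOT_REACHED",
]


@dataclass(frozen=True)
class SampleGrid:
    """Grid of candidate per-item sample sizes for the bootstrap.

    Defaults start at 20 participants in steps of 5 with 500 replicates per
    size; ``stop`` is inclusive.
    """

    start: int = 20
    stop: int = 300
    step: int = 5
    nsim: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start < 2:
            raise ValueError("grid start must be at least 2")
        if self.stop < self.start:
            raise ValueError("grid stop must be >= start")
        if self.step < 1 or self.nsim < 1:
            raise ValueError("step and nsim must be positive")

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 1, self.step)


class SimulatedSEs(NamedTuple):
    """Bootstrap SE array of shape (n_sizes, nsim, n_items) plus labels."""

    sizes: np.ndarray
    items: list[str]
    ses: np.ndarray


class ProportionSummary:
    """Percent-below-cutoff curve over the sample-size grid.

    Wraps a DataFrame with columns ``sample_size`` and ``percent_below``
    (the mean over replicates of the fraction of items with SE below the
    cutoff, in [0, 1]).
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"sample_size", "percent_below"}
        if not required <= set(frame.columns):
            raise KeyError(f"summary needs columns {sorted(required)}")
        self.frame = frame.sort_values("sample_size").reset_index(drop=True)

    @classmethod
    def from_pairs(cls, pairs) -> "ProportionSummary":
        return cls(pd.DataFrame(pairs, columns=["sample_size", "percent_below"]))

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ProportionSummary({len(self)} sizes)"


def simulate_samples(pilot: ScoreTable, grid: SampleGrid) -> SimulatedSEs:
    """Bootstrap item SEs for every grid size × replicate × item.

    Per item and size n, ``grid.nsim`` resamples of n scores are drawn with
    replacement from that item's pilot scores; each resample's SE
    (SD on n−1 over sqrt(n)) is recorded.  Deterministic under ``grid.seed``.
    """
    by_item = pilot.scores_by_item()
    items = list(by_item)
    sizes = grid.sizes
    ses = np.empty((sizes.size, grid.nsim, len(items)))
    rng = np.random.default_rng(grid.seed)
    for j, item in enumerate(items):
        scores = by_item[item]
        for i, n in enumerate(sizes):
            idx = rng.integers(0, scores.size, size=(grid.nsim, int(n)))
            draws = scores[idx]
            ses[i, :, j] = draws.std(axis=1, ddof=1) / math.sqrt(n)
    return SimulatedSEs(sizes=sizes, items=items, ses=ses)


def calculate_proportion(sim: SimulatedSEs, cutoff: float) -> ProportionSummary:
    """Average percent of items below the cutoff, per sample size.

    The fraction of items with SE strictly below the cutoff is computed per
    replicate, then averaged over replicates (replicate-then-average order).
    A zero cutoff is allowed and classifies nothing as below.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    below = (sim.ses < cutoff).mean(axis=2)  # fraction of items, per replicate
    percent = below.mean(axis=1)  # average over replicates
    return ProportionSummary(
        pd.DataFrame({"sample_size": sim.sizes, "percent_below": percent})
    )


#: Sentinel returned when no grid size reaches the target level.
NOT_REACHED = None


def projected_n(
    summary: ProportionSummary, level: float
) -> tuple[int, float] | None:
    """Smallest grid size whose percent-below reaches ``level``.

    Returns the first-crossing ``(sample_size, achieved_percent)`` on the
    averaged curve, or ``None`` when no size qualifies.  The achieved
    percent may exceed the nominal level (the curve is discrete).
    """
    if len(summary) == 0:
        raise ValueError("empty proportion summary")
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    hits = summary.frame[summary.frame["percent_below"] >= level]
    if hits.empty:
        return NOT_REACHED
    row = hits.iloc[0]
    return int(row["sample_size"]), float(row["percent_below"])
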