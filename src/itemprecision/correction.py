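"""Sample-size corrections and final plan assembly.

Raw bootstrap projections grow almost linearly with the pilot size — more
pilot information should not demand ever more participants.  Two corrections
address this:

* the decay factor, ``1 − sqrt((N_pilot − min_sim)/N_pilot)^log2(N_pilot)``,
  multiplies the projection so that recommendations level off as pilot size
  grows (and leave the smallest pilots untouched);
* a nine-term regression approximation of the decay-corrected size from
  quantities a researcher actually has — projected N, pilot N, proportion of
  possible variance, and the achieved percent ("power") — with each variable
  entering both raw and log2-transformed.

A retention adjustment then inflates the corrected size by 1/p_retained to
offset expected trial-level data loss, rounding up to whole participants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import NOT_REACHED, ProportionSummary, projected_n

__all__ = [
    "CorrectionCoefficients",
    "FOURTH_DECILE_COEFFS",
    "ALL_DECILE_COEFFS",
    "PlanRow",
    "PlanResult",
    "decay_factor",
    "apply_decay",
    "regression_correction",
    "loss_adjust",
    "calculate_correction",
]


@dataclass(frozen=True)
class CorrectionCoefficients:
    """Coefficients of the nine-term sample-size correction regression.

    Power enters in percent units (80, not 0.80).
    """

    intercept: float
    b_projected: float
    b_pilot: float
    b_log2_projected: float
    b_log2_pilot: float
    b_log2_power: float
    b_prop_var: float
    b_log2_prop_var: float
    b_power: float

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if not math.isfinite(value):
                raise ValueError(f"coefficient {name} is not finite")


#: Default coefficient set, fitted for the 4th-decile cutoff (the
#: recommended cutoff level).
FOURTH_DECILE_COEFFS = CorrectionCoefficients(
    intercept=206.589,
    b_projected=0.368,
    b_pilot=-0.770,
    b_log2_projected=27.541,
    b_log2_pilot=2.583,
    b_log2_power=-66.151,
    b_prop_var=16.405,
    b_log2_prop_var=-1.367,
    b_power=1.088,
)

#: Alternate set fitted across all decile cutoffs, for non-default deciles.
ALL_DECILE_COEFFS = CorrectionCoefficients(
    intercept=111.049,
    b_projected=0.429,
    b_pilot=15.434,
    b_log2_projected=-0.718,
    b_log2_pilot=0.606,
    b_log2_power=19.522,
    b_prop_var=-0.729,
    b_log2_prop_var=4.655,
    b_power=-39.367,
)


def decay_factor(n_pilot: int, min_sim: int) -> float:
    """Leveling-off multiplier for projections from larger pilots.

    ``1 − sqrt((n_pilot − min_sim)/n_pilot)^log2(n_pilot)``.  Equals 1 when
    the pilot is no larger than the smallest simulated size (no decay) and
    decreases strictly as the pilot grows.
    """
    if min_sim < 1:
        raise ValueError("min_sim must be at least 1")
    if n_pilot < min_sim:
        raise ValueError(
            f"n_pilot ({n_pilot}) must be at least min_sim ({min_sim})"
        )
    base = math.sqrt((n_pilot - min_sim) / n_pilot)
    return 1.0 - base ** math.log2(n_pilot)


def apply_decay(projected: float, n_pilot: int, min_sim: int) -> float:
    """Projected size times the decay factor."""
    return projected * decay_factor(n_pilot, min_sim)


def regression_correction(
    projected_n: float,
    pilot_n: float,
    prop_var: float,
    power_percent: float,
    coeffs: CorrectionCoefficients = FOURTH_DECILE_COEFFS,
) -> float:
    """Regression-approximated corrected sample size (real-valued).

    Parameters are the projected size from the bootstrap, the pilot size,
    the proportion of possible variance, and the percent of items below the
    cutoff in percent units (0–100].
    """
    if projected_n < 1 or pilot_n < 1:
        raise ValueError("projected_n and pilot_n must be at least 1")
    if prop_var <= 0:
        raise ValueError(
            "prop_var must be positive (its log enters the regression); "
            "floor it at a small positive value if the pilot shows no "
            "item-SD heterogeneity"
        )
    if not 0 < power_percent <= 100:
        raise ValueError("power_percent must lie in (0, 100]")
    c = coeffs
    return (
        c.intercept
        + c.b_projected * projected_n
        + c.b_pilot * pilot_n
        + c.b_log2_projected * math.log2(projected_n)
        + c.b_log2_pilot * math.log2(pilot_n)
        + c.b_log2_power * math.log2(power_percent)
        + c.b_prop_var * prop_var
        + c.b_log2_prop_var * math.log2(prop_var)
        + c.b_power * power_percent
    )


def loss_adjust(n: float, retention: float) -> int:
    """Inflate a sample size for expected data loss and round up.

    ``retention`` is the proportion of trials retained in (0, 1]; the
    adjusted size is ceil(n / retention).
    """
    if not 0 < retention <= 1:
        raise ValueError("retention must lie in (0, 1]")
    return int(math.ceil(n / retention))


@dataclass(frozen=True)
class PlanRow:
    """Plan entry for one target level (percent units)."""

    level: float
    projected_n: int | None
    achieved_percent: float | None
    corrected_n: float | None
    final_n: int | None

    @property
    def reached(self) -> bool:
        return self.projected_n is not None


@dataclass(frozen=True)
class PlanResult:
    """Final sample-size plan across target levels.

    ``minimum_n``/``maximum_n`` are the loss-adjusted sizes at the smallest
    and largest reached levels; ``se_cutoff`` is the stopping rule for
    adaptive designs.
    """

    rows: list[PlanRow]
    se_cutoff: float
    retention: float
    minimum_n: int | None
    maximum_n: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "level": r.level,
                    "projected_n": r.projected_n,
                    "achieved_percent": r.achieved_percent,
                    "corrected_n": r.corrected_n,
                    "final_n": r.final_n,
                }
                for r in self.rows
            ]
        )

    def to_dict(self) -> dict:
        return {
            "se_cutoff": self.se_cutoff,
            "retention": self.retention,
            "minimum_n": self.minimum_n,
            "maximum_n": self.maximum_n,
            "levels": [
                {
                    "level": r.level,
                    "projected_n": r.projected_n,
                    "achieved_percent": r.achieved_percent,
                    "corrected_n": r.corrected_n,
                    "final_n": r.final_n,
                }
                for r in self.rows
            ],
        }


def calculate_correction(
    summary: ProportionSummary,
    pilot_n: int,
    prop_var: float,
    power_levels=(80, 85, 90, 95),
    retention: float = 1.0,
    coeffs: CorrectionCoefficients = FOURTH_DECILE_COEFFS,
    se_cutoff: float = float("nan"),
    grid_start: int | None = None,
    use_achieved_power: bool = True,
) -> PlanResult:
    """Assemble the final plan: projected, corrected, and loss-adjusted N.

    Per target level (percent units): the projected size is the first
    crossing of the percent-below curve; the power entering the regression
    is the achieved percent at that crossing (or the nominal level when
    ``use_achieved_power`` is false); the corrected size comes from
    :func:`regression_correction` and the final size from
    :func:`loss_adjust`.  Corrected sizes that fall below the grid start are
    floored there with a warning (the regression extrapolates poorly below
    the simulated range).  Levels the grid never reaches are kept as
    not-reached rows and excluded from the min/max designation.
    """
    if grid_start is None:
        grid_start = int(summary.frame["sample_size"].min())
    rows = []
    for level in sorted(power_levels):
        hit = projected_n(summary, level / 100.0)
        if hit is NOT_REACHED:
            rows.append(PlanRow(level, None, None, None, None))
            continue
        proj, achieved = hit
        power = achieved * 100.0 if use_achieved_power else float(level)
        corrected = regression_correction(proj, pilot_n, prop_var, power, coeffs)
        if corrected < grid_start:
            warnings.warn(
                f"corrected size {corrected:.1f} at level {level}% falls "
                f"below the simulated grid start {grid_start}; flooring",
                stacklevel=2,
            )
            corrected = float(grid_start)
        rows.append(
            PlanRow(level, proj, achieved * 100.0, corrected,
                    loss_adjust(corrected, retention))
        )
    reached = [r for r in rows if r.reached]
    return PlanResult(
        rows=rows,
        se_cutoff=se_cutoff,
        retention=retention,
        minimum_n=reached[0].final_n if reached else None,
        maximum_n=reached[-1].final_n if reached else None,
    )
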