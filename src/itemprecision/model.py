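"""Model-style front end: a planner built from pilot data, fitted by
bootstrap simulation, returning a results object with a summary table.

`PrecisionPlanner` holds the pilot data and design choices (scale bounds,
cutoff decile); `fit()` runs the six-step procedure — per-item SEs, decile
cutoff, bootstrap percent-below curves over a sample-size grid, projection
at the target levels, regression correction, retention adjustment — and
returns a `PlanResults` carrying every intermediate along with the final
minimum/stopping-rule/maximum recommendation.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from .bootstrap import ProportionSummary, SampleGrid, SimulatedSEs, \
    calculate_proportion, simulate_samples
from .correction import CorrectionCoefficients, FOURTH_DECILE_COEFFS, \
    PlanResult, calculate_correction
from .data import ScaleSpec, ScoreTable, read_score_table
from .precision import CutoffResult, calculate_cutoff, check_stop

__all__ = ["PrecisionPlanner", "PlanResults"]

# Below this pilot size, recommendations become unstable across researchers
# and item-SE estimates biased; ~30 is the practical lower bound.
_PILOT_N_ADVISORY = 30


class PrecisionPlanner:
    """Precision-based sample-size planner for a multi-item instrument.

    Parameters
    ----------
    data : ScoreTable or pandas.DataFrame
        Long-format pilot observations (participant, item, score).
    scale : ScaleSpec, optional
        Instrument bounds; inferred from the data when omitted (with a
        warning, since inferred bounds understate the possible range).
    decile : float
        Quantile of the pilot items' SEs used as cutoff/stopping rule.

    Examples
    --------
    >>> planner = PrecisionPlanner.from_csv("pilot.csv", scale=ScaleSpec(1, 5))
    >>> results = planner.fit(seed=42)
    >>> print(results.summary())
    """

    def __init__(
        self,
        data: ScoreTable | pd.DataFrame,
        scale: ScaleSpec | None = None,
        decile: float = 0.4,
    ) -> None:
        if isinstance(data, pd.DataFrame):
            data = ScoreTable(data, scale=scale)
        self.data = data
        if scale is None:
            scale = data.scale
        if scale is None:
            scale = ScaleSpec.infer(data.data["score"])
            warnings.warn(
                "scale bounds inferred from the data "
                f"([{scale.minimum}, {scale.maximum}]); declare them "
                "explicitly if the instrument's range is wider",
                stacklevel=2,
            )
        self.scale = scale
        self.decile = decile
        self._cutoff: CutoffResult | None = None

    # -- constructors -------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        participant: str = "participant",
        item: str = "item",
        score: str = "score",
        scale: ScaleSpec | None = None,
        decile: float = 0.4,
    ) -> "PrecisionPlanner":
        table = ScoreTable(
            df,
            columns={"participant": participant, "item": item, "score": score},
            scale=scale,
        )
        return cls(table, scale=scale, decile=decile)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        participant: str = "participant",
        item: str = "item",
        score: str = "score",
        scale: ScaleSpec | None = None,
        decile: float = 0.4,
    ) -> "PrecisionPlanner":
        table = read_score_table(
            path, participant=participant, item=item, score=score, scale=scale
        )
        return cls(table, scale=scale, decile=decile)

    # -- estimation ---------------------------------------------------

    @property
    def cutoff(self) -> CutoffResult:
        """The cutoff-step outputs (computed once, cached)."""
        if self._cutoff is None:
            self._cutoff = calculate_cutoff(self.data, self.scale, self.decile)
            if self._cutoff.pilot_n < _PILOT_N_ADVISORY:
                warnings.warn(
                    f"pilot size {self._cutoff.pilot_n} is below the "
                    f"recommended ~{_PILOT_N_ADVISORY} participants; "
                    "recommendations from very small pilots are unstable",
                    stacklevel=2,
                )
        return self._cutoff

    def fit(
        self,
        grid: SampleGrid | None = None,
        power_levels=(80, 85, 90, 95),
        retention: float = 1.0,
        coeffs: CorrectionCoefficients = FOURTH_DECILE_COEFFS,
        use_achieved_power: bool = True,
        seed: int | None = None,
    ) -> "PlanResults":
        """Run the bootstrap projection and corrections; return results.

        Parameters
        ----------
        grid : SampleGrid, optional
            Candidate sizes and replicate count (default 20–300 by 5,
            500 replicates).  ``seed`` overrides the grid's seed.
        power_levels : sequence of percents
            Target percentages of items below the cutoff.
        retention : float
            Expected proportion of usable trials, for the loss adjustment.
        use_achieved_power : bool
            Feed the achieved (not nominal) percent into the correction
            regression.
        """
        if grid is None:
            grid = SampleGrid()
        if seed is not None:
            grid = SampleGrid(grid.start, grid.stop, grid.step, grid.nsim, seed)
        cutoff = self.cutoff
        sim = simulate_samples(self.data, grid)
        summary = calculate_proportion(sim, cutoff.se_cutoff)
        plan = calculate_correction(
            summary,
            pilot_n=cutoff.pilot_n,
            prop_var=cutoff.prop_var,
            power_levels=power_levels,
            retention=retention,
            coeffs=coeffs,
            se_cutoff=cutoff.se_cutoff,
            grid_start=grid.start,
            use_achieved_power=use_achieved_power,
        )
        return PlanResults(self, grid, cutoff, sim, summary, plan)


class PlanResults:
    """Fitted sample-size plan with all intermediates.

    Attributes
    ----------
    cutoff : CutoffResult
    proportion_summary : ProportionSummary
    plan : PlanResult
    """

    def __init__(
        self,
        model: PrecisionPlanner,
        grid: SampleGrid,
        cutoff: CutoffResult,
        simulated: SimulatedSEs,
        proportion_summary: ProportionSummary,
        plan: PlanResult,
    ) -> None:
        self.model = model
        self.grid = grid
        self.cutoff = cutoff
        self.simulated = simulated
        self.proportion_summary = proportion_summary
        self.plan = plan

    # convenience passthroughs
    @property
    def se_cutoff(self) -> float:
        return self.cutoff.se_cutoff

    @property
    def minimum_n(self) -> int | None:
        return self.plan.minimum_n

    @property
    def maximum_n(self) -> int | None:
        return self.plan.maximum_n

    def check_stop(self, current: ScoreTable | pd.DataFrame):
        """Apply the stopping rule to interim data from the main study."""
        if isinstance(current, pd.DataFrame):
            current = ScoreTable(current)
        return check_stop(current, self.se_cutoff)

    def to_dict(self) -> dict:
        return {
            "package": {"name": "itemprecision", "version": __version__},
            "config": {
                "scale": {
                    "minimum": self.model.scale.minimum,
                    "maximum": self.model.scale.maximum,
                    "discrete": self.model.scale.discrete,
                },
                "decile": self.model.decile,
                "grid": {
                    "start": int(self.grid.start),
                    "stop": int(self.grid.stop),
                    "step": int(self.grid.step),
                    "nsim": int(self.grid.nsim),
                    "seed": int(self.grid.seed),
                },
            },
            "cutoff": self.cutoff.to_dict(),
            "proportion_summary": self.proportion_summary.frame.to_dict("records"),
            "plan": self.plan.to_dict(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        """Human-readable report of the plan."""
        c = self.cutoff
        lines = [
            "Precision-based sample-size plan",
            "=" * 48,
            f"Items: {len(c.per_item)}    Pilot n: {c.pilot_n}",
            f"Scale: [{self.model.scale.minimum}, {self.model.scale.maximum}]"
            f"    Decile: {c.decile:.1f}",
            f"SE cutoff (stopping rule): {c.se_cutoff:.4f}",
            f"SD of item SDs: {c.sd_item_sd:.4f}"
            f"    Proportion of possible variance: {c.prop_var:.4f}",
            "-" * 48,
            f"{'level %':>8} {'projected':>10} {'achieved %':>11} "
            f"{'corrected':>10} {'final N':>8}",
        ]
        for r in self.plan.rows:
            if not r.reached:
                lines.append(f"{r.level:>8.0f} {'not reached on grid':>41}")
                continue
            lines.append(
                f"{r.level:>8.0f} {r.projected_n:>10d} "
                f"{r.achieved_percent:>11.2f} {r.corrected_n:>10.2f} "
                f"{r.final_n:>8d}"
            )
        lines += [
            "-" * 48,
            f"Retention assumed: {self.plan.retention:.2f}",
            f"Minimum N: {self.plan.minimum_n}    "
            f"Stopping rule SE: {c.se_cutoff:.4f}    "
            f"Maximum N: {self.plan.maximum_n}",
        ]
        return "\n".join(lines)

    def plot_curve(self, ax=None):  # pragma: no cover - convenience plotting
        """Plot the percent-below-cutoff curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.proportion_summary.frame
        ax.plot(f["sample_size"], 100 * f["percent_below"], marker="o", ms=3)
        for r in self.plan.rows:
            if r.reached:
                ax.axvline(r.projected_n, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("sample size per item")
        ax.set_ylabel("% items with SE below cutoff")
        return ax

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PlanResults(min={self.plan.minimum_n}, "
            f"stop_se={self.se_cutoff:.4g}, max={self.plan.maximum_n})"
        )
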