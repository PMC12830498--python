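"""Simulation harness for validating the planning procedure.

Replicates, at configurable scale, the factorial validation design: simulate
populations across scale types × heterogeneity levels × shapes, let
"researchers" draw pilots and run the procedure, and summarise how stable
and unbiased the recommendations are as pilot size varies.  Also sweeps the
fraction of bimodal items to probe mixture distributions.

Full-scale replication of the original factorial (hundreds of researchers ×
hundreds of replicates) is reachable through the grid parameters; defaults
are reduced so a sweep runs in minutes, since the quantities of interest are
trends, not figure-exact values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bootstrap import NOT_REACHED, SampleGrid, calculate_proportion, \
    projected_n, simulate_samples
from .correction import apply_decay, regression_correction
from .data import ScoreTable
from .precision import calculate_cutoff, decile_cutoff
from .simulate import PopulationConfig, draw_pilot, preset_config, \
    simulate_population

__all__ = [
    "ConditionGrid",
    "ConditionResult",
    "run_condition",
    "evaluate_pilot_sizes",
    "bimodal_sweep",
]


@dataclass(frozen=True)
class ConditionGrid:
    """Factorial design of the pilot-size evaluation."""

    scales: Sequence[str] = ("likert", "percent", "milliseconds")
    heterogeneity: Sequence[str] = ("small", "medium", "large")
    shapes: Sequence[str] = ("symmetric", "ceiling")
    pilot_sizes: Sequence[int] = (20, 30, 40)
    n_researchers: int = 20
    grid: SampleGrid = field(
        default_factory=lambda: SampleGrid(start=20, stop=600, step=20, nsim=50)
    )
    levels: Sequence[float] = (80, 85, 90, 95)
    decile: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.scales and self.heterogeneity and self.shapes
                and self.pilot_sizes):
            raise ValueError("every factor needs at least one level")


@dataclass(frozen=True)
class ConditionResult:
    """Per-level outcome of one researcher run on one condition."""

    table: pd.DataFrame  # columns: level, projected_n, achieved, decay_n, corrected_n
    se_cutoff: float
    prop_var: float
    pilot_n: int


def run_condition(
    config: PopulationConfig,
    pilot_size: int,
    grid: SampleGrid,
    levels: Sequence[float] = (80, 85, 90, 95),
    decile: float = 0.4,
) -> ConditionResult:
    """One simulated researcher: population → pilot → projection → corrections.

    Returns per-level projected sizes plus the decay-corrected size (the
    harness's ground truth) and the regression-corrected size for
    comparison.  Deterministic under ``config.seed`` and ``grid.seed``.
    """
    population = simulate_population(config)
    pilot = draw_pilot(population, pilot_size, seed=grid.seed + 1)
    cutoff = calculate_cutoff(pilot, config.scale, decile)
    sim = simulate_samples(pilot, grid)
    summary = calculate_proportion(sim, cutoff.se_cutoff)
    degenerate = cutoff.se_cutoff == 0  # every pilot item constant
    rows = []
    for level in levels:
        # a zero cutoff means items are already measured exactly; the
        # smallest simulated size suffices at every level
        hit = (
            (int(grid.start), 1.0) if degenerate
            else projected_n(summary, level / 100.0)
        )
        if hit is NOT_REACHED:
            rows.append(
                dict(level=level, projected_n=np.nan, achieved=np.nan,
                     decay_n=np.nan, corrected_n=np.nan)
            )
            continue
        proj, achieved = hit
        decay_n = apply_decay(proj, cutoff.pilot_n, int(grid.start))
        corrected = (
            regression_correction(
                proj, cutoff.pilot_n, cutoff.prop_var, achieved * 100.0
            )
            if cutoff.prop_var > 0  # log of prop_var undefined at 0
            else np.nan
        )
        rows.append(
            dict(level=level, projected_n=proj, achieved=achieved * 100.0,
                 decay_n=decay_n, corrected_n=corrected)
        )
    return ConditionResult(
        table=pd.DataFrame(rows),
        se_cutoff=cutoff.se_cutoff,
        prop_var=cutoff.prop_var,
        pilot_n=cutoff.pilot_n,
    )


def _population_sds(population: ScoreTable) -> pd.Series:
    by_item = population.scores_by_item()
    return pd.Series(
        {item: float(np.std(s, ddof=1)) for item, s in by_item.items()}
    )


def evaluate_pilot_sizes(grid: ConditionGrid) -> pd.DataFrame:
    """Stability and bias of recommendations as pilot size varies.

    For each condition × pilot size, ``n_researchers`` researchers each draw
    a pilot from the same population and run the procedure.  Reported per
    cell:

    * ``sd_recommended_n`` — SD across researchers of the decay-corrected
      recommendation, averaged over levels (instability measure);
    * ``rel_se_bias`` — mean over items and researchers of
      (estimated SE − true SE)/true SE, where the true SE is the population
      item SD over sqrt(pilot size);
    * ``rel_cutoff_bias`` — mean over researchers of (pilot cutoff −
      population cutoff)/population cutoff, the population cutoff being the
      decile of the population item SEs at the same pilot size.
    """
    rng_root = np.random.SeedSequence(grid.seed)
    records = []
    for scale in grid.scales:
        for het in grid.heterogeneity:
            for shape in grid.shapes:
                cond_seed = rng_root.spawn(1)[0]
                pop_seed = int(cond_seed.generate_state(1)[0] % (2**31))
                config = preset_config(f"{scale}-{het}-{shape}", seed=pop_seed)
                population = simulate_population(config)
                pop_sds = _population_sds(population)
                for pilot_size in grid.pilot_sizes:
                    true_se = pop_sds / np.sqrt(pilot_size)
                    pop_cutoff = decile_cutoff(true_se.to_numpy(), grid.decile)
                    recs, se_biases, cut_biases = [], [], []
                    for r in range(grid.n_researchers):
                        pilot_seed = pop_seed + 1000 * pilot_size + r
                        pilot = draw_pilot(population, pilot_size, pilot_seed)
                        cutoff = calculate_cutoff(pilot, config.scale, grid.decile)
                        est_se = pd.Series(
                            {p.item: p.se for p in cutoff.per_item}
                        )
                        se_biases.append(
                            float(((est_se - true_se) / true_se).mean())
                        )
                        cut_biases.append(
                            (cutoff.se_cutoff - pop_cutoff) / pop_cutoff
                        )
                        sim = simulate_samples(
                            pilot, replace(grid.grid, seed=pilot_seed + 7)
                        )
                        summary = calculate_proportion(sim, cutoff.se_cutoff)
                        level_recs = []
                        for level in grid.levels:
                            hit = projected_n(summary, level / 100.0)
                            if hit is not NOT_REACHED:
                                level_recs.append(
                                    apply_decay(hit[0], cutoff.pilot_n,
                                                int(grid.grid.start))
                                )
                        if level_recs:
                            recs.append(level_recs)
                    if recs:
                        width = max(map(len, recs))
                        rec_arr = np.array([r for r in recs if len(r) == width])
                    else:
                        rec_arr = np.empty((0, 0))
                    sd_rec = (
                        float(np.mean(rec_arr.std(axis=0, ddof=1)))
                        if rec_arr.ndim == 2 and rec_arr.shape[0] > 1
                        else np.nan
                    )
                    records.append(
                        dict(
                            scale=scale, heterogeneity=het, shape=shape,
                            pilot_size=pilot_size,
                            sd_recommended_n=sd_rec,
                            rel_se_bias=float(np.mean(se_biases)),
                            rel_cutoff_bias=float(np.mean(cut_biases)),
                        )
                    )
    return pd.DataFrame(records)


def bimodal_sweep(
    fractions: Sequence[float] = tuple(np.round(np.arange(0, 1.01, 0.1), 1)),
    base: PopulationConfig | None = None,
    pilot_size: int = 30,
    grid: SampleGrid | None = None,
    levels: Sequence[float] = (80, 85, 90, 95),
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Recommended N as the fraction of bimodal items varies.

    Base condition is the small-heterogeneity 1–7 rating configuration.
    Returns one row per fraction × level with the replicate-averaged
    projected and decay-corrected sizes plus the across-item SD of SEs
    (the mechanism: a few bimodal items raise SE heterogeneity, all-bimodal
    lowers it again).
    """
    if base is None:
        base = preset_config("likert-small-symmetric")
    if grid is None:
        grid = SampleGrid(start=20, stop=600, step=20, nsim=50)
    records = []
    for frac in fractions:
        per_level: dict[float, list] = {lv: [] for lv in levels}
        se_sds = []
        for rep in range(n_replicates):
            config = replace(base, bimodal_fraction=float(frac),
                             seed=base.seed + 7919 * rep)
            rep_grid = replace(grid, seed=grid.seed + 104729 * rep)
            res = run_condition(config, pilot_size, rep_grid, levels)
            for _, row in res.table.iterrows():
                per_level[row["level"]].append(
                    (row["projected_n"], row["decay_n"])
                )
            se_sds.append(res.prop_var)
        for lv in levels:
            vals = np.array(per_level[lv], dtype=float)
            records.append(
                dict(
                    bimodal_fraction=float(frac),
                    level=lv,
                    projected_n=float(np.nanmean(vals[:, 0])),
                    decay_n=float(np.nanmean(vals[:, 1])),
                    prop_var=float(np.mean(se_sds)),
                )
            )
    return pd.DataFrame(records)
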