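"""Synthetic populations and pilot samples for multi-item instruments.

Each item's scores are drawn from a normal distribution whose mean and SD
are themselves drawn across items (a two-level hierarchy): item means come
from Normal(mu, sigma_mu) and item SDs from Normal(sigma, sigma_sigma),
truncated to stay positive.  Scores are rounded to whole numbers — most
instruments record integers — and clamped to the scale endpoints, which is
the only mechanism by which skew (ceiling/floor pile-up) enters.

Bimodal items are half-ceiling/half-floor mixtures, stressing the case where
an aggregate distribution hides two sub-populations of responders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ScaleSpec, ScoreTable

__all__ = [
    "PopulationConfig",
    "PRESETS",
    "preset_config",
    "simulate_population",
    "make_bimodal_item",
    "draw_pilot",
]

# Ratio below which a drawn item SD is rejected and redrawn; negative or
# near-zero SDs are impossible quantities, and sigma >= 2.5*sigma_sigma in
# every preset so rejections are rare and barely perturb the target moments.
_SD_FLOOR_FRACTION = 0.01
_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of a simulated item population.

    Parameters
    ----------
    n_items : int
        Number of items in the instrument.
    n_obs : int
        Observations per item in the population draw.
    mu : float
        Grand mean of item means (score units).
    sigma_mu : float
        SD of item means across items.
    sigma : float
        Grand item SD (within-item spread).
    sigma_sigma : float
        SD of item SDs across items — the heterogeneity knob.
    scale : ScaleSpec
        Scale bounds; scores are rounded then clamped to these.
    shape : {"symmetric", "ceiling", "floor"}
        Where the drawing mean sits.  ``mu`` is interpreted as the symmetric
        mean; ``ceiling_mu`` is used for ceiling items and its mirror about
        the scale midpoint for floor items.
    ceiling_mu : float
        Drawing mean for ceiling-shaped items.
    bimodal_fraction : float
        Proportion of items built as half-ceiling + half-floor mixtures.
    seed : int
        Seed for the hierarchical random stream.
    """

    n_items: int = 30
    n_obs: int = 1000
    mu: float = 4.0
    sigma_mu: float = 0.25
    sigma: float = 2.0
    sigma_sigma: float = 0.2
    scale: ScaleSpec = field(default_factory=lambda: ScaleSpec(1, 7, discrete=True))
    shape: str = "symmetric"
    ceiling_mu: float = 6.0
    bimodal_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.bimodal_fraction <= 1:
            raise ValueError("bimodal_fraction must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_obs < 2:
            raise ValueError("n_obs must be at least 2")
        if self.shape not in {"symmetric", "ceiling", "floor"}:
            raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def floor_mu(self) -> float:
        """Mirror of the ceiling mean about the scale midpoint."""
        return self.scale.minimum + self.scale.maximum - self.ceiling_mu

    def drawing_mu(self) -> float:
        if self.shape == "symmetric":
            return self.mu
        if self.shape == "ceiling":
            return self.ceiling_mu
        return self.floor_mu


# The three instrument archetypes × three heterogeneity levels.  Keys:
# likert (1-7 rating), percent (0-100), milliseconds (0-3000 latency).
_SCALE_PARAMS = {
    "likert": dict(
        mu=4.0, ceiling_mu=6.0, sigma_mu=0.25, sigma=2.0,
        scale=ScaleSpec(1, 7, discrete=True),
        sigma_sigma={"small": 0.2, "medium": 0.4, "large": 0.8},
    ),
    "percent": dict(
        mu=50.0, ceiling_mu=85.0, sigma_mu=10.0, sigma=25.0,
        scale=ScaleSpec(0, 100, discrete=True),
        sigma_sigma={"small": 4.0, "medium": 8.0, "large": 16.0},
    ),
    "milliseconds": dict(
        mu=1000.0, ceiling_mu=2500.0, sigma_mu=150.0, sigma=400.0,
        scale=ScaleSpec(0, 3000, discrete=True),
        sigma_sigma={"small": 50.0, "medium": 100.0, "large": 200.0},
    ),
}

PRESETS = tuple(
    f"{scale}-{het}-{shape}"
    for scale in _SCALE_PARAMS
    for het in ("small", "medium", "large")
    for shape in ("symmetric", "ceiling")
)


def preset_config(name: str, **overrides) -> PopulationConfig:
    """Build a :class:`PopulationConfig` from a preset name.

    Names have the form ``<scale>-<heterogeneity>[-<shape>]``, e.g.
    ``likert-small-symmetric`` or ``percent-large-ceiling``; shape defaults
    to symmetric.  Keyword overrides are applied on top.
    """
    parts = name.lower().split("-")
    if len(parts) == 2:
        parts.append("symmetric")
    if len(parts) != 3:
        raise ValueError(f"preset name {name!r} not of form scale-heterogeneity-shape")
    scale_name, het, shape = parts
    if scale_name not in _SCALE_PARAMS:
        raise ValueError(f"unknown scale {scale_name!r}; choose from {list(_SCALE_PARAMS)}")
    params = _SCALE_PARAMS[scale_name]
    if het not in params["sigma_sigma"]:
        raise ValueError(f"unknown heterogeneity {het!r}; choose small/medium/large")
    cfg = PopulationConfig(
        mu=params["mu"],
        ceiling_mu=params["ceiling_mu"],
        sigma_mu=params["sigma_mu"],
        sigma=params["sigma"],
        sigma_sigma=params["sigma_sigma"][het],
        scale=params["scale"],
        shape=shape,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _round_clamp(x: np.ndarray, scale: ScaleSpec) -> np.ndarray:
    """Round half away from zero, then clamp to the scale endpoints."""
    r = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return np.clip(r, scale.minimum, scale.maximum)


def _draw_item_sds(rng: np.random.Generator, n: int, sigma: float,
                   sigma_sigma: float) -> np.ndarray:
    sds = rng.normal(sigma, sigma_sigma, n)
    floor = _SD_FLOOR_FRACTION * sigma
    for _ in range(_MAX_REDRAWS):
        bad = sds < floor
        if not bad.any():
            return sds
        sds[bad] = rng.normal(sigma, sigma_sigma, int(bad.sum()))
    raise RuntimeError(
        "item-SD truncation rejected too many draws; sigma_sigma is too "
        "large relative to sigma"
    )


def make_bimodal_item(
    config: PopulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw one bimodal item: a half-ceiling + half-floor mixture.

    The ceiling half draws around ``ceiling_mu`` and the floor half around
    its mirror about the scale midpoint, both with an item SD drawn from the
    usual Normal(sigma, sigma_sigma) machinery.  For odd ``n_obs`` the
    larger half goes to the ceiling component.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_floor = config.n_obs // 2
    n_ceil = config.n_obs - n_floor
    halves = []
    for mu0, n in ((config.ceiling_mu, n_ceil), (config.floor_mu, n_floor)):
        mean = rng.normal(mu0, config.sigma_mu)
        sd = float(_draw_item_sds(rng, 1, config.sigma, config.sigma_sigma)[0])
        halves.append(rng.normal(mean, sd, n))
    return _round_clamp(np.concatenate(halves), config.scale)


def simulate_population(config: PopulationConfig) -> ScoreTable:
    """Generate a synthetic population :class:`ScoreTable` from ``config``.

    Deterministic under ``config.seed``: the item-parameter draws and each
    item's score stream come from spawned child streams, so changing
    ``bimodal_fraction`` does not reshuffle the non-bimodal items' draws.
    """
    ss = np.random.SeedSequence(config.seed)
    param_seed, *item_seeds = ss.spawn(config.n_items + 1)
    param_rng = np.random.default_rng(param_seed)

    n_bimodal = int(round(config.bimodal_fraction * config.n_items))
    means = param_rng.normal(config.drawing_mu(), config.sigma_mu, config.n_items)
    sds = _draw_item_sds(param_rng, config.n_items, config.sigma, config.sigma_sigma)

    frames = []
    for i in range(config.n_items):
        rng = np.random.default_rng(item_seeds[i])
        if i < n_bimodal:
            scores = make_bimodal_item(config, rng)
        else:
            scores = _round_clamp(
                rng.normal(means[i], sds[i], config.n_obs), config.scale
            )
        frames.append(
            pd.DataFrame(
                {
                    "participant": np.arange(1, config.n_obs + 1),
                    "item": f"item_{i + 1:02d}",
                    "score": scores,
                }
            )
        )
    return ScoreTable(pd.concat(frames, ignore_index=True), scale=config.scale)


def draw_pilot(
    population: ScoreTable, n_per_item: int, seed: int
) -> ScoreTable:
    """Sample a pilot study from a population, with replacement per item.

    Mimics a researcher collecting ``n_per_item`` observations for every
    item.  Deterministic under ``seed``.
    """
    if n_per_item < 2:
        raise ValueError("n_per_item must be at least 2")
    rng = np.random.default_rng(seed)
    frames = []
    for item, scores in population.scores_by_item().items():
        draw = rng.choice(scores, size=n_per_item, replace=True)
        frames.append(
            pd.DataFrame(
                {
                    "participant": np.arange(1, n_per_item + 1),
                    "item": item,
                    "score": draw,
                }
            )
        )
    return ScoreTable(pd.concat(frames, ignore_index=True), scale=population.scale)
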