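"""Population simulator: bounds, determinism, and moment recovery."""

import numpy as np
import pytest
from dataclasses import replace

from itemprecision import (
    PRESETS,
    PopulationConfig,
    ScaleSpec,
    draw_pilot,
    make_bimodal_item,
    preset_config,
    simulate_population,
)


def item_sds(table):
    return np.array(
        [np.std(s, ddof=1) for s in table.scores_by_item().values()]
    )


class TestPresets:
    def test_all_names_resolve(self):
        for name in PRESETS:
            cfg = preset_config(name)
            assert isinstance(cfg, PopulationConfig)

    @pytest.mark.parametrize(
        "name, sigma, lo, hi",
        [
            ("likert-small-symmetric", 2.0, 1, 7),
            ("percent-medium-ceiling", 25.0, 0, 100),
            ("milliseconds-large-symmetric", 400.0, 0, 3000),
        ],
    )
    def test_preset_parameters(self, name, sigma, lo, hi):
        cfg = preset_config(name)
        assert cfg.sigma == sigma
        assert (cfg.scale.minimum, cfg.scale.maximum) == (lo, hi)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset_config("guttman-small-symmetric")


class TestSimulatePopulation:
    def test_scores_are_integers_within_bounds(self):
        cfg = preset_config("likert-small-symmetric", seed=1)
        table = simulate_population(cfg)
        scores = table.data["score"].to_numpy()
        assert scores.min() >= 1 and scores.max() <= 7
        assert np.allclose(scores, np.round(scores))
        assert table.n_items == 30
        assert (table.n_per_item() == 1000).all()

    def test_degenerate_variance_collapses_to_rounded_mean(self):
        cfg = PopulationConfig(
            n_items=3, n_obs=50, mu=4.2, sigma_mu=0.0, sigma=1e-9,
            sigma_sigma=0.0, scale=ScaleSpec(1, 7, discrete=True), seed=2,
        )
        table = simulate_population(cfg)
        assert (table.data["score"] == 4.0).all()

    def test_grand_mean_recovers_mu(self):
        # law-of-large-numbers check against the drawing distribution
        cfg = preset_config("likert-small-symmetric", n_obs=10_000, seed=3)
        table = simulate_population(cfg)
        means = np.array([s.mean() for s in table.scores_by_item().values()])
        mc_se = cfg.sigma_mu / np.sqrt(cfg.n_items)
        # rounding+clamping of a symmetric mid-scale config is mean-preserving
        assert abs(means.mean() - 4.0) < 3 * mc_se + 0.02

    def test_seed_determinism(self):
        cfg = preset_config("percent-small-symmetric", n_obs=100, seed=11)
        a = simulate_population(cfg).data
        b = simulate_population(cfg).data
        assert a.equals(b)

    def test_ceiling_shape_left_skewed(self):
        cfg = preset_config("likert-small-ceiling", seed=4)
        table = simulate_population(cfg)
        scores = table.data["score"]
        # clamping at the top pulls the mean below the drawing mean of 6
        assert scores.mean() < 6.0
        assert scores.skew() < 0

    def test_sigma_sigma_recovered_across_heterogeneity(self):
        # empirical SD of item SDs tracks the heterogeneity knob
        got = []
        for het in ("small", "medium", "large"):
            vals = [
                item_sds(
                    simulate_population(
                        preset_config(f"milliseconds-{het}-symmetric",
                                      n_items=60, seed=s)
                    )
                ).std(ddof=1)
                for s in range(3)
            ]
            got.append(np.mean(vals))
        assert got[0] < got[1] < got[2]
        # milliseconds symmetric mid-scale barely clamps: values near nominal
        for observed, nominal in zip(got, (50, 100, 200)):
            assert abs(observed - nominal) / nominal < 0.35


class TestBimodal:
    def test_modes_near_ceiling_and_floor(self):
        cfg = PopulationConfig(
            n_items=1, n_obs=2000, sigma=0.3, sigma_sigma=0.01,
            sigma_mu=0.01, scale=ScaleSpec(1, 7, discrete=True),
            ceiling_mu=6.0, seed=5,
        )
        scores = make_bimodal_item(cfg)
        low = scores[scores <= 4]
        high = scores[scores > 4]
        assert abs(low.mean() - 2.0) < 0.2
        assert abs(high.mean() - 6.0) < 0.2

    def test_mixture_mean_is_midpoint(self):
        cfg = PopulationConfig(
            n_items=1, n_obs=10_000, sigma=0.3, sigma_sigma=0.01,
            sigma_mu=0.01, scale=ScaleSpec(1, 7, discrete=True), seed=6,
        )
        scores = make_bimodal_item(cfg)
        se = scores.std(ddof=1) / np.sqrt(scores.size)
        assert abs(scores.mean() - 4.0) < 3 * se + 0.05

    def test_odd_n_obs_gives_ceiling_the_extra(self):
        cfg = PopulationConfig(
            n_items=1, n_obs=11, sigma=0.1, sigma_sigma=0.001,
            sigma_mu=0.001, scale=ScaleSpec(1, 7, discrete=True), seed=7,
        )
        scores = make_bimodal_item(cfg)
        assert (scores > 4).sum() == 6

    def test_zero_fraction_identical_to_plain_population(self):
        base = preset_config("likert-small-symmetric", n_obs=100, seed=8)
        a = simulate_population(base).data
        b = simulate_population(replace(base, bimodal_fraction=0.0)).data
        assert a.equals(b)

    def test_fraction_sets_item_count(self):
        cfg = preset_config(
            "likert-small-symmetric", n_obs=4000, bimodal_fraction=0.5, seed=9
        )
        table = simulate_population(cfg)
        by_item = table.scores_by_item()
        sds = {k: np.std(v, ddof=1) for k, v in by_item.items()}
        # bimodal items (built first) spread wider than plain sigma=2 items
        widest = sorted(sds, key=sds.get, reverse=True)[:15]
        assert set(widest) == {f"item_{i:02d}" for i in range(1, 16)}


class TestDrawPilot:
    def test_constant_population_gives_constant_pilot(self):
        cfg = PopulationConfig(
            n_items=1, n_obs=10, mu=5, sigma_mu=0, sigma=1e-9, sigma_sigma=0,
            scale=ScaleSpec(1, 7, discrete=True), seed=10,
        )
        pilot = draw_pilot(simulate_population(cfg), 20, seed=0)
        assert (pilot.data["score"] == 5.0).all()
        assert len(pilot) == 20

    def test_same_seed_same_pilot(self):
        pop = simulate_population(preset_config("likert-small-symmetric", seed=12))
        a = draw_pilot(pop, 25, seed=99).data
        b = draw_pilot(pop, 25, seed=99).data
        assert a.equals(b)

    def test_rejects_tiny_pilot(self):
        pop = simulate_population(preset_config("likert-small-symmetric", seed=13))
        with pytest.raises(ValueError):
            draw_pilot(pop, 1, seed=0)

    def test_large_resample_recovers_population_means(self):
        pop = simulate_population(
            preset_config("likert-small-symmetric", n_items=5, n_obs=200, seed=14)
        )
        pilot = draw_pilot(pop, 5000, seed=1)
        pop_scores = pop.scores_by_item()
        for item, drawn in pilot.scores_by_item().items():
            src = pop_scores[item]
            boot_se = src.std(ddof=0) / np.sqrt(drawn.size)
            assert abs(drawn.mean() - src.mean()) < 3 * boot_se + 1e-9
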