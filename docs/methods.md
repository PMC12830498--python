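# Methods

## The planning problem

A multi-item study estimates one mean per item. The precision of item *i*
after *n* participants is its standard error, SE_i = SD_i/√n (sample SD,
n−1 denominator). Planning for precision means choosing *n* so that a
target share of items reaches a sufficiently small SE — an
accuracy-in-parameter-estimation criterion rather than a power-for-a-test
criterion. Because items differ in their SDs, no closed form gives the
required *n*; `itemprecision` estimates it by bootstrap simulation from
pilot data.

## The procedure

**Cutoff.** Per-item SEs are computed from the pilot; the cutoff is the
empirical 0.4 quantile (4th decile) of those SEs, by linear interpolation
between order statistics at position h = (n−1)q + 1 (the "type 7"
convention; `numpy.quantile`'s default serves as an independent oracle in
the tests). Lower deciles are stricter; 0.4 balances strictness against
feasibility and is the default. The same value is the stopping rule for
adaptive designs: an item has "stopped" when its interim SE is strictly
below the cutoff.

**Projection.** For each candidate size n on a grid (default 20–300 by 5),
each item is resampled with replacement from its own pilot scores
(per-item, because pilot items typically have unequal n) and the resample's
SE recorded; 500 replicates per size by default. The fraction of items
below the cutoff is computed per replicate and then averaged
(replicate-then-average). The projected N at level L is the first grid size
whose averaged percent reaches L (first crossing, not a global search; the
achieved percent at the crossing may exceed L and is carried forward).

**Correction.** Raw projections rise almost linearly with pilot size —
more pilot information should not demand ever more participants. The decay
factor

    1 − √((N_pilot − min_sim)/N_pilot)^log₂(N_pilot)

(min_sim = smallest simulated size, default 20) multiplies the projection;
it equals 1 when the pilot is no larger than min_sim and decreases strictly
in pilot size, imposing the asymptotic leveling-off expected of power
curves. For a researcher holding a single pilot, the decay-corrected size
is approximated by a fixed nine-coefficient regression on projected N,
pilot N, the proportion of possible variance, and the percent level, each
raw and log₂-transformed. Two coefficient sets ship as constants:
`FOURTH_DECILE_COEFFS` (default, fitted at the recommended 0.4 cutoff) and
`ALL_DECILE_COEFFS` (fitted across cutoff deciles, for non-default
deciles). Re-estimating these coefficients from a fresh full-scale
simulation is out of scope; they are treated as published constants.
**Power enters in percent units** (80, not 0.80). By default the achieved
percent at the crossing is fed to the regression; `use_achieved_power=False`
feeds the nominal level instead, which is how the shipped worked-example
values are reproduced.

**Heterogeneity summary.** The proportion of possible variance is
SD_itemSD / √((max − min)²/4) — the SD of the item *standard deviations*
(not of the SEs; only the SD-of-SDs version reproduces the worked-example
value 0.28/2 = 0.14) divided by half the scale range, the largest SD a
bounded scale admits. It is dimensionless and invariant to jointly
rescaling scores and bounds.

**Loss adjustment and reporting.** Corrected sizes are divided by the
expected retention proportion and rounded up (`ceil`). The plan designates
the smallest reached level's final N as the minimum, the cutoff SE as the
stopping rule, and the largest reached level's final N as the maximum;
pairing other levels is the user's choice. Corrected sizes below the grid
start are floored there with a warning — the regression is an
interpolation over the simulated range and extrapolates poorly below it.
A representative pilot n for tables with unequal per-item counts is the
ceiling of the mean per-item n (e.g. mean 28.52 → 29).

## The population simulator

`simulate_population` draws, per item, a mean from Normal(μ, σ_μ) and an SD
from Normal(σ, σ_σ), then n_obs scores from Normal(mean_i, sd_i), rounds
them to whole numbers and clamps them to the scale endpoints. Presets
encode three instrument archetypes × three heterogeneity levels:

| parameter | likert | percent | milliseconds |
|---|---|---|---|
| bounds | 1–7 | 0–100 | 0–3000 |
| μ (symmetric) | 4 | 50 | 1000 |
| μ (ceiling) | 6 | 85 | 2500 |
| σ_μ | 0.25 | 10 | 150 |
| σ | 2 | 25 | 400 |
| σ_σ small/medium/large | 0.2/0.4/0.8 | 4/8/16 | 50/100/200 |

Numerical choices, each genuinely open and decided once:

- **SD positivity guard.** Item SDs are redrawn while below 0.01·σ.
  Negative SDs are impossible; σ ≥ 2.5·σ_σ in every preset, so rejections
  are rare and the target moments are essentially preserved.
- **Rounding then clamping**, half away from zero. The order and tie rule
  are not forced by anything upstream; ties have negligible probability for
  continuous draws, and for these presets clamp-then-round differs only on
  a measure-zero set.
- **Floor means** mirror the ceiling mean about the scale midpoint
  (min + max − ceiling_μ): 2 for likert, 15 for percent, 500 for
  milliseconds. Only the ceiling means are prescribed; the mirror is the
  natural symmetric completion.
- **Bimodal items** concatenate n_obs/2 scores drawn around the ceiling
  mean and n_obs/2 around the floor mean (larger half to the ceiling when
  n_obs is odd), with the usual SD machinery per component.
- **Seeding** is hierarchical (`SeedSequence.spawn`): the item-parameter
  draw and each item's score stream get independent child streams, so e.g.
  changing the bimodal fraction does not reshuffle unrelated items.
- Skew arises **only** through boundary clamping; there are no skewed
  primitive generators. Millisecond scores are rounded like the others,
  mimicking integer-recorded latencies.

What the simulator emulates: bounded, integer-recorded scales with
heterogeneous item variances and ceiling/floor/bimodal pathologies. What it
does not: participant-level correlation across items (each item's stream is
independent), missingness mechanisms, ordinal response processes, or
heavy-tailed latency shapes. Passing tests therefore show the procedure
behaves correctly for independent bounded item streams, not that real-data
recommendations are unbiased under, say, strong participant effects.

A convenience reconstruction of pilot data from published per-item means
and SDs (normal resampling) is possible through the same machinery but is
an approximation: the generating distribution of the original scores is
unknown.

## The validation harness

`run_condition` simulates one researcher: population → pilot →
cutoff → bootstrap → projected, decay-corrected, and regression-corrected N.
`evaluate_pilot_sizes` repeats this for many researchers per condition and
reports, per condition × pilot size: the SD across researchers of the
decay-corrected recommendation (instability), the mean relative SE bias
(estimated SE − true SE)/true SE with the true SE taken as the population
item SD at the *same* n (the only comparable choice), and the relative
cutoff bias against the population's 4th-decile cutoff at that n.
`bimodal_sweep` varies the fraction of bimodal items from 0 to 1.

Default harness problem sizes are deliberately reduced — tens of
researchers, tens of bootstrap replicates, grids to a few hundred — because
the quantities of interest are trends (recommendations grow with
heterogeneity, flatten with pilot size, rise then fall across the bimodal
sweep), which are stable at this scale; full-scale factorial runs remain
reachable through the config. The test suite checks those trends with
paired seeds; the acceptance script reports the scale-ordering summary
(average proportion of possible variance: percent > likert > milliseconds)
from 50 replicate populations per condition.

## Known limitations

- The correction regression is only valid inside the simulated design
  space (pilots ~20–100, grids from 20, bounded integer scales); outputs
  below the grid start are floored rather than trusted.
- A pilot with zero SE heterogeneity (prop var 0) has no defined
  regression correction (log₂ of 0); the harness reports NaN there and the
  planner raises with advice to floor the proportion.
- Percent-below curves are noisy at small replicate counts; the first
  crossing rule is applied to the averaged curve, so nsim trades run time
  against projection stability.
- Recommendations from pilots under ~30 participants are unstable across
  researchers; the planner warns below that size.
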