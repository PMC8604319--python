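# Methods

This note documents the model, its parameters, the numerical and design
choices behind `harvestmse`, and what its simulations can and cannot say
about real harvest systems.

## Population model and the within-year loop

The operating model is a single closed population with continuous
abundance and discrete yearly logistic growth,
`N ← max(0, N + r·N·(1 − N/K))`. No age, sex, or spatial structure is
represented; predators and other biotic interactions are assumed absorbed
into the variability of the demographic rates.

Each year runs a fixed sequence: grow → observe → decide → perturb quota
→ harvest → remove. The order matters (for example, harvest acts on the
post-growth population, and monitoring sees the pre-harvest stock); it is
fixed and documented here rather than configurable, so that all results
are comparable.

Populations are continuous rather than integer, which keeps the logistic
model exact and the control rules smooth. "Extinction" therefore needs a
convention: when the post-harvest population drops below the
`extinction_floor` (default 1 individual) it is set to zero and stays
there. The floor gives the persistence metric a well-defined event; its
exact value only matters for trajectories that were headed to quasi-zero
anyway.

A quota exceeding the available population is harvested as the whole
population, not treated as an error: quotas are intentions, harvest is
physically bounded.

## Stochasticity

Four inputs vary per (replicate, year): the growth rate `r` (additive
around the species mean `r̄`) and three multiplicative factors centred at
1 — monitoring `m`, quota-setting `q`, and implementation `h`. Each is
normal with a standard deviation chosen by the context's variability
level (low/high), truncated to its support: `m, q, h ≥ 0`, and `r` within
the species' `r_bounds` (default `[−r̄, 2r̄]`, preventing pathological
negative-growth explosions while allowing bad years).

The variance is partitioned between a replicate-level offset `b_i`
(parameter uncertainty, constant over the 20 years of a replicate) and a
yearly innovation `e_{i,t}` (temporal stochasticity), with
`variance_partition` (default 0.5, an even split — the natural choice
when nothing distinguishes the two sources) giving the replicate-level
share. Draws are implemented by inverse-CDF sampling: `b_i` is an
unbounded normal, and the yearly component is drawn from the normal
truncated so that the *sum* `centre + b_i + e_{i,t}` respects the
declared bounds. With `variance_partition = 0` the marginal distribution
is exactly the truncated normal of the full sigma, which is how the test
suite checks the sampler against the closed-form truncated-normal mean.

All randomness flows from a single master seed. Every replicate's seed is
derived from (master seed, species-name hash, SID, strategy-label hash,
replicate index) — identity, not execution order — so results are
identical for any worker count, any single cell can be re-run in
isolation, and two extensionally equal strategies (e.g.
threshold-proportional with T = 0 versus proportional) produce bitwise
identical trajectories under a shared seed.

## Harvest control rules

* `no_harvest`: quota 0 (baseline).
* `constant`: a fixed yearly quota `c`.
* `proportional`: `p · N̂`.
* `threshold_proportional`: `p · N̂` when `N̂ > T`, else 0.

The threshold rule harvests a proportion of the whole estimate, not of
the surplus above the threshold; the surplus variant exists behind the
`tp_surplus` config flag but is not the default. The threshold comparison
is strict (a tie yields 0) — immaterial for continuous populations.
Quotas are continuous; `round_quotas` rounds to whole animals for realism
studies. Rules and parameters are fixed over a simulation's whole
timeframe.

Parameter grids are species-portable: constants and thresholds are
expressed in config as fractions of the species' *moderate size* (the
midpoint of the low and high critical thresholds) and converted to
individuals at grid build; proportions are absolute fractions. Default
grids walk 1% increments; thresholds range from the quasi-extinction
threshold to the moderate size.

## Evaluation

Ten raw metrics per replicate, all oriented so higher is better:
persistence (0/1 from the extinction flag); five year-counts comparing
the post-harvest population to the species' critical thresholds with
strict inequalities (years above quasi-extinction, above low, between low
and high, below high, below overabundance); and four harvest statistics
(mean, minimum, years non-zero, and consistency = 0 − standard deviation
of the yearly harvests; the population (ddof = 0) standard deviation of
the realized 20-year series is used, as a descriptive spread of the
series actually experienced). A flag (`metrics_on = "pre"`) switches the
population metrics to the pre-harvest series.

Standardization maps each metric linearly to 0–100 within each
environmental context, pooling **all replicates and all decision
variables** of that context. Two bound regimes coexist deliberately:
persistence and the year-counts have absolute ideals (0–1, 0–T), while
the harvest volume metrics are bounded above by the largest value
observed in the context ensemble and harvest consistency is bounded below
by the largest observed harvest variability. If an ensemble is degenerate
(best = worst, e.g. no strategy ever harvests), values equal to the ideal
pole score 100 and anything else 0, with a warning. Clipping to [0, 100]
guards floating-point overshoot only.

Composite scores are unweighted means of a set's member metrics —
computed per replicate first, then averaged over replicates (the two
orders differ because metrics co-vary within replicates). The six sets
range from "classic" persistence + mean harvest to the complete
ten-metric view; persistence belongs to every set. This linear,
equal-weight aggregation encodes risk-neutral, linear stakeholder
preferences; no weighting or nonlinear utility is offered.

Because the standardization is context-relative, the experiment runner is
two-pass per context: simulate every decision variable, resolve bounds
from the pooled ensemble, then score. Per-cell raw-metric tables can be
checkpointed on disk; a checkpoint directory written under a different
configuration hash is refused.

## Comparative analysis

*Optimal parameters* are the argmax of the mean composite score over a
kind's grid; scores are rounded to 6 decimals before tie detection
(Monte-Carlo noise creates spurious near-ties), ties broken toward the
smallest parameter vector in grid order with all tied optima reported.
*Rankings* let tied kinds share the better rank. *Value forgone* is the
optimal kind's best score minus the chosen kind's best score, in points
on the 0–100 composite scale; a relative variant (% of the optimal score)
is reported alongside. Kinds jointly optimal within the tie tolerance
carry value forgone exactly 0.

*Pairwise contrasts* difference two levels of one factor (species,
variability, start scenario, or evaluation set) across all matched
combinations of the remaining factors, reporting the distribution of
differences and the proportions below/at/above zero; unmatched
complements are counted and excluded. Optimal-parameter contrasts use the
fractional (moderate-size-scaled) constant and threshold columns so
species are comparable.

*Information value*: the (context, set) cases are partitioned by what the
decision-maker may condition on — nothing, species, variability, starting
population, the full environmental context, or the evaluation set. Within
each cell one strategy kind is chosen under two rules, most-frequently-
optimal and minimum mean value forgone, and judged by the pooled
frequency of being (jointly) optimal and the pooled mean value forgone.
Both rules are reported because they can disagree; under the min-forgone
rule the pooled mean value forgone is provably non-increasing as the
partition refines.

## Default configuration

The shipped config spans three species on the slow–fast life-history
gradient. Their moderate sizes (moose 600, roe deer 6950, ptarmigan
17500 individuals) follow published expert elicitation; the growth rates
(0.25 / 0.50 / 1.00 yr⁻¹), carrying capacities (1400 / 16000 / 40000),
thresholds, and variation magnitudes are placeholder values chosen once
to respect the gradient's qualitative ordering (moose lowest in growth,
variation, and thresholds; ptarmigan highest) at magnitudes typical for
the respective taxa. They are clearly marked in the config and meant to
be overridden; no test depends on them except through the ordering and
the moderate sizes. 20-year timeframe, 1000 replicates.

## What the simulations do and do not show

The generator emulates the variability structure of managed harvest
systems — environmental stochasticity, parameter uncertainty, monitoring
error, stakeholder pressure on quotas, and sloppy implementation — under
a deliberately simple logistic, unstructured population. Passing tests
demonstrate the machinery is correct and the comparative patterns
(adaptive rules dominating constant quotas, evaluation context driving
perceived outcomes) are internally consistent; they do not validate the
placeholder parameter magnitudes, and none of the simulated data carries
age/sex/spatial structure, directional monitoring bias, time trends
(e.g. climate), or density-dependence forms other than logistic. Absolute
score levels should not be read as predictions for real populations.

## Problem sizes

The test suite uses 1-species toy factorials (≤10 replicates) for exact
and structural checks, and a 2 × 200-replicate single-context run for the
Monte-Carlo stability check. In that check both seed sets are
standardized under bounds resolved from the pooled ensemble: the
context-relative bounds are max statistics whose sampling error is shared
by every replicate of a run, so comparing pipeline-standardized means
against per-replicate standard errors would conflate bound noise with
Monte-Carlo error in the metric means.

`scripts/acceptance.py` runs the full 18-context factorial with coarser
grids (constants and proportions 2–40% in 2% steps, threshold-rule
proportions 5–50% in 5% steps, 5 thresholds per species; 91 strategy
specs per species) and 150 replicates — about 250k replicate simulations,
a few minutes on one CPU — which is ample for the case-level frequencies
and score summaries it reports.
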