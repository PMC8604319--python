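# Default three-species factorial configuration.
#
# The moderate population sizes implied by the thresholds (moose 600,
# roe deer 6950, ptarmigan 17500 — the midpoints of the low and high
# critical thresholds) are fixed by published expert elicitation.  The
# remaining life-history and variation values are PLACEHOLDER defaults:
# they respect the slow--fast life-history ordering (moose: lowest growth
# rate, variation, and thresholds; ptarmigan: highest) but are not measured
# values, and should be overridden with case-specific estimates where
# available.
species:
  - name: moose
    r_mean: 0.25
    K: 1400
    thresholds: {quasi_extinct: 100, low: 400, high: 800, overabundant: 1200}
    sd:
      r: {low: 0.05, high: 0.15}
      m: {low: 0.05, high: 0.15}
      q: {low: 0.05, high: 0.15}
      h: {low: 0.05, high: 0.15}
  - name: roe_deer
    r_mean: 0.50
    K: 16000
    thresholds: {quasi_extinct: 900, low: 4400, high: 9500, overabundant: 14000}
    sd:
      r: {low: 0.10, high: 0.25}
      m: {low: 0.10, high: 0.25}
      q: {low: 0.08, high: 0.20}
      h: {low: 0.08, high: 0.20}
  - name: ptarmigan
    r_mean: 1.00
    K: 40000
    thresholds: {quasi_extinct: 2000, low: 10000, high: 25000, overabundant: 35000}
    sd:
      r: {low: 0.20, high: 0.40}
      m: {low: 0.15, high: 0.35}
      q: {low: 0.10, high: 0.25}
      h: {low: 0.10, high: 0.25}

experiment:
  timeframe: 20
  replicates: 1000
  master_seed: 42
  variance_partition: 0.5
  extinction_floor: 1.0

# Constants and thresholds are fractions of each species' moderate size;
# proportions are absolute fractions of the observed population.
grids:
  constant: {min: 0.01, max: 1.00, step: 0.01}
  proportional: {min: 0.01, max: 1.00, step: 0.01}
  threshold_proportional:
    proportion: {min: 0.01, max: 1.00, step: 0.01}
    threshold_step: 0.01

evaluation_sets:
  - classic_harv
  - classic_pop_harv
  - population_focus
  - harvest_focus
  - complete_small_game
  - complete
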