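"""The yearly simulation loop: stochastic logistic growth, noisy
monitoring, quota perturbation, imperfect harvest, and removal.

Each replicate runs the same within-year sequence for every year t:

1. grow:     N_grow = logistic_step(N_{t-1}, r_t, K)
2. observe:  N_obs  = m_t * N_grow
3. decide:   Q      = control rule applied to N_obs
4. perturb:  Q'     = q_t * Q          (stakeholder influence on the quota)
5. harvest:  H      = clamp(h_t * Q', 0, N_grow)
6. remove:   N_t    = N_grow - H

The four stochastic inputs r, m, q, h are drawn per (replicate, year) from
truncated normals whose variance is partitioned between a replicate-level
component (parameter uncertainty, constant within a replicate) and a
yearly component (temporal stochasticity).  Populations are continuous; a
post-harvest population below the extinction floor is set to zero and
stays there (absorbing extinction).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .config import (
    EnvironmentalContext,
    ExperimentConfig,
    HarvestStrategySpec,
    SpeciesProfile,
    Variability,
)
from .strategies import set_quota

__all__ = [
    "Trajectory",
    "VariationDraws",
    "logistic_step",
    "draw_variation",
    "simulate_replicate",
    "simulate_scenario",
    "replicate_seed",
    "trajectories_to_frame",
]

#: fixed draw order; independent of the harvest strategy so that
#: extensionally equal strategies produce bitwise-identical trajectories
#: under a shared seed
_FACTOR_ORDER = ("r", "m", "q", "h")


@dataclass
class Trajectory:
    """One replicate's yearly series (index 0 is year 1)."""

    years: np.ndarray
    N: np.ndarray        #: true post-harvest population
    N_pre: np.ndarray    #: pre-harvest (post-growth) population
    N_obs: np.ndarray    #: monitored estimate
    Q: np.ndarray        #: initial quota from the control rule
    Q_mod: np.ndarray    #: quota after stakeholder perturbation
    H: np.ndarray        #: realized harvest
    extinct: bool
    extinction_year: int | None


@dataclass
class VariationDraws:
    """Per-year stochastic inputs for one replicate."""

    r: np.ndarray  #: growth rate, additive around r_mean, truncated to r_bounds
    m: np.ndarray  #: monitoring factor, multiplicative, centre 1, lower bound 0
    q: np.ndarray  #: quota-setting factor, multiplicative, centre 1, lower bound 0
    h: np.ndarray  #: harvest-implementation factor, multiplicative, centre 1, lower bound 0


def logistic_step(N: float, r: float, K: float) -> float:
    """One year of logistic growth: max(0, N + r*N*(1 - N/K))."""
    if K <= 0:
        raise ValueError(f"carrying capacity K must be > 0, got {K}")
    if N < 0:
        raise ValueError(f"population N must be >= 0, got {N}")
    return max(0.0, N + r * N * (1.0 - N / K))


def _draw_factor(
    rng: np.random.Generator,
    n_years: int,
    center: float,
    sigma: float,
    lower: float,
    upper: float,
    variance_partition: float,
) -> np.ndarray:
    """Replicate+yearly partitioned normal draws, truncated on the sum.

    The replicate-level offset b ~ N(0, vp*sigma^2) is drawn first; yearly
    values are then drawn from a normal with sd sqrt(1-vp)*sigma truncated
    so that center + b + e lies within [lower, upper].  With vp = 0 the
    result is exactly a truncated normal with the full sigma.
    """
    if sigma == 0:
        return np.full(n_years, center)
    vp = variance_partition
    b = rng.normal(0.0, math.sqrt(vp) * sigma) if vp > 0 else 0.0
    scale = math.sqrt(1.0 - vp) * sigma
    loc = center + b
    if scale == 0:
        return np.full(n_years, min(max(loc, lower), upper))
    cdf_lo = ndtr((lower - loc) / scale) if np.isfinite(lower) else 0.0
    cdf_hi = ndtr((upper - loc) / scale) if np.isfinite(upper) else 1.0
    u = rng.uniform(cdf_lo, cdf_hi, size=n_years)
    x = loc + scale * ndtri(np.clip(u, 1e-15, 1 - 1e-15))
    return np.clip(x, lower, upper)


def draw_variation(
    profile: SpeciesProfile,
    variability: Variability,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> VariationDraws:
    """Draw the r, m, q, h series for one replicate.

    With all standard deviations zero the draws are exactly r_mean and 1.
    """
    T = config.timeframe_T
    vp = config.variance_partition
    out = {}
    for factor in _FACTOR_ORDER:
        sigma = profile.sd(factor, variability)
        if factor == "r":
            lower, upper = profile.r_bounds
            center = profile.r_mean
        else:
            lower, upper, center = 0.0, math.inf, 1.0
        out[factor] = _draw_factor(rng, T, center, sigma, lower, upper, vp)
    return VariationDraws(**out)


def replicate_seed(
    master_seed: int,
    context: EnvironmentalContext,
    strategy: HarvestStrategySpec,
    replicate: int,
) -> np.random.SeedSequence:
    """Deterministic, cell-local sub-seed for one replicate.

    Derived from the master seed, the context identity (species name hash
    and SID), the strategy label hash, and the replicate index — never from
    execution order, so results are independent of parallelization.
    """
    species_key = zlib.crc32(context.species.name.encode()) & 0x7FFFFFFF
    strategy_key = zlib.crc32(strategy.label.encode()) & 0x7FFFFFFF
    return np.random.SeedSequence(
        [int(master_seed), species_key, context.sid, strategy_key, int(replicate)]
    )


def simulate_replicate(
    context: EnvironmentalContext,
    strategy: HarvestStrategySpec,
    config: ExperimentConfig,
    seed: int | np.random.SeedSequence,
) -> Trajectory:
    """Simulate one replicate trajectory over the configured timeframe."""
    profile = context.species
    T = config.timeframe_T
    K = profile.K
    rng = np.random.default_rng(seed)
    draws = draw_variation(profile, context.variability, config, rng)

    N = np.empty(T)
    N_pre = np.empty(T)
    N_obs = np.empty(T)
    Q = np.empty(T)
    Q_mod = np.empty(T)
    H = np.empty(T)
    extinct = False
    extinction_year: int | None = None

    n_prev = float(context.n0)
    for t in range(T):
        n_grow = logistic_step(n_prev, float(draws.r[t]), K)
        n_obs = draws.m[t] * n_grow
        quota = set_quota(n_obs, strategy, config)
        q_mod = draws.q[t] * quota
        h = min(max(0.0, draws.h[t] * q_mod), n_grow)
        n = n_grow - h
        if not extinct and n < config.extinction_floor:
            extinct = True
            extinction_year = t + 1
        if extinct:
            n = 0.0
        N_pre[t] = n_grow
        N_obs[t] = n_obs
        Q[t] = quota
        Q_mod[t] = q_mod
        H[t] = h
        N[t] = n
        n_prev = n

    return Trajectory(
        years=np.arange(1, T + 1),
        N=N,
        N_pre=N_pre,
        N_obs=N_obs,
        Q=Q,
        Q_mod=Q_mod,
        H=H,
        extinct=extinct,
        extinction_year=extinction_year,
    )


def simulate_scenario(
    context: EnvironmentalContext,
    strategy: HarvestStrategySpec,
    config: ExperimentConfig,
    n_replicates: int | None = None,
) -> list[Trajectory]:
    """Simulate all replicates of one (context, strategy) cell.

    Replicate i uses the deterministic sub-seed from :func:`replicate_seed`,
    so the result is independent of execution order and worker count.
    """
    n = config.n_replicates if n_replicates is None else n_replicates
    return [
        simulate_replicate(
            context, strategy, config, replicate_seed(config.master_seed, context, strategy, i)
        )
        for i in range(n)
    ]


def trajectories_to_frame(
    trajectories: list[Trajectory],
    context: EnvironmentalContext,
    strategy: HarvestStrategySpec,
):
    """Tidy per-year table of a scenario (for the optional trajectory dump)."""
    import pandas as pd

    frames = []
    for i, tr in enumerate(trajectories):
        frames.append(
            pd.DataFrame(
                {
                    "species": context.species.name,
                    "context_sid": context.sid,
                    "strategy": strategy.kind.value,
                    "params": strategy.label,
                    "replicate": i,
                    "year": tr.years,
                    "N": tr.N,
                    "N_pre": tr.N_pre,
                    "N_obs": tr.N_obs,
                    "Q": tr.Q,
                    "Q_mod": tr.Q_mod,
                    "H": tr.H,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
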