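"""Harvest control rules: map an observed population estimate to a quota.

Four rules are supported: *no harvest* (quota 0), *constant* (a fixed
number of individuals per year, independent of the estimate),
*proportional* (a fixed fraction of the estimate), and
*threshold-proportional* (a fixed fraction of the estimate, but only when
the estimate exceeds a threshold; otherwise 0).  The rule and its
parameters are fixed for the whole simulated timeframe; only the estimate
varies year to year.
"""

from __future__ import annotations

from .config import ExperimentConfig, HarvestStrategySpec, StrategyKind

__all__ = ["set_quota"]


def set_quota(
    n_obs: float,
    strategy: HarvestStrategySpec,
    config: ExperimentConfig | None = None,
) -> float:
    """Initial quota (individuals, >= 0) for an observed population estimate.

    The threshold comparison is strict: an estimate exactly at the threshold
    yields a zero quota.  With ``config.tp_surplus`` the threshold rule
    harvests a fraction of the surplus above the threshold instead of the
    whole estimate; with ``config.round_quotas`` quotas are rounded to whole
    animals.  Both are off by default.
    """
    if n_obs < 0:
        raise ValueError(f"n_obs must be >= 0, got {n_obs}")
    kind = strategy.kind
    if kind is StrategyKind.NO_HARVEST:
        quota = 0.0
    elif kind is StrategyKind.CONSTANT:
        quota = float(strategy.constant_c)
    elif kind is StrategyKind.PROPORTIONAL:
        quota = strategy.proportion_p * n_obs
    elif kind is StrategyKind.THRESHOLD_PROPORTIONAL:
        if n_obs > strategy.threshold_T:
            base = (n_obs - strategy.threshold_T) if (config is not None and config.tp_surplus) else n_obs
            quota = strategy.proportion_p * base
        else:
            quota = 0.0
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown strategy kind: {kind!r}")
    if config is not None and config.round_quotas:
        quota = float(round(quota))
    return max(0.0, quota)
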