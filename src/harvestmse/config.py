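"""Simulation inputs: species profiles, environmental contexts, harvest
strategies, parameter grids, and experiment settings.

The environmental context of a simulation is a species (a point on the
slow--fast life-history gradient), a variability level (low/high, applied
jointly to growth, monitoring, quota-setting, and harvest-implementation
variation), and a starting-population scenario.  Each (variability,
start-scenario) pair carries a scenario identifier SID 1--6.  Decision
variables are harvest strategies (no-harvest, constant, proportional,
threshold-proportional) crossed with their parameter grids, expressed in
1%-style increments of species-specific scales so the grids are portable
across species.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ConfigError",
    "ConfigFileError",
    "SchemaError",
    "InvariantError",
    "Variability",
    "StartScenario",
    "StrategyKind",
    "SpeciesProfile",
    "EnvironmentalContext",
    "HarvestStrategySpec",
    "GridRange",
    "ExperimentConfig",
    "COMPOSITE_SET_NAMES",
    "load_config",
    "default_config",
    "build_environmental_grid",
    "build_decision_grid",
    "total_model_count",
]


# --------------------------------------------------------------------------
# Errors

class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigFileError(ConfigError):
    """The config file is missing or cannot be parsed."""


class SchemaError(ConfigError):
    """The parsed config does not match the documented schema."""


class InvariantError(ConfigError):
    """A domain invariant is violated (e.g. thresholds out of order)."""


# --------------------------------------------------------------------------
# Enumerations

class Variability(str, enum.Enum):
    LOW = "low"
    HIGH = "high"


class StartScenario(str, enum.Enum):
    MODERATE = "moderate"
    QUASI_EXTINCTION = "quasi_extinction"
    OVERABUNDANCE = "overabundance"


class StrategyKind(str, enum.Enum):
    NO_HARVEST = "no_harvest"
    CONSTANT = "constant"
    PROPORTIONAL = "proportional"
    THRESHOLD_PROPORTIONAL = "threshold_proportional"


#: SID codes for (start scenario, variability): odd = low, even = high
#: variability; moderate starts are SID 1/2, quasi-extinction 3/4,
#: overabundance 5/6.
SID_TABLE: dict[tuple[StartScenario, Variability], int] = {
    (StartScenario.MODERATE, Variability.LOW): 1,
    (StartScenario.MODERATE, Variability.HIGH): 2,
    (StartScenario.QUASI_EXTINCTION, Variability.LOW): 3,
    (StartScenario.QUASI_EXTINCTION, Variability.HIGH): 4,
    (StartScenario.OVERABUNDANCE, Variability.LOW): 5,
    (StartScenario.OVERABUNDANCE, Variability.HIGH): 6,
}

COMPOSITE_SET_NAMES = (
    "classic_harv",
    "classic_pop_harv",
    "population_focus",
    "harvest_focus",
    "complete_small_game",
    "complete",
)


# --------------------------------------------------------------------------
# Species

@dataclass(frozen=True)
class SpeciesProfile:
    """Life-history, monitoring, and threshold parameters for one species.

    Thresholds are the four critical population levels used by the
    population-based evaluation metrics.  ``moderate_size`` (the midpoint of
    the low and high thresholds) is the species' scaling unit for constant
    and threshold parameter grids.  Variation magnitudes are normal standard
    deviations per variability level: ``sd_r_*`` on the yearly growth rate
    (additive around ``r_mean``), ``sd_m_*``/``sd_q_*``/``sd_h_*`` on
    multiplicative factors centred at 1 for monitoring, quota setting, and
    harvest implementation.
    """

    name: str
    r_mean: float
    K: float
    threshold_quasi_extinct: float
    threshold_low: float
    threshold_high: float
    threshold_overabundant: float
    sd_r_low: float
    sd_r_high: float
    sd_m_low: float
    sd_m_high: float
    sd_q_low: float
    sd_q_high: float
    sd_h_low: float
    sd_h_high: float
    #: inclusive truncation bounds for stochastic growth-rate draws
    r_bounds: tuple[float, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.r_bounds is None:
            object.__setattr__(self, "r_bounds", (-self.r_mean, 2 * self.r_mean))
        else:
            object.__setattr__(self, "r_bounds", tuple(float(b) for b in self.r_bounds))
        if not self.name:
            raise InvariantError("species field 'name' must be non-empty")
        if not self.K > 0:
            raise InvariantError(f"species {self.name!r}: field 'K' must be > 0, got {self.K}")
        if not self.r_mean > 0:
            raise InvariantError(
                f"species {self.name!r}: field 'r_mean' must be > 0, got {self.r_mean}"
            )
        t = {
            "threshold_quasi_extinct": self.threshold_quasi_extinct,
            "threshold_low": self.threshold_low,
            "threshold_high": self.threshold_high,
            "threshold_overabundant": self.threshold_overabundant,
        }
        if not t["threshold_quasi_extinct"] > 0:
            raise InvariantError(
                f"species {self.name!r}: field 'threshold_quasi_extinct' must be > 0"
            )
        if not t["threshold_quasi_extinct"] <= t["threshold_low"]:
            raise InvariantError(
                f"species {self.name!r}: fields 'threshold_quasi_extinct' "
                f"({t['threshold_quasi_extinct']}) and 'threshold_low' "
                f"({t['threshold_low']}) must satisfy quasi_extinct <= low"
            )
        if not t["threshold_low"] < t["threshold_high"]:
            raise InvariantError(
                f"species {self.name!r}: fields 'threshold_low' ({t['threshold_low']}) and "
                f"'threshold_high' ({t['threshold_high']}) must satisfy low < high"
            )
        if not t["threshold_high"] <= t["threshold_overabundant"]:
            raise InvariantError(
                f"species {self.name!r}: fields 'threshold_high' ({t['threshold_high']}) and "
                f"'threshold_overabundant' ({t['threshold_overabundant']}) must satisfy "
                "high <= overabundant"
            )
        for factor in ("r", "m", "q", "h"):
            lo = getattr(self, f"sd_{factor}_low")
            hi = getattr(self, f"sd_{factor}_high")
            if lo < 0 or hi < 0:
                raise InvariantError(
                    f"species {self.name!r}: fields 'sd_{factor}_low'/'sd_{factor}_high' "
                    "must be >= 0"
                )
            if lo > hi:
                raise InvariantError(
                    f"species {self.name!r}: field 'sd_{factor}_low' ({lo}) must not exceed "
                    f"'sd_{factor}_high' ({hi})"
                )
        if not self.r_bounds[0] <= self.r_mean <= self.r_bounds[1]:
            raise InvariantError(
                f"species {self.name!r}: field 'r_bounds' {self.r_bounds} must bracket "
                f"'r_mean' ({self.r_mean})"
            )

    @property
    def moderate_size(self) -> float:
        """Midpoint of the low and high critical thresholds."""
        return (self.threshold_low + self.threshold_high) / 2.0

    def sd(self, factor: str, variability: Variability) -> float:
        """Standard deviation of one variation factor at a variability level."""
        return getattr(self, f"sd_{factor}_{Variability(variability).value}")


# --------------------------------------------------------------------------
# Environmental contexts

@dataclass(frozen=True)
class EnvironmentalContext:
    """One species x variability x starting-population scenario."""

    species: SpeciesProfile
    variability: Variability
    start_scenario: StartScenario

    @property
    def sid(self) -> int:
        return SID_TABLE[(self.start_scenario, self.variability)]

    @property
    def n0(self) -> float:
        """Starting population implied by the start scenario."""
        if self.start_scenario is StartScenario.MODERATE:
            return self.species.moderate_size
        if self.start_scenario is StartScenario.QUASI_EXTINCTION:
            return self.species.threshold_quasi_extinct
        return self.species.threshold_overabundant

    @property
    def label(self) -> str:
        return f"{self.species.name}/SID{self.sid}"


# --------------------------------------------------------------------------
# Harvest strategies

@dataclass(frozen=True)
class HarvestStrategySpec:
    """A harvest strategy kind plus the parameters relevant to it.

    Parameters irrelevant to the kind must be absent (None).
    """

    kind: StrategyKind
    constant_c: float | None = None
    proportion_p: float | None = None
    threshold_T: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", StrategyKind(self.kind))
        k = self.kind
        relevant = {
            StrategyKind.NO_HARVEST: set(),
            StrategyKind.CONSTANT: {"constant_c"},
            StrategyKind.PROPORTIONAL: {"proportion_p"},
            StrategyKind.THRESHOLD_PROPORTIONAL: {"proportion_p", "threshold_T"},
        }[k]
        for name in ("constant_c", "proportion_p", "threshold_T"):
            value = getattr(self, name)
            if name in relevant and value is None:
                raise InvariantError(f"strategy {k.value}: field {name!r} is required")
            if name not in relevant and value is not None:
                raise InvariantError(
                    f"strategy {k.value}: field {name!r} is not applicable"
                )
        if self.constant_c is not None and self.constant_c < 0:
            raise InvariantError("field 'constant_c' must be >= 0")
        if self.proportion_p is not None and not 0 <= self.proportion_p <= 1:
            raise InvariantError("field 'proportion_p' must be in [0, 1]")
        if self.threshold_T is not None and self.threshold_T < 0:
            raise InvariantError("field 'threshold_T' must be >= 0")

    def validate_for_species(self, species: SpeciesProfile) -> None:
        """Check species-relative bounds (threshold within quasi..moderate)."""
        if self.threshold_T is not None:
            lo = species.threshold_quasi_extinct
            hi = species.moderate_size
            if not lo <= self.threshold_T <= hi:
                raise InvariantError(
                    f"field 'threshold_T' ({self.threshold_T}) must lie within "
                    f"[{lo}, {hi}] for species {species.name!r}"
                )

    @property
    def label(self) -> str:
        """Compact text label used in result tables, e.g. ``tp(p=0.12,T=450)``."""
        k = self.kind
        if k is StrategyKind.NO_HARVEST:
            return "nh"
        if k is StrategyKind.CONSTANT:
            return f"c(c={self.constant_c:g})"
        if k is StrategyKind.PROPORTIONAL:
            return f"p(p={self.proportion_p:g})"
        return f"tp(p={self.proportion_p:g},T={self.threshold_T:g})"

    def params(self) -> dict[str, float]:
        return {
            name: getattr(self, name)
            for name in ("constant_c", "proportion_p", "threshold_T")
            if getattr(self, name) is not None
        }


# --------------------------------------------------------------------------
# Experiment configuration

@dataclass(frozen=True)
class GridRange:
    """Inclusive min..max range walked in fixed steps (fractional units)."""

    min: float
    max: float
    step: float

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise InvariantError(f"grid field 'step' must be > 0, got {self.step}")
        if self.min > self.max:
            raise InvariantError(
                f"grid fields 'min' ({self.min}) and 'max' ({self.max}) must satisfy min <= max"
            )

    def values(self) -> list[float]:
        """Grid points min, min+step, ... up to max (inclusive, fp-safe)."""
        out = []
        k = 0
        while True:
            v = self.min + k * self.step
            if v > self.max + 1e-9 * self.step:
                break
            out.append(round(v, 12))
            k += 1
        return out


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully validated experiment settings plus the species profiles."""

    species: tuple[SpeciesProfile, ...]
    timeframe_T: int = 20
    n_replicates: int = 1000
    master_seed: int = 42
    #: fraction of each variation variance assigned to the replicate level
    #: (the remainder is yearly)
    variance_partition: float = 0.5
    extinction_floor: float = 1.0
    constant_grid: GridRange = field(default_factory=lambda: GridRange(0.01, 1.0, 0.01))
    proportion_grid: GridRange = field(default_factory=lambda: GridRange(0.01, 1.0, 0.01))
    tp_proportion_grid: GridRange = field(default_factory=lambda: GridRange(0.01, 1.0, 0.01))
    #: threshold grid step as a fraction of moderate_size; the range is fixed
    #: from the quasi-extinction threshold to moderate_size
    threshold_step: float = 0.01
    strategies: tuple[StrategyKind, ...] = tuple(StrategyKind)
    evaluation_sets: tuple[str, ...] = COMPOSITE_SET_NAMES
    variability_levels: tuple[Variability, ...] = (Variability.LOW, Variability.HIGH)
    start_scenarios: tuple[StartScenario, ...] = (
        StartScenario.MODERATE,
        StartScenario.QUASI_EXTINCTION,
        StartScenario.OVERABUNDANCE,
    )
    #: evaluate population metrics on post-harvest ("post") or pre-harvest
    #: ("pre") population
    metrics_on: str = "post"
    #: threshold-proportional harvests p*(N_obs - T) instead of p*N_obs
    tp_surplus: bool = False
    #: round quotas to whole animals
    round_quotas: bool = False
    #: decimals used when rounding scores for tie detection in the analysis
    tie_decimals: int = 6
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise InvariantError("field 'species' must list at least one profile")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise InvariantError(f"field 'species' contains duplicate names: {names}")
        if self.timeframe_T < 1:
            raise InvariantError(f"field 'timeframe_T' must be >= 1, got {self.timeframe_T}")
        if self.n_replicates < 1:
            raise InvariantError(f"field 'n_replicates' must be >= 1, got {self.n_replicates}")
        if not 0 <= self.variance_partition <= 1:
            raise InvariantError(
                f"field 'variance_partition' must be in [0, 1], got {self.variance_partition}"
            )
        if self.extinction_floor < 0:
            raise InvariantError("field 'extinction_floor' must be >= 0")
        if not self.threshold_step > 0:
            raise InvariantError(f"field 'threshold_step' must be > 0, got {self.threshold_step}")
        if self.metrics_on not in ("post", "pre"):
            raise InvariantError(f"field 'metrics_on' must be 'post' or 'pre', got {self.metrics_on!r}")
        for s in self.evaluation_sets:
            if s not in COMPOSITE_SET_NAMES:
                raise InvariantError(
                    f"field 'evaluation_sets' contains unknown set {s!r}; "
                    f"known sets: {COMPOSITE_SET_NAMES}"
                )
        if not self.variability_levels:
            raise InvariantError("field 'variability_levels' must be non-empty")
        if not self.start_scenarios:
            raise InvariantError("field 'start_scenarios' must be non-empty")
        if not self.strategies:
            raise InvariantError("field 'strategies' must be non-empty")

    def species_by_name(self, name: str) -> SpeciesProfile:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def config_hash(self) -> str:
        """Stable hash of everything that affects simulation results."""
        def enc(o: Any) -> Any:
            if isinstance(o, enum.Enum):
                return o.value
            if isinstance(o, (SpeciesProfile, GridRange)):
                return {k: enc(v) for k, v in vars(o).items()}
            if isinstance(o, (tuple, list)):
                return [enc(v) for v in o]
            return o

        payload = {k: enc(v) for k, v in vars(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def with_overrides(self, **kwargs: Any) -> "ExperimentConfig":
        return replace(self, **kwargs)


# --------------------------------------------------------------------------
# Loading

def _require_mapping(obj: Any, where: str) -> Mapping[str, Any]:
    if not isinstance(obj, Mapping):
        raise SchemaError(f"{where}: expected a mapping, got {type(obj).__name__}")
    return obj


def _get_number(d: Mapping[str, Any], key: str, where: str, default: Any = ...) -> float:
    if key not in d:
        if default is not ...:
            return default
        raise SchemaError(f"{where}: required field {key!r} is missing")
    v = d[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise SchemaError(f"{where}: field {key!r} must be a number, got {v!r}")
    return v


def _parse_species(entry: Any, index: int) -> SpeciesProfile:
    where = f"species[{index}]"
    d = _require_mapping(entry, where)
    name = d.get("name")
    if not isinstance(name, str) or not name:
        raise SchemaError(f"{where}: field 'name' must be a non-empty string")
    thresholds = _require_mapping(d.get("thresholds", {}), f"{where}.thresholds")
    sds = _require_mapping(d.get("sd", {}), f"{where}.sd")
    sd_kwargs: dict[str, float] = {}
    for factor in ("r", "m", "q", "h"):
        fd = _require_mapping(sds.get(factor, {}), f"{where}.sd.{factor}")
        sd_kwargs[f"sd_{factor}_low"] = _get_number(fd, "low", f"{where}.sd.{factor}")
        sd_kwargs[f"sd_{factor}_high"] = _get_number(fd, "high", f"{where}.sd.{factor}")
    r_bounds = d.get("r_bounds")
    if r_bounds is not None:
        if (not isinstance(r_bounds, Sequence)) or len(r_bounds) != 2:
            raise SchemaError(f"{where}: field 'r_bounds' must be a [lower, upper] pair")
        r_bounds = (float(r_bounds[0]), float(r_bounds[1]))
    return SpeciesProfile(
        name=name,
        r_mean=_get_number(d, "r_mean", where),
        K=_get_number(d, "K", where),
        threshold_quasi_extinct=_get_number(thresholds, "quasi_extinct", f"{where}.thresholds"),
        threshold_low=_get_number(thresholds, "low", f"{where}.thresholds"),
        threshold_high=_get_number(thresholds, "high", f"{where}.thresholds"),
        threshold_overabundant=_get_number(thresholds, "overabundant", f"{where}.thresholds"),
        r_bounds=r_bounds,
        **sd_kwargs,
    )


def _parse_grid(d: Mapping[str, Any], where: str, default: GridRange) -> GridRange:
    if not d:
        return default
    d = _require_mapping(d, where)
    return GridRange(
        min=_get_number(d, "min", where, default.min),
        max=_get_number(d, "max", where, default.max),
        step=_get_number(d, "step", where, default.step),
    )


def parse_config(data: Any, source: str = "<config>") -> ExperimentConfig:
    """Build a validated :class:`ExperimentConfig` from parsed YAML/JSON data."""
    d = _require_mapping(data, source)
    unknown = set(d) - {"species", "experiment", "grids", "evaluation_sets", "strategies"}
    if unknown:
        raise SchemaError(f"{source}: unknown top-level fields {sorted(unknown)}")
    species_raw = d.get("species")
    if not isinstance(species_raw, Sequence) or isinstance(species_raw, str) or not species_raw:
        raise SchemaError(f"{source}: field 'species' must be a non-empty list")
    species = tuple(_parse_species(s, i) for i, s in enumerate(species_raw))

    exp = _require_mapping(d.get("experiment", {}), f"{source}.experiment")
    grids = _require_mapping(d.get("grids", {}), f"{source}.grids")
    defaults = ExperimentConfig(species=species)

    tp = _require_mapping(grids.get("threshold_proportional", {}), f"{source}.grids.threshold_proportional")

    def enum_list(key: str, enum_cls: type[enum.Enum], default: tuple) -> tuple:
        raw = exp.get(key)
        if raw is None:
            return default
        if not isinstance(raw, Sequence) or isinstance(raw, str):
            raise SchemaError(f"{source}.experiment: field {key!r} must be a list")
        try:
            return tuple(enum_cls(v) for v in raw)
        except ValueError as e:
            raise SchemaError(f"{source}.experiment: field {key!r}: {e}") from None

    sets_raw = d.get("evaluation_sets")
    if sets_raw is None:
        sets = COMPOSITE_SET_NAMES
    elif not isinstance(sets_raw, Sequence) or isinstance(sets_raw, str):
        raise SchemaError(f"{source}: field 'evaluation_sets' must be a list")
    else:
        sets = tuple(sets_raw)

    strategies_raw = d.get("strategies")
    if strategies_raw is None:
        strategies = tuple(StrategyKind)
    else:
        if not isinstance(strategies_raw, Sequence) or isinstance(strategies_raw, str):
            raise SchemaError(f"{source}: field 'strategies' must be a list")
        try:
            strategies = tuple(StrategyKind(v) for v in strategies_raw)
        except ValueError as e:
            raise SchemaError(f"{source}: field 'strategies': {e}") from None

    return ExperimentConfig(
        species=species,
        timeframe_T=int(_get_number(exp, "timeframe", f"{source}.experiment", defaults.timeframe_T)),
        n_replicates=int(_get_number(exp, "replicates", f"{source}.experiment", defaults.n_replicates)),
        master_seed=int(_get_number(exp, "master_seed", f"{source}.experiment", defaults.master_seed)),
        variance_partition=_get_number(
            exp, "variance_partition", f"{source}.experiment", defaults.variance_partition
        ),
        extinction_floor=_get_number(
            exp, "extinction_floor", f"{source}.experiment", defaults.extinction_floor
        ),
        metrics_on=exp.get("metrics_on", defaults.metrics_on),
        tp_surplus=bool(exp.get("tp_surplus", defaults.tp_surplus)),
        round_quotas=bool(exp.get("round_quotas", defaults.round_quotas)),
        constant_grid=_parse_grid(grids.get("constant", {}), f"{source}.grids.constant", defaults.constant_grid),
        proportion_grid=_parse_grid(
            grids.get("proportional", {}), f"{source}.grids.proportional", defaults.proportion_grid
        ),
        tp_proportion_grid=_parse_grid(
            tp.get("proportion", {}),
            f"{source}.grids.threshold_proportional.proportion",
            defaults.tp_proportion_grid,
        ),
        threshold_step=_get_number(
            tp, "threshold_step", f"{source}.grids.threshold_proportional", defaults.threshold_step
        ),
        strategies=strategies,
        evaluation_sets=sets,
        variability_levels=enum_list("variability_levels", Variability, defaults.variability_levels),
        start_scenarios=enum_list("start_scenarios", StartScenario, defaults.start_scenarios),
        output_dir=exp.get("output_dir"),
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML (or JSON, a YAML subset) config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigFileError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigFileError(f"config file {path} is not valid YAML: {e}") from e
    return parse_config(data, source=str(path))


def default_config() -> ExperimentConfig:
    """The shipped default configuration (three-species factorial)."""
    text = resources.files("harvestmse").joinpath("data/default_config.yaml").read_text()
    return parse_config(yaml.safe_load(text), source="default_config.yaml")


# --------------------------------------------------------------------------
# Grid enumeration

def build_environmental_grid(config: ExperimentConfig) -> list[EnvironmentalContext]:
    """All environmental contexts, in species order then SID ascending."""
    out = []
    for species in config.species:
        cells = [
            EnvironmentalContext(species, variability, start)
            for start in config.start_scenarios
            for variability in config.variability_levels
        ]
        cells.sort(key=lambda c: c.sid)
        out.extend(cells)
    return out


def build_decision_grid(
    config: ExperimentConfig, species: SpeciesProfile
) -> list[HarvestStrategySpec]:
    """All harvest strategy specs for one species, in deterministic order.

    Order: no-harvest, then constants ascending, proportions ascending, and
    the threshold-proportional cross product (proportion ascending, then
    threshold ascending).  Constants and thresholds are expressed in config
    as fractions of the species' moderate size and converted to individuals
    here.
    """
    mod = species.moderate_size
    out: list[HarvestStrategySpec] = []
    for kind in config.strategies:
        if kind is StrategyKind.NO_HARVEST:
            out.append(HarvestStrategySpec(kind))
        elif kind is StrategyKind.CONSTANT:
            values = [round(f * mod, 9) for f in config.constant_grid.values()]
            if not values:
                raise InvariantError(
                    f"grid 'constant' produces no values for species {species.name!r}"
                )
            out.extend(HarvestStrategySpec(kind, constant_c=c) for c in values)
        elif kind is StrategyKind.PROPORTIONAL:
            values = config.proportion_grid.values()
            if not values:
                raise InvariantError("grid 'proportional' produces no values")
            out.extend(HarvestStrategySpec(kind, proportion_p=p) for p in values)
        elif kind is StrategyKind.THRESHOLD_PROPORTIONAL:
            props = config.tp_proportion_grid.values()
            lo = species.threshold_quasi_extinct
            thresholds = []
            k = 0
            while True:
                v = lo + k * config.threshold_step * mod
                if v > mod + 1e-9:
                    break
                thresholds.append(min(v, mod))
                k += 1
            if not props or not thresholds:
                raise InvariantError(
                    f"grid 'threshold_proportional' produces no values for species "
                    f"{species.name!r}"
                )
            out.extend(
                HarvestStrategySpec(kind, proportion_p=p, threshold_T=t)
                for p in props
                for t in thresholds
            )
    for spec in out:
        spec.validate_for_species(species)
    return out


def total_model_count(config: ExperimentConfig) -> int:
    """Number of environment x strategy x parameter models in the factorial."""
    n_ctx_per_species = len(config.variability_levels) * len(config.start_scenarios)
    return sum(
        n_ctx_per_species * len(build_decision_grid(config, s)) for s in config.species
    )
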