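"""Run configuration.

:class:`SimulationConfig` collects every numeric parameter of the model in one
frozen dataclass whose defaults are the model's standard study conditions:
host/parasite population sizes of 500/250 (250/125 during the isolated burn-in
phase of a competitive simulation, 1000/250 once the populations are merged),
1000 generations, a 150-step host life preceded by 5 equilibrium steps, a
50-step developmental window, a protein-use coefficient of 0.01, per-timestep
activation budgets of 0.1 (scarce) and 1.0 (plentiful), a 30% per-generation
death cap with a parasite-burden death threshold of 0.9, and host/parasite
mutation rates of 5e-3 and 1e-2 with their event weights.

Configs round-trip losslessly through JSON (:func:`load_config` /
:func:`save_config`); unknown keys and out-of-range values are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

SCARCE = "scarce"
PLENTIFUL = "plentiful"
ALTERNATING = "alternating"
RESOURCE_CONDITIONS = (SCARCE, PLENTIFUL, ALTERNATING)

SYNCHRONOUS = "synchronous"
ASYNCHRONOUS = "asynchronous"
SYNCHRONIES = (SYNCHRONOUS, ASYNCHRONOUS)

DEVELOPMENT_FIRST = "development-first"
DEVELOPMENT_LAST = "development-last"
SIGNAL_ORDERS = (DEVELOPMENT_FIRST, DEVELOPMENT_LAST)

#: Readings of the developmental-signal formula: ``sin(x/2) + 0.5`` (default)
#: or ``sin(x)/2 + 0.5``.
HALF_ANGLE = "half-angle"
HALF_AMPLITUDE = "half-amplitude"
SIGNAL_VARIANTS = (HALF_ANGLE, HALF_AMPLITUDE)


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable parameters of a simulation, with standard defaults."""

    # population sizes
    host_population: int = 500
    parasite_population: int = 250
    burn_in_host_population: int = 250
    burn_in_parasite_population: int = 125
    competition_host_population: int = 1000
    competition_parasite_population: int = 250

    # horizons
    generations: int = 1000
    burn_in_generations: int = 500
    competition_generations: int = 1000

    # life phase
    life_steps: int = 150
    equilibrium_steps: int = 5
    development_window: int = 50

    # dynamics
    use_coef: float = 0.01
    initial_active: float = 0.5
    parasite_inoculum: float = 0.5
    connection_probability: float = 0.5
    resource_condition: str = SCARCE
    scarce_limit: float = 0.1
    plentiful_limit: float = 1.0

    # selection
    death_cap: float = 0.30
    death_threshold: float = 0.9

    # mutation
    host_mutation_rate: float = 5e-3
    # (add edge, delete edge, alter coefficient, delete protein, duplicate protein)
    host_mutation_weights: tuple[float, ...] = (0.25, 0.25, 0.30, 0.10, 0.10)
    parasite_mutation_rate: float = 1e-2
    # (retarget, redraw coefficient)
    parasite_mutation_weights: tuple[float, ...] = (0.5, 0.5)

    # parasite constants
    parasite_self_coefficient: float = 0.8
    parasite_detector_coefficient: float = 1.0
    effector_to_parasite_coefficient: float = -1.0
    parasite_target_domain: int = 8

    # scenario
    synchrony: str = SYNCHRONOUS
    signal_order: str = DEVELOPMENT_FIRST
    signal_variant: str = HALF_ANGLE

    # bookkeeping
    snapshot_interval: int = 0
    seed: int | None = None


_FIELDS = {f.name: f for f in dataclasses.fields(SimulationConfig)}


def validate_config(config: SimulationConfig) -> SimulationConfig:
    """Raise :class:`ValueError` on out-of-range or inconsistent parameters."""

    def require(cond: bool, msg: str) -> None:
        if not cond:
            raise ValueError(f"invalid configuration: {msg}")

    for name in (
        "host_population",
        "parasite_population",
        "burn_in_host_population",
        "burn_in_parasite_population",
        "competition_host_population",
        "competition_parasite_population",
        "generations",
        "burn_in_generations",
        "competition_generations",
        "life_steps",
        "development_window",
        "parasite_target_domain",
    ):
        require(int(getattr(config, name)) > 0, f"{name} must be positive")
    require(config.equilibrium_steps >= 0, "equilibrium_steps must be >= 0")
    require(config.snapshot_interval >= 0, "snapshot_interval must be >= 0")
    require(
        config.life_steps >= 2 * config.development_window,
        "life_steps must cover the developmental window and an "
        "equally long infection window after it",
    )
    require(config.use_coef >= 0, "use_coef must be >= 0")
    require(0 <= config.initial_active <= 1, "initial_active must lie in [0, 1]")
    require(0 <= config.parasite_inoculum <= 1, "parasite_inoculum must lie in [0, 1]")
    require(
        0 <= config.connection_probability <= 1,
        "connection_probability must lie in [0, 1]",
    )
    require(config.scarce_limit > 0, "scarce_limit must be > 0")
    require(config.plentiful_limit > 0, "plentiful_limit must be > 0")
    require(0 <= config.death_cap <= 1, "death_cap must lie in [0, 1]")
    require(0 <= config.death_threshold <= 1, "death_threshold must lie in [0, 1]")
    require(0 <= config.host_mutation_rate <= 1, "host_mutation_rate must lie in [0, 1]")
    require(
        0 <= config.parasite_mutation_rate <= 1,
        "parasite_mutation_rate must lie in [0, 1]",
    )
    for name, n_events in (("host_mutation_weights", 5), ("parasite_mutation_weights", 2)):
        weights = getattr(config, name)
        require(len(weights) == n_events, f"{name} must list {n_events} weights")
        require(all(w >= 0 for w in weights), f"{name} must be non-negative")
        require(abs(sum(weights) - 1.0) < 1e-9, f"{name} must sum to 1")
    require(config.resource_condition in RESOURCE_CONDITIONS, "unknown resource_condition")
    require(config.synchrony in SYNCHRONIES, "unknown synchrony")
    require(config.signal_order in SIGNAL_ORDERS, "unknown signal_order")
    require(config.signal_variant in SIGNAL_VARIANTS, "unknown signal_variant")
    require(
        config.parasite_population <= config.host_population,
        "more parasites than hosts",
    )
    require(
        config.burn_in_parasite_population <= config.burn_in_host_population,
        "more burn-in parasites than hosts",
    )
    return config


def resource_limit(config: SimulationConfig, generation: int) -> float:
    """Per-timestep budget for newly activated protein in ``generation``.

    Under the alternating condition the budget switches every generation,
    scarce on even generation indices and plentiful on odd ones.
    """
    if config.resource_condition == SCARCE:
        return config.scarce_limit
    if config.resource_condition == PLENTIFUL:
        return config.plentiful_limit
    if config.resource_condition == ALTERNATING:
        return config.scarce_limit if generation % 2 == 0 else config.plentiful_limit
    raise ValueError(f"unknown resource condition {config.resource_condition!r}")


def config_to_dict(config: SimulationConfig) -> dict:
    data = dataclasses.asdict(config)
    for key, value in data.items():
        if isinstance(value, tuple):
            data[key] = list(value)
    return data


def config_from_dict(data: dict) -> SimulationConfig:
    unknown = set(data) - set(_FIELDS)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return validate_config(replace(SimulationConfig(), **coerced))


def load_config(path: str | Path) -> SimulationConfig:
    """Read a JSON config file; absent keys fall back to the defaults."""
    text = Path(path).read_text()
    data = json.loads(text) if text.strip() else {}
    if not isinstance(data, dict):
        raise ValueError("configuration file must contain a JSON object")
    return config_from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(config), indent=2) + "\n")


def config_hash(config: SimulationConfig) -> str:
    """Stable short digest of a config, used in run manifests."""
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
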