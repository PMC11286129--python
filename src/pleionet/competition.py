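"""Two-phase competitive simulations.

A shared-effector and an independent-effector host population (250 hosts,
125 parasites each by default) first co-evolve in isolation for a burn-in of
250, 500 or 1000 generations.  The populations are then merged along with
their parasites and compete in a single fitness-weighted reproduction market
(offspring inherit their parent's architecture, host population restored to
1000 after each generation).  The merged parasites form one pool and infect
hosts of either architecture uniformly, so prevalence is 25% during
competition.  A competition resolves when one architecture goes extinct; a
draw is declared if both survive to the generation horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from . import model_core as mc
from .config import (
    ALTERNATING,
    PLENTIFUL,
    RESOURCE_CONDITIONS,
    SCARCE,
    SYNCHRONIES,
    SimulationConfig,
)
from .evolution import (
    ExtinctionError,
    PopulationHistory,
    PopulationState,
    RngStreams,
    run_coevolution,
    run_generation,
)

DRAW = "draw"


@dataclass
class CompetitionResult:
    """Outcome of one competitive simulation."""

    winner: str  # "shared", "independent" or "draw"
    generations_to_resolution: int
    composition: np.ndarray  # fraction shared, index 0 = merged start
    burn_in_generations: int
    synchrony: str
    resource_condition: str
    seed: int | None = None
    failed: str | None = None

    @property
    def final_shared_fraction(self) -> float:
        return float(self.composition[-1])


def run_burn_in(
    architecture: str,
    config: SimulationConfig,
    seed,
) -> PopulationState:
    """Isolated co-evolution at burn-in sizes for ``burn_in_generations``."""
    history = run_coevolution(
        config,
        seed,
        architecture,
        generations=config.burn_in_generations,
        host_target=config.burn_in_host_population,
        parasite_target=config.burn_in_parasite_population,
    )
    if history.cause is not None:
        raise ExtinctionError(history.cause, history.final_state.generation)
    return history.final_state


def run_competition(
    shared_state: PopulationState,
    independent_state: PopulationState,
    config: SimulationConfig,
    seed,
) -> CompetitionResult:
    """Merge two burn-in endpoints and compete to extinction or draw."""
    streams = RngStreams.from_seed(seed)
    hosts = list(shared_state.hosts) + list(independent_state.hosts)
    parasites = list(shared_state.parasites) + list(independent_state.parasites)
    generation = max(shared_state.generation, independent_state.generation)

    def shared_fraction(population: list[mc.Host]) -> float:
        return sum(1 for h in population if h.architecture == mc.SHARED) / len(population)

    composition = [shared_fraction(hosts)]
    winner = DRAW
    resolved_at = config.competition_generations
    for g in range(config.competition_generations):
        hosts, parasites, stats = run_generation(
            hosts,
            parasites,
            generation + g,
            config,
            streams,
            host_target=config.competition_host_population,
            parasite_target=config.competition_parasite_population,
        )
        fraction = stats["shared_fraction"]
        composition.append(fraction)
        if fraction == 0.0:
            winner, resolved_at = mc.INDEPENDENT, g + 1
            break
        if fraction == 1.0:
            winner, resolved_at = mc.SHARED, g + 1
            break

    return CompetitionResult(
        winner=winner,
        generations_to_resolution=resolved_at,
        composition=np.asarray(composition),
        burn_in_generations=config.burn_in_generations,
        synchrony=config.synchrony,
        resource_condition=config.resource_condition,
    )


def run_competitive_simulation(config: SimulationConfig, seed) -> CompetitionResult:
    """Both burn-ins plus the competition, from one seed."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    shared_seed, independent_seed, competition_seed = ss.spawn(3)
    try:
        shared_state = run_burn_in(mc.SHARED, config, shared_seed)
        independent_state = run_burn_in(mc.INDEPENDENT, config, independent_seed)
    except ExtinctionError as exc:
        return CompetitionResult(
            winner=DRAW,
            generations_to_resolution=0,
            composition=np.asarray([0.5]),
            burn_in_generations=config.burn_in_generations,
            synchrony=config.synchrony,
            resource_condition=config.resource_condition,
            failed=str(exc),
        )
    result = run_competition(shared_state, independent_state, config, competition_seed)
    if isinstance(seed, (int, np.integer)):
        result.seed = int(seed)
    return result


def run_campaign(
    config: SimulationConfig,
    replicates: int,
    *,
    synchronies: tuple[str, ...] = SYNCHRONIES,
    resources: tuple[str, ...] = (SCARCE, ALTERNATING, PLENTIFUL),
    burn_ins: tuple[int, ...] = (250, 500, 1000),
    seed=0,
) -> pd.DataFrame:
    """Seeded replicates over the condition grid; tidy results table.

    Each row records its own seed, so any row can be reproduced in isolation
    with :func:`run_competitive_simulation`.
    """
    for r in resources:
        if r not in RESOURCE_CONDITIONS:
            raise ValueError(f"unknown resource condition {r!r}")
    cells = [
        (sync, resource, burn_in)
        for sync in synchronies
        for resource in resources
        for burn_in in burn_ins
    ]
    n_rows = len(cells) * replicates
    row_seeds = np.random.SeedSequence(seed).generate_state(max(n_rows, 1)) & 0x7FFFFFFF
    rows = []
    i = 0
    for sync, resource, burn_in in cells:
        cell_config = dc_replace(
            config,
            synchrony=sync,
            resource_condition=resource,
            burn_in_generations=burn_in,
        )
        for replicate in range(replicates):
            row_seed = int(row_seeds[i])
            i += 1
            result = run_competitive_simulation(cell_config, row_seed)
            rows.append(
                {
                    "synchrony": sync,
                    "resources": resource,
                    "burn_in": burn_in,
                    "replicate": replicate,
                    "seed": row_seed,
                    "winner": result.winner,
                    "generations": result.generations_to_resolution,
                    "final_shared_fraction": result.final_shared_fraction,
                }
            )
    columns = [
        "synchrony",
        "resources",
        "burn_in",
        "replicate",
        "seed",
        "winner",
        "generations",
        "final_shared_fraction",
    ]
    return pd.DataFrame(rows, columns=columns)
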