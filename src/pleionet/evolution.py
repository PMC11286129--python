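"""The generation cycle: infection, death, reproduction, mutation.

Each generation: every parasite infects one distinct host (prevalence =
parasites / hosts), all lives are simulated, fitness is computed, then up to
30% of each population dies.  Host deaths prioritise uncontrolled infections
(Par.Area above the 0.9 death threshold); if those exceed the cap a uniform
subset of exactly the cap dies, otherwise remaining deaths are drawn in a
single randomized pass over survivors, each dying with probability
``1 - W / W_max``.  The least-fit 30% of parasites die.  Surviving hosts
reproduce fitness-weighted (with replacement) until the population is
restored; parasites reproduce in descending fitness order, contributing 1, 2
or 3 offspring according to their final within-host abundance (thirds of
[0, 1]), cycling until the population is replenished.  Offspring mutate
rarely (hosts 5e-3, parasites 1e-2) and receive exactly one event.

All randomness flows from named substreams spawned from a single seed
(:class:`RngStreams`), so identical seeds give bit-identical histories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import lifecycle, model_core as mc
from .config import SimulationConfig, resource_limit

HOST_EVENTS = (
    "add_edge",
    "delete_edge",
    "alter_coefficient",
    "delete_protein",
    "duplicate_protein",
)
PARASITE_EVENTS = ("retarget", "new_coefficient")


class ExtinctionError(RuntimeError):
    """A population has no survivors left to reproduce."""

    def __init__(self, population: str, generation: int | None = None):
        self.population = population
        self.generation = generation
        super().__init__(f"{population} population went extinct")


@dataclass
class RngStreams:
    """Named random substreams so analyses can hold some sources fixed."""

    initialization: np.random.Generator
    infection: np.random.Generator
    death: np.random.Generator
    mutation: np.random.Generator

    @classmethod
    def from_seed(cls, seed) -> "RngStreams":
        if isinstance(seed, RngStreams):
            return seed
        if isinstance(seed, np.random.Generator):
            children = seed.spawn(4)
        else:
            if not isinstance(seed, np.random.SeedSequence):
                seed = np.random.SeedSequence(seed)
            children = [np.random.default_rng(s) for s in seed.spawn(4)]
        return cls(*children)


# ---------------------------------------------------------------------------
# infection and death
# ---------------------------------------------------------------------------

def assign_infections(
    hosts: list, parasites: list, rng: np.random.Generator
) -> np.ndarray:
    """Host index for each parasite; distinct hosts, uniform without replacement."""
    if len(parasites) > len(hosts):
        raise ValueError("more parasites than hosts")
    return rng.choice(len(hosts), size=len(parasites), replace=False)


def select_host_deaths(
    parasite_areas: np.ndarray,
    fitness: np.ndarray,
    death_cap: float,
    death_threshold: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of hosts that die this generation (at most ``cap`` of them).

    Uncontrolled infections die first; any excess over the cap is thinned
    uniformly back into the population.  Remaining deaths come from a single
    randomized pass over the other hosts, each dying with probability
    ``1 - W / W_max`` — the fittest host always survives its visit.
    """
    n = len(fitness)
    cap = math.floor(death_cap * n)
    burdened = np.flatnonzero(parasite_areas > death_threshold)
    if len(burdened) >= cap:
        if len(burdened) == cap:
            return burdened
        return np.sort(rng.choice(burdened, size=cap, replace=False))
    deaths = list(burdened)
    others = np.setdiff1d(np.arange(n), burdened)
    remaining = cap - len(deaths)
    if remaining > 0 and len(others) > 0:
        w_max = fitness[others].max()
        for i in rng.permutation(others):
            if remaining == 0:
                break
            if rng.random() < 1.0 - fitness[i] / w_max:
                deaths.append(int(i))
                remaining -= 1
    return np.sort(np.asarray(deaths, dtype=int))


def select_parasite_deaths(fitness: np.ndarray, death_cap: float) -> np.ndarray:
    """The least-fit ``floor(cap * N)`` parasites; ties broken by input order."""
    k = math.floor(death_cap * len(fitness))
    order = np.argsort(fitness, kind="stable")
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

def mutate_host(
    host: mc.Host,
    rng: np.random.Generator,
    weights: tuple[float, ...] = (0.25, 0.25, 0.30, 0.10, 0.10),
) -> mc.Host:
    """Apply exactly one mutation event; infeasible events are no-ops.

    Events and relative probabilities: add edge 0.25 (any legal ordered pair,
    cross-network allowed), delete edge 0.25, redraw one coefficient 0.30,
    delete a signalling protein 0.10 (skipped when its network would lose its
    last signalling protein), duplicate a signalling protein with all its
    edges 0.10.  Detectors and effectors are never deleted or duplicated.
    """
    event = HOST_EVENTS[rng.choice(len(HOST_EVENTS), p=weights)]

    if event == "add_edge":
        existing = {(e.source, e.target) for e in host.edges}
        candidates = [
            pair
            for pair in host.valid_pairs(cross_network=True)
            if pair not in existing
        ]
        if not candidates:
            return host
        source, target = candidates[rng.integers(len(candidates))]
        new_edge = mc.RegulatoryEdge(source, target, float(rng.uniform(-1.0, 1.0)))
        return replace(host, edges=host.edges + (new_edge,))

    if event == "delete_edge":
        if not host.edges:
            return host
        victim = int(rng.integers(len(host.edges)))
        return replace(
            host, edges=tuple(e for i, e in enumerate(host.edges) if i != victim)
        )

    if event == "alter_coefficient":
        if not host.edges:
            return host
        which = int(rng.integers(len(host.edges)))
        edges = list(host.edges)
        edges[which] = replace(edges[which], coefficient=float(rng.uniform(-1.0, 1.0)))
        return replace(host, edges=tuple(edges))

    signalling = [p for p in host.proteins if p.role == mc.SIGNAL]

    if event == "delete_protein":
        victim = signalling[rng.integers(len(signalling))]
        peers = [p for p in signalling if p.network == victim.network]
        if len(peers) <= 1:
            return host
        proteins = tuple(p for p in host.proteins if p.id != victim.id)
        edges = tuple(
            e for e in host.edges if victim.id not in (e.source, e.target)
        )
        return replace(host, proteins=proteins, edges=edges)

    # duplicate_protein: copy the protein with all incoming and outgoing edges
    original = signalling[rng.integers(len(signalling))]
    copy = mc.Protein(host.next_protein_id, mc.SIGNAL, original.network)
    new_edges = list(host.edges)
    for e in host.edges:
        if e.source == original.id and e.target == original.id:
            new_edges.append(mc.RegulatoryEdge(copy.id, copy.id, e.coefficient))
        elif e.source == original.id:
            new_edges.append(mc.RegulatoryEdge(copy.id, e.target, e.coefficient))
        elif e.target == original.id:
            new_edges.append(mc.RegulatoryEdge(e.source, copy.id, e.coefficient))
    return replace(host, proteins=host.proteins + (copy,), edges=tuple(new_edges))


def mutate_parasite(
    parasite: mc.Parasite,
    rng: np.random.Generator,
    weights: tuple[float, ...] = (0.5, 0.5),
    target_domain: int = 8,
) -> mc.Parasite:
    """Retarget (uniform over the index domain) or redraw the coefficient."""
    event = PARASITE_EVENTS[rng.choice(len(PARASITE_EVENTS), p=weights)]
    if event == "retarget":
        return replace(parasite, target_index=int(rng.integers(target_domain)))
    return replace(parasite, target_coefficient=float(rng.uniform(-1.0, 1.0)))


# ---------------------------------------------------------------------------
# reproduction
# ---------------------------------------------------------------------------

def reproduce_hosts(
    survivors: list[mc.Host],
    fitness: np.ndarray,
    target_size: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[mc.Host]:
    """Survivors plus fitness-weighted offspring up to ``target_size``."""
    if not survivors:
        raise ExtinctionError("host")
    n_offspring = target_size - len(survivors)
    if n_offspring <= 0:
        return list(survivors)
    probabilities = np.asarray(fitness, dtype=float)
    probabilities = probabilities / probabilities.sum()
    parents = rng.choice(len(survivors), size=n_offspring, p=probabilities)
    offspring = []
    for parent in parents:
        child = survivors[parent]
        if rng.random() < config.host_mutation_rate:
            child = mutate_host(child, rng, config.host_mutation_weights)
        offspring.append(child)
    return list(survivors) + offspring


def parasite_offspring_count(abundance: float) -> int:
    """1, 2 or 3 offspring for final abundance in thirds of [0, 1]."""
    if not 0.0 <= abundance <= 1.0:
        raise ValueError(f"abundance {abundance} outside [0, 1]")
    if abundance <= 1.0 / 3.0:
        return 1
    if abundance <= 2.0 / 3.0:
        return 2
    return 3


def reproduce_parasites(
    survivors: list[mc.Parasite],
    fitness: np.ndarray,
    abundance: np.ndarray,
    target_size: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[mc.Parasite]:
    """Survivors plus offspring in descending-fitness order.

    Each survivor contributes its abundance-determined offspring count per
    pass; passes repeat until the population is replenished, the final batch
    truncated.
    """
    if not survivors:
        raise ExtinctionError("parasite")
    order = np.argsort(-np.asarray(fitness, dtype=float), kind="stable")
    offspring: list[mc.Parasite] = []
    need = target_size - len(survivors)
    while need > 0:
        for i in order:
            if need == 0:
                break
            batch = min(parasite_offspring_count(float(abundance[i])), need)
            for _ in range(batch):
                child = survivors[i]
                if rng.random() < config.parasite_mutation_rate:
                    child = mutate_parasite(
                        child,
                        rng,
                        config.parasite_mutation_weights,
                        config.parasite_target_domain,
                    )
                offspring.append(child)
            need -= batch
    return list(survivors) + offspring


# ---------------------------------------------------------------------------
# generation loop
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    """Hosts and parasites at a generation boundary."""

    hosts: list[mc.Host]
    parasites: list[mc.Parasite]
    generation: int = 0


@dataclass
class PopulationHistory:
    """Per-generation summaries plus the final populations."""

    records: list[dict] = field(default_factory=list)
    final_state: PopulationState | None = None
    snapshots: dict[int, list[mc.Host]] = field(default_factory=dict)
    cause: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def run_generation(
    hosts: list[mc.Host],
    parasites: list[mc.Parasite],
    generation: int,
    config: SimulationConfig,
    streams: RngStreams,
    *,
    host_target: int,
    parasite_target: int,
) -> tuple[list[mc.Host], list[mc.Parasite], dict]:
    """One full generation; returns the next populations and summary stats."""
    schedule = lifecycle.SignallingSchedule.from_config(config)
    limit = resource_limit(config, generation)
    n = len(hosts)

    host_idx = assign_infections(hosts, parasites, streams.infection)
    links: list[mc.ParasiteLinks | None] = [None] * n
    infection_steps = np.full(n, -1, dtype=int)
    for k, h in enumerate(host_idx):
        links[h] = lifecycle.attach_parasite(
            hosts[h],
            parasites[k],
            effector_coefficient=config.effector_to_parasite_coefficient,
        )
        infection_steps[h] = schedule.draw_infection_step(streams.infection)

    lives = lifecycle.simulate_population(
        hosts,
        links,
        infection_steps,
        schedule=schedule,
        resource_limit=limit,
        use_coef=config.use_coef,
        equilibrium_steps=config.equilibrium_steps,
        initial_active=config.initial_active,
        inoculum=config.parasite_inoculum,
        signal_variant=config.signal_variant,
    )
    fitness = lives.fitness
    parasite_areas = lives.parasite_area
    parasite_fit = parasite_areas[host_idx]
    parasite_abundance = lives.parasite_final[host_idx]

    deaths = select_host_deaths(
        parasite_areas, fitness, config.death_cap, config.death_threshold, streams.death
    )
    dead = np.zeros(n, dtype=bool)
    dead[deaths] = True
    infected_deaths = int(np.sum(parasite_areas[deaths] > config.death_threshold))
    survivors = [hosts[i] for i in range(n) if not dead[i]]
    new_hosts = reproduce_hosts(
        survivors, fitness[~dead], host_target, config, streams.mutation
    )

    p_deaths = select_parasite_deaths(parasite_fit, config.death_cap)
    p_dead = np.zeros(len(parasites), dtype=bool)
    p_dead[p_deaths] = True
    p_survivors = [parasites[i] for i in range(len(parasites)) if not p_dead[i]]
    new_parasites = reproduce_parasites(
        p_survivors,
        parasite_fit[~p_dead],
        parasite_abundance[~p_dead],
        parasite_target,
        config,
        streams.mutation,
    )

    n_shared = sum(1 for h in new_hosts if h.architecture == mc.SHARED)
    stats = {
        "generation": generation,
        "resource_limit": limit,
        "prevalence": len(parasites) / n,
        "mean_host_fitness": float(fitness.mean()),
        "var_host_fitness": float(fitness.var()),
        "mean_parasite_fitness": float(parasite_fit.mean()),
        "host_deaths": int(len(deaths)),
        "infected_host_deaths": infected_deaths,
        "host_death_fraction": len(deaths) / n,
        "n_hosts": len(new_hosts),
        "n_parasites": len(new_parasites),
        "n_shared_hosts": n_shared,
        "shared_fraction": n_shared / len(new_hosts),
    }
    return new_hosts, new_parasites, stats


def run_coevolution(
    config: SimulationConfig,
    seed,
    architecture: str = mc.INDEPENDENT,
    *,
    generations: int | None = None,
    host_target: int | None = None,
    parasite_target: int | None = None,
) -> PopulationHistory:
    """Co-evolve one host population with its parasites.

    ``seed`` may be an int, a Generator, or prepared :class:`RngStreams`.
    Population sizes and horizon default to the config's independent-evolution
    values; the competition module overrides them for burn-in phases.
    """
    streams = RngStreams.from_seed(seed)
    host_target = host_target or config.host_population
    parasite_target = parasite_target or config.parasite_population
    generations = generations if generations is not None else config.generations

    hosts = [
        mc.init_host(
            architecture,
            streams.initialization,
            connection_probability=config.connection_probability,
        )
        for _ in range(host_target)
    ]
    parasites = [
        mc.init_parasite(
            streams.initialization, target_domain=config.parasite_target_domain
        )
        for _ in range(parasite_target)
    ]

    history = PopulationHistory()
    generation = 0
    for generation in range(generations):
        try:
            hosts, parasites, stats = run_generation(
                hosts,
                parasites,
                generation,
                config,
                streams,
                host_target=host_target,
                parasite_target=parasite_target,
            )
        except ExtinctionError as exc:
            history.cause = f"extinct:{exc.population}@{generation}"
            break
        history.records.append(stats)
        if config.snapshot_interval and (generation + 1) % config.snapshot_interval == 0:
            history.snapshots[generation] = list(hosts)
    history.final_state = PopulationState(hosts, parasites, generation + 1)
    return history
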