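"""Genotypes and resource-capped signalling dynamics.

A host is a pair of small signed regulatory networks, one immune and one
developmental.  Each network starts from a detector (which receives external
input: the developmental signal, or the parasite), three signalling proteins
and an effector (which produces the trait output).  In the *independent*
architecture the two networks have their own effectors (10 proteins); in the
*shared* architecture a single pleiotropic effector serves both networks
(9 proteins).

Every protein is a unit concentration pool split into an active fraction
``P*`` and the implicit inactive fraction ``1 - P*``; only the active fraction
regulates targets.  Per unit timestep the active fraction of protein ``i``
changes by

    d[Pi*] = (1 - Pi*) * sum_j k_ij Pj*  -  Pi* * sum_j I_ij Pj*  -  use_i,
    use_i  = use_coef * (number of outgoing interactions of i),

where positive edge coefficients feed the upregulatory sum ``k`` and the
magnitudes of negative coefficients feed the downregulatory sum ``I``.  A
resource condition caps the total newly activated protein per timestep: when
the sum of positive changes exceeds the budget, all positive changes are
scaled down proportionally.  Integration is forward Euler with dt = 1, active
fractions clamped to [0, 1] after each step.

A parasite is a minimal genotype: a target signalling protein in the host's
immune network, a signed regulatory coefficient on that target, a fixed
self-upregulation of 0.8 (replication) and a fixed +1 link to the host's
immune detector.  During infection it is treated as one extra node of the
immune network and obeys the same dynamics, including the resource cap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

DETECTOR = "detector"
SIGNAL = "signal"
EFFECTOR = "effector"
ROLES = (DETECTOR, SIGNAL, EFFECTOR)

IMMUNE = "immune"
DEVELOPMENTAL = "developmental"
SHARED = "shared"
NETWORKS = (IMMUNE, DEVELOPMENTAL, SHARED)

INDEPENDENT = "independent"
ARCHITECTURES = (INDEPENDENT, SHARED)

#: Key used for the within-host parasite node in delta maps.
PARASITE_NODE = -1

DEFAULT_USE_COEF = 0.01


@dataclass(frozen=True, order=True)
class Protein:
    """A network node: stable id, role and network membership."""

    id: int
    role: str
    network: str

    def networks(self) -> tuple[str, ...]:
        """Networks this protein belongs to (a shared effector is in both)."""
        if self.network == SHARED:
            return (IMMUNE, DEVELOPMENTAL)
        return (self.network,)


@dataclass(frozen=True, order=True)
class RegulatoryEdge:
    """Directed signed regulation ``source -> target``, coefficient in [-1, 1]."""

    source: int
    target: int
    coefficient: float


def shares_network(a: Protein, b: Protein) -> bool:
    return bool(set(a.networks()) & set(b.networks()))


def edge_allowed(source: Protein, target: Protein, *, cross_network: bool = False) -> bool:
    """Whether a regulatory edge ``source -> target`` is legal.

    Detectors and effectors may never connect directly (either direction);
    self-loops are legal on signalling proteins only.  At initialization only
    same-network pairs are valid (``cross_network=False``); mutation may add
    cross-network edges.
    """
    roles = {source.role, target.role}
    if DETECTOR in roles and EFFECTOR in roles:
        return False
    if source.id == target.id:
        return source.role == SIGNAL
    if not cross_network and not shares_network(source, target):
        return False
    return True


@dataclass(frozen=True)
class Host:
    """Immutable host genotype: architecture tag, protein roster, edge set.

    Proteins are kept sorted by id and edges by (source, target) so that
    structural equality and hashing are canonical; mutation returns new Host
    objects.
    """

    architecture: str
    proteins: tuple[Protein, ...]
    edges: tuple[RegulatoryEdge, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "proteins", tuple(sorted(self.proteins, key=lambda p: p.id))
        )
        object.__setattr__(
            self, "edges", tuple(sorted(self.edges, key=lambda e: (e.source, e.target)))
        )

    # -- roster helpers ---------------------------------------------------
    def protein(self, pid: int) -> Protein:
        for p in self.proteins:
            if p.id == pid:
                return p
        raise KeyError(f"no protein with id {pid}")

    def proteins_in(self, network: str) -> tuple[Protein, ...]:
        return tuple(p for p in self.proteins if network in p.networks())

    def signalling(self, network: str) -> tuple[Protein, ...]:
        return tuple(
            p for p in self.proteins if p.role == SIGNAL and p.network == network
        )

    def detector(self, network: str) -> Protein:
        for p in self.proteins:
            if p.role == DETECTOR and p.network == network:
                return p
        raise KeyError(f"no {network} detector")

    @property
    def immune_effector(self) -> Protein:
        for p in self.proteins:
            if p.role == EFFECTOR and p.network in (IMMUNE, SHARED):
                return p
        raise KeyError("no immune effector")

    @property
    def developmental_effector(self) -> Protein:
        for p in self.proteins:
            if p.role == EFFECTOR and p.network in (DEVELOPMENTAL, SHARED):
                return p
        raise KeyError("no developmental effector")

    @property
    def next_protein_id(self) -> int:
        return max(p.id for p in self.proteins) + 1

    def valid_pairs(self, *, cross_network: bool = False) -> list[tuple[int, int]]:
        """All legal ordered (source, target) id pairs, in canonical order."""
        return [
            (a.id, b.id)
            for a in self.proteins
            for b in self.proteins
            if edge_allowed(a, b, cross_network=cross_network)
        ]


@dataclass(frozen=True)
class Parasite:
    """Parasite genotype.

    ``target_index`` addresses the host's immune signalling proteins (sorted
    by id) modulo their count, so any parasite resolves a target on any host.
    The self- and detector-coefficients are constants of the model.
    """

    target_index: int
    target_coefficient: float
    self_coefficient: float = 0.8
    detector_coefficient: float = 1.0


@dataclass(frozen=True)
class ParasiteLinks:
    """A parasite's regulatory links once attached to a concrete host.

    ``target_id is None`` describes a non-disrupting parasite: it replicates
    and is attacked by the effector but cannot interfere with host signalling.
    """

    detector_id: int
    effector_id: int
    target_id: int | None
    target_coefficient: float
    self_coefficient: float = 0.8
    detector_coefficient: float = 1.0
    effector_coefficient: float = -1.0

    @property
    def out_degree(self) -> int:
        """Outgoing interactions of the parasite node (detector, self, target)."""
        return 2 + (self.target_id is not None)


@dataclass
class NetworkState:
    """Active fractions of every host protein plus, optionally, the parasite."""

    active: dict[int, float]
    parasite: float | None = None

    @classmethod
    def uniform(cls, host: Host, value: float = 0.5) -> "NetworkState":
        return cls({p.id: float(value) for p in host.proteins})

    def copy(self) -> "NetworkState":
        return NetworkState(dict(self.active), self.parasite)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _roster(architecture: str) -> tuple[Protein, ...]:
    if architecture == INDEPENDENT:
        return (
            Protein(0, DETECTOR, IMMUNE),
            Protein(1, SIGNAL, IMMUNE),
            Protein(2, SIGNAL, IMMUNE),
            Protein(3, SIGNAL, IMMUNE),
            Protein(4, EFFECTOR, IMMUNE),
            Protein(5, DETECTOR, DEVELOPMENTAL),
            Protein(6, SIGNAL, DEVELOPMENTAL),
            Protein(7, SIGNAL, DEVELOPMENTAL),
            Protein(8, SIGNAL, DEVELOPMENTAL),
            Protein(9, EFFECTOR, DEVELOPMENTAL),
        )
    if architecture == SHARED:
        return (
            Protein(0, DETECTOR, IMMUNE),
            Protein(1, SIGNAL, IMMUNE),
            Protein(2, SIGNAL, IMMUNE),
            Protein(3, SIGNAL, IMMUNE),
            Protein(4, DETECTOR, DEVELOPMENTAL),
            Protein(5, SIGNAL, DEVELOPMENTAL),
            Protein(6, SIGNAL, DEVELOPMENTAL),
            Protein(7, SIGNAL, DEVELOPMENTAL),
            Protein(8, EFFECTOR, SHARED),
        )
    raise ValueError(f"unknown architecture {architecture!r}")


def init_host(
    architecture: str,
    rng: np.random.Generator,
    *,
    connection_probability: float = 0.5,
) -> Host:
    """Random founder host.

    Every valid ordered same-network pair (including self-loops on signalling
    proteins, excluding detector-effector pairs) receives an edge with
    probability ``connection_probability``, coefficient drawn uniformly from
    [-1, 1].  No cross-network edges exist at initialization; the shared
    effector belongs to both networks, so its connections are within-network.
    """
    roster = _roster(architecture)
    probe = Host(architecture, roster, ())
    edges = []
    for source, target in probe.valid_pairs(cross_network=False):
        if rng.random() < connection_probability:
            edges.append(RegulatoryEdge(source, target, float(rng.uniform(-1.0, 1.0))))
    return Host(architecture, roster, tuple(edges))


def init_parasite(rng: np.random.Generator, *, target_domain: int = 8) -> Parasite:
    """Random founder parasite: uniform target index and coefficient."""
    return Parasite(
        target_index=int(rng.integers(target_domain)),
        target_coefficient=float(rng.uniform(-1.0, 1.0)),
    )


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def regulatory_deltas(
    state: NetworkState,
    host: Host,
    parasite_links: ParasiteLinks | None = None,
    use_coef: float = DEFAULT_USE_COEF,
    external_inputs: Mapping[int, float] | None = None,
) -> dict[int, float]:
    """Raw per-node change in active fraction for one unit timestep.

    ``external_inputs`` maps a protein id to an already-weighted contribution
    added to its upregulatory sum (used for the developmental signal, an
    external node with a +1 link to the developmental detector).  When
    ``parasite_links`` is given the parasite is one extra node: its delta is
    returned under :data:`PARASITE_NODE` and the host effector's link to it
    counts toward the effector's protein use.
    """
    act = state.active
    up = {p.id: 0.0 for p in host.proteins}
    down = {p.id: 0.0 for p in host.proteins}
    out = {p.id: 0 for p in host.proteins}
    for edge in host.edges:
        a = act[edge.source]  # KeyError -> edge references a missing protein
        if edge.coefficient >= 0:
            up[edge.target] += edge.coefficient * a
        else:
            down[edge.target] += -edge.coefficient * a
        out[edge.source] += 1
    if external_inputs:
        for pid, contribution in external_inputs.items():
            up[pid] += contribution

    deltas: dict[int, float] = {}
    if parasite_links is not None:
        if state.parasite is None:
            raise ValueError("parasite links given but state has no parasite abundance")
        abundance = state.parasite
        up[parasite_links.detector_id] += parasite_links.detector_coefficient * abundance
        if parasite_links.target_id is not None:
            coef = parasite_links.target_coefficient
            if coef >= 0:
                up[parasite_links.target_id] += coef * abundance
            else:
                down[parasite_links.target_id] += -coef * abundance
        out[parasite_links.effector_id] += 1
        par_up = parasite_links.self_coefficient * abundance
        par_down = -parasite_links.effector_coefficient * act[parasite_links.effector_id]
        deltas[PARASITE_NODE] = (
            (1.0 - abundance) * par_up
            - abundance * par_down
            - use_coef * parasite_links.out_degree
        )

    for p in host.proteins:
        pi = act[p.id]
        deltas[p.id] = (1.0 - pi) * up[p.id] - pi * down[p.id] - use_coef * out[p.id]
    return deltas


def apply_resource_cap(deltas: Mapping[int, float], limit: float) -> dict[int, float]:
    """Scale positive deltas so their sum does not exceed ``limit``.

    Negative deltas (inactivation) are never rescaled.  Identity when the
    budget is not binding.
    """
    if limit <= 0:
        raise ValueError("resource limit must be > 0")
    positive_sum = sum(v for v in deltas.values() if v > 0)
    if positive_sum <= limit:
        return dict(deltas)
    scale = limit / positive_sum
    return {k: (v * scale if v > 0 else v) for k, v in deltas.items()}


def step(
    state: NetworkState,
    host: Host,
    parasite_links: ParasiteLinks | None = None,
    *,
    resource_limit: float = np.inf,
    use_coef: float = DEFAULT_USE_COEF,
    external_inputs: Mapping[int, float] | None = None,
) -> NetworkState:
    """One forward-Euler timestep; all active fractions clamped to [0, 1]."""
    deltas = regulatory_deltas(state, host, parasite_links, use_coef, external_inputs)
    if np.isfinite(resource_limit):
        deltas = apply_resource_cap(deltas, resource_limit)
    new_active = {
        p.id: float(min(1.0, max(0.0, state.active[p.id] + deltas[p.id])))
        for p in host.proteins
    }
    parasite = state.parasite
    if parasite_links is not None:
        parasite = float(min(1.0, max(0.0, state.parasite + deltas[PARASITE_NODE])))
    return NetworkState(new_active, parasite)


# ---------------------------------------------------------------------------
# legality
# ---------------------------------------------------------------------------

def validate_host(host: Host) -> Host:
    """Raise :class:`ValueError` if a genotype violates the model's rules."""

    def fail(msg: str) -> None:
        raise ValueError(f"illegal host genotype: {msg}")

    if host.architecture not in ARCHITECTURES:
        fail(f"unknown architecture {host.architecture!r}")
    ids = [p.id for p in host.proteins]
    if len(ids) != len(set(ids)):
        fail("duplicate protein ids")
    by_id = {p.id: p for p in host.proteins}
    for p in host.proteins:
        if p.role not in ROLES:
            fail(f"unknown role {p.role!r}")
        if p.network not in NETWORKS:
            fail(f"unknown network {p.network!r}")
        if p.network == SHARED and p.role != EFFECTOR:
            fail("only an effector may be shared between networks")
    for network in (IMMUNE, DEVELOPMENTAL):
        detectors = [p for p in host.proteins if p.role == DETECTOR and p.network == network]
        if len(detectors) != 1:
            fail(f"{network} network must have exactly one detector")
        if not host.signalling(network):
            fail(f"{network} network must keep at least one signalling protein")
    effectors = [p for p in host.proteins if p.role == EFFECTOR]
    expected = 2 if host.architecture == INDEPENDENT else 1
    if len(effectors) != expected:
        fail(f"{host.architecture} host must have {expected} effector(s)")
    if host.architecture == SHARED and effectors[0].network != SHARED:
        fail("shared host effector must belong to both networks")
    seen_pairs = set()
    for edge in host.edges:
        if edge.source not in by_id or edge.target not in by_id:
            fail(f"edge {edge.source}->{edge.target} references a missing protein")
        if not -1.0 <= edge.coefficient <= 1.0:
            fail(f"coefficient {edge.coefficient} outside [-1, 1]")
        if not edge_allowed(by_id[edge.source], by_id[edge.target], cross_network=True):
            fail(f"edge {edge.source}->{edge.target} is forbidden")
        if (edge.source, edge.target) in seen_pairs:
            fail(f"duplicate edge {edge.source}->{edge.target}")
        seen_pairs.add((edge.source, edge.target))
    return host
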