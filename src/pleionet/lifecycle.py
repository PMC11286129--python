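"""One host's life: equilibrium, development, infection, fitness.

A life is 5 equilibrium steps (no input, all active fractions starting at
0.5) followed by 150 life steps.  For 50 of those steps the host receives a
periodic developmental signal ``sin(x/2) + 0.5`` with ``x`` on a 50-point
grid from 0 to 8*pi; the signal acts as an external node with a fixed +1
upregulatory link to the developmental detector.  Infection attaches the
parasite's links from a random step inside the scenario's infection window:

=================  ==================  ==============  ================
signal order       development window  synchronous     asynchronous
=================  ==================  ==============  ================
development-first  steps 0-49          steps 0-49      steps 50-99
development-last   steps 100-149       steps 100-149   steps 0-49
=================  ==================  ==============  ================

Fitness combines three costs, ``W = exp(-(Imm.Eff.Area + Par.Area +
Dev.Cost))``: the immune effector's mean activity over the whole life, the
parasite's mean abundance from infection to the end of life, and a
developmental-tracking cost ``(1 - corr(signal, output)) + mean|signal -
output|`` over the developmental window.  Parasite fitness is Par.Area.

Two equivalent integrators are provided: :func:`simulate_life`, a readable
per-edge reference for one host, and :func:`simulate_population`, a
vectorized engine that runs a whole population in padded dense arrays and is
used by the evolutionary loop.  The test-suite holds them to each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import model_core as mc
from .config import (
    ASYNCHRONOUS,
    DEVELOPMENT_FIRST,
    DEVELOPMENT_LAST,
    HALF_AMPLITUDE,
    HALF_ANGLE,
    SIGNAL_ORDERS,
    SIGNAL_VARIANTS,
    SYNCHRONIES,
    SYNCHRONOUS,
    SimulationConfig,
)


# ---------------------------------------------------------------------------
# developmental signal
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def developmental_signal_series(
    variant: str = HALF_ANGLE, window: int = 50
) -> np.ndarray:
    """The 50 developmental signal values on the grid x in [0, 8*pi]."""
    if variant not in SIGNAL_VARIANTS:
        raise ValueError(f"unknown signal variant {variant!r}")
    x = np.linspace(0.0, 8.0 * np.pi, window)
    if variant == HALF_ANGLE:
        series = np.sin(x / 2.0) + 0.5
    else:  # HALF_AMPLITUDE
        series = np.sin(x) / 2.0 + 0.5
    series.setflags(write=False)
    return series


def developmental_signal(
    step_index: int, variant: str = HALF_ANGLE, window: int = 50
) -> float:
    """Signal value at one developmental step (0-based, range checked)."""
    if not 0 <= step_index < window:
        raise IndexError(f"developmental step {step_index} outside 0..{window - 1}")
    return float(developmental_signal_series(variant, window)[step_index])


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignallingSchedule:
    """Timing of the developmental window and the infection window."""

    synchrony: str = SYNCHRONOUS
    order: str = DEVELOPMENT_FIRST
    life_steps: int = 150
    development_window: int = 50

    def __post_init__(self) -> None:
        if self.synchrony not in SYNCHRONIES:
            raise ValueError(f"unknown synchrony {self.synchrony!r}")
        if self.order not in SIGNAL_ORDERS:
            raise ValueError(f"unknown signal order {self.order!r}")
        if self.life_steps < 2 * self.development_window:
            raise ValueError("life too short for development + infection windows")

    @property
    def development_start(self) -> int:
        if self.order == DEVELOPMENT_FIRST:
            return 0
        return self.life_steps - self.development_window

    def development_steps(self) -> range:
        start = self.development_start
        return range(start, start + self.development_window)

    def infection_window(self) -> tuple[int, int]:
        """Inclusive (first, last) life step at which infection may start."""
        w = self.development_window
        if self.synchrony == SYNCHRONOUS:
            start = self.development_start
            return (start, start + w - 1)
        if self.order == DEVELOPMENT_FIRST:
            # the window immediately after development
            return (w, 2 * w - 1)
        # development-last: the first half of the signal-free period
        return (0, w - 1)

    def draw_infection_step(self, rng: np.random.Generator) -> int:
        first, last = self.infection_window()
        return int(rng.integers(first, last + 1))

    def midpoint_infection_step(self) -> int:
        """Fixed mid-window infection step, used by robustness probes."""
        first, last = self.infection_window()
        return first + (last - first + 1) // 2

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "SignallingSchedule":
        return cls(
            synchrony=config.synchrony,
            order=config.signal_order,
            life_steps=config.life_steps,
            development_window=config.development_window,
        )


# ---------------------------------------------------------------------------
# attaching parasites
# ---------------------------------------------------------------------------

def attach_parasite(
    host: mc.Host,
    parasite: mc.Parasite,
    *,
    effector_coefficient: float = -1.0,
) -> mc.ParasiteLinks:
    """Resolve a parasite's links on a concrete host.

    The target is the immune signalling protein at ``target_index`` modulo the
    number of immune signalling proteins (sorted by id); the host's immune (or
    shared) effector gains a -1 downregulatory link onto the parasite.
    """
    signalling = host.signalling(mc.IMMUNE)
    if not signalling:
        raise ValueError("host immune network has no signalling protein to target")
    target = signalling[parasite.target_index % len(signalling)]
    return mc.ParasiteLinks(
        detector_id=host.detector(mc.IMMUNE).id,
        effector_id=host.immune_effector.id,
        target_id=target.id,
        target_coefficient=parasite.target_coefficient,
        self_coefficient=parasite.self_coefficient,
        detector_coefficient=parasite.detector_coefficient,
        effector_coefficient=effector_coefficient,
    )


def non_disrupting_links(
    host: mc.Host,
    *,
    self_coefficient: float = 0.8,
    detector_coefficient: float = 1.0,
    effector_coefficient: float = -1.0,
) -> mc.ParasiteLinks:
    """Links of a parasite that cannot interfere with host signalling."""
    return mc.ParasiteLinks(
        detector_id=host.detector(mc.IMMUNE).id,
        effector_id=host.immune_effector.id,
        target_id=None,
        target_coefficient=0.0,
        self_coefficient=self_coefficient,
        detector_coefficient=detector_coefficient,
        effector_coefficient=effector_coefficient,
    )


# ---------------------------------------------------------------------------
# reference (single-host) life simulation
# ---------------------------------------------------------------------------

def equilibrate(
    host: mc.Host,
    resource_limit: float,
    *,
    steps: int = 5,
    use_coef: float = mc.DEFAULT_USE_COEF,
    initial_active: float = 0.5,
) -> mc.NetworkState:
    """Free-run the network from uniform activation, no input, no parasite."""
    state = mc.NetworkState.uniform(host, initial_active)
    for _ in range(steps):
        state = mc.step(state, host, resource_limit=resource_limit, use_coef=use_coef)
    return state


@dataclass
class LifeRecord:
    """Trajectories and timing of one simulated host life.

    ``active`` holds one post-step value per timestep for each protein over
    the full time axis (equilibrium + life); ``parasite_series`` is aligned to
    the same axis and zero before the infection step (``None`` when
    uninfected).  ``infection_step`` is a life-step index.
    """

    host: mc.Host
    active: dict[int, np.ndarray]
    parasite_series: np.ndarray | None
    infection_step: int | None
    signal: np.ndarray
    development_start: int
    equilibrium_steps: int
    life_steps: int

    def life_series(self, pid: int) -> np.ndarray:
        return self.active[pid][self.equilibrium_steps:]

    def dev_output(self) -> np.ndarray:
        """Developmental effector output over the developmental window."""
        eff = self.host.developmental_effector.id
        start = self.development_start
        return self.life_series(eff)[start:start + len(self.signal)]


def simulate_life(
    host: mc.Host,
    parasite: mc.Parasite | None = None,
    *,
    schedule: SignallingSchedule,
    resource_limit: float,
    rng: np.random.Generator | None = None,
    infection_step: int | None = None,
    parasite_links: mc.ParasiteLinks | None = None,
    use_coef: float = mc.DEFAULT_USE_COEF,
    equilibrium_steps: int = 5,
    initial_active: float = 0.5,
    inoculum: float = 0.5,
    signal_variant: str = HALF_ANGLE,
) -> LifeRecord:
    """Run equilibrium plus one full life and record every trajectory.

    The parasite may be given as a genotype (links resolved via
    :func:`attach_parasite`) or as pre-resolved ``parasite_links`` (as the
    robustness probe does).  The infection step is drawn from the schedule's
    window unless passed explicitly; the parasite enters with abundance
    ``inoculum`` at that step, before the step's deltas are computed.
    """
    if parasite is not None and parasite_links is None:
        parasite_links = attach_parasite(host, parasite)
    infected = parasite_links is not None
    if infected and infection_step is None:
        if rng is None:
            raise ValueError("need an rng (or explicit infection_step) to infect")
        infection_step = schedule.draw_infection_step(rng)

    total = equilibrium_steps + schedule.life_steps
    signal = developmental_signal_series(signal_variant, schedule.development_window)
    series = {p.id: np.zeros(total) for p in host.proteins}
    par_series = np.zeros(total) if infected else None

    state = mc.NetworkState.uniform(host, initial_active)
    t_axis = 0
    for _ in range(equilibrium_steps):
        state = mc.step(state, host, resource_limit=resource_limit, use_coef=use_coef)
        for pid in series:
            series[pid][t_axis] = state.active[pid]
        t_axis += 1

    dev_start = schedule.development_start
    dev_detector = host.detector(mc.DEVELOPMENTAL).id
    for t in range(schedule.life_steps):
        links = None
        if infected and t >= infection_step:
            if t == infection_step:
                state.parasite = float(inoculum)
            links = parasite_links
        external = None
        if dev_start <= t < dev_start + schedule.development_window:
            external = {dev_detector: float(signal[t - dev_start])}
        state = mc.step(
            state,
            host,
            links,
            resource_limit=resource_limit,
            use_coef=use_coef,
            external_inputs=external,
        )
        for pid in series:
            series[pid][t_axis] = state.active[pid]
        if infected and t >= infection_step:
            par_series[t_axis] = state.parasite
        t_axis += 1

    return LifeRecord(
        host=host,
        active=series,
        parasite_series=par_series,
        infection_step=infection_step if infected else None,
        signal=np.asarray(signal),
        development_start=dev_start,
        equilibrium_steps=equilibrium_steps,
        life_steps=schedule.life_steps,
    )


# ---------------------------------------------------------------------------
# derived scalars
# ---------------------------------------------------------------------------

def immune_effector_area(record: LifeRecord) -> float:
    """Mean immune (or shared) effector activity over the life steps."""
    return float(record.life_series(record.host.immune_effector.id).mean())


def parasite_area(record: LifeRecord) -> float:
    """Mean parasite abundance from infection start to end of life; 0 if none."""
    if record.parasite_series is None:
        return 0.0
    start = record.equilibrium_steps + record.infection_step
    return float(record.parasite_series[start:].mean())


def developmental_cost(signal_series: np.ndarray, effector_series: np.ndarray) -> float:
    """``(1 - Pearson corr) + mean |signal - output|`` over the window.

    The correlation is defined as 0 when either series is constant: a flat
    output carries no signal-tracking information.
    """
    sig = np.asarray(signal_series, dtype=float)
    out = np.asarray(effector_series, dtype=float)
    if sig.shape != out.shape:
        raise ValueError("signal and effector series must have equal length")
    mean_abs = float(np.abs(sig - out).mean())
    s_sig = sig.std()
    s_out = out.std()
    if s_sig == 0.0 or s_out == 0.0:
        corr = 0.0
    else:
        corr = float(((sig - sig.mean()) * (out - out.mean())).mean() / (s_sig * s_out))
    return (1.0 - corr) + mean_abs


def record_developmental_cost(record: LifeRecord) -> float:
    return developmental_cost(record.signal, record.dev_output())


def host_fitness(record: LifeRecord) -> float:
    """``W = exp(-(Imm.Eff.Area + Par.Area + Dev.Cost))``; in (0, 1] for
    non-negative costs."""
    total = (
        immune_effector_area(record)
        + parasite_area(record)
        + record_developmental_cost(record)
    )
    return float(np.exp(-total))


def parasite_fitness(record: LifeRecord) -> float:
    """Parasite fitness is the infection-normalized parasite area."""
    if record.parasite_series is None:
        raise ValueError("parasite fitness is undefined for an uninfected life")
    return parasite_area(record)


# ---------------------------------------------------------------------------
# vectorized population engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _DenseHost:
    """Cached dense form of a host: W[target, source], out-degrees, indices."""

    n: int
    W: np.ndarray
    outdeg: np.ndarray
    ids: tuple[int, ...]
    index: dict
    immune_effector: int
    developmental_effector: int
    developmental_detector: int


@lru_cache(maxsize=32768)
def _dense(host: mc.Host) -> _DenseHost:
    ids = tuple(p.id for p in host.proteins)
    index = {pid: i for i, pid in enumerate(ids)}
    n = len(ids)
    W = np.zeros((n, n))
    outdeg = np.zeros(n)
    for e in host.edges:
        W[index[e.target], index[e.source]] = e.coefficient
        outdeg[index[e.source]] += 1
    W.setflags(write=False)
    outdeg.setflags(write=False)
    return _DenseHost(
        n=n,
        W=W,
        outdeg=outdeg,
        ids=ids,
        index=index,
        immune_effector=index[host.immune_effector.id],
        developmental_effector=index[host.developmental_effector.id],
        developmental_detector=index[host.detector(mc.DEVELOPMENTAL).id],
    )


@dataclass
class PopulationLifeResult:
    """Per-host outcome arrays for one generation's batch of lives."""

    immune_effector_area: np.ndarray
    parasite_area: np.ndarray
    developmental_cost: np.ndarray
    fitness: np.ndarray
    parasite_final: np.ndarray
    immune_effector_series: np.ndarray | None = None
    developmental_effector_series: np.ndarray | None = None
    parasite_series: np.ndarray | None = None


def simulate_population(
    hosts: list[mc.Host],
    parasite_links: list[mc.ParasiteLinks | None],
    infection_steps: np.ndarray,
    *,
    schedule: SignallingSchedule,
    resource_limit: float,
    use_coef: float = mc.DEFAULT_USE_COEF,
    equilibrium_steps: int = 5,
    initial_active: float = 0.5,
    inoculum: float = 0.5,
    signal_variant: str = HALF_ANGLE,
    record_series: bool = False,
) -> PopulationLifeResult:
    """Simulate every host's life in one padded batch.

    ``infection_steps[h]`` is the life step at which host ``h`` is infected,
    or -1 for uninfected hosts.  Semantics are identical to running
    :func:`simulate_life` per host with the same infection step; the batch
    merely pads all hosts to a common size and keeps the parasite in the last
    slot of each padded state vector.
    """
    n_hosts = len(hosts)
    if len(parasite_links) != n_hosts:
        raise ValueError("one links entry (possibly None) required per host")
    infection_steps = np.asarray(infection_steps, dtype=int)
    dense = [_dense(h) for h in hosts]
    m = max(d.n for d in dense) + 1  # one extra slot for the parasite
    par = m - 1

    W = np.zeros((n_hosts, m, m))
    exists = np.zeros((n_hosts, m))
    outdeg = np.zeros((n_hosts, m))
    use_extra = np.zeros((n_hosts, m))  # outgoing links that exist only while infected
    dev_det = np.zeros((n_hosts, m))
    imm_eff_idx = np.zeros(n_hosts, dtype=int)
    dev_eff_idx = np.zeros(n_hosts, dtype=int)
    infected = np.zeros(n_hosts, dtype=bool)

    for h, d in enumerate(dense):
        W[h, : d.n, : d.n] = d.W
        exists[h, : d.n] = 1.0
        outdeg[h, : d.n] = d.outdeg
        dev_det[h, d.developmental_detector] = 1.0
        imm_eff_idx[h] = d.immune_effector
        dev_eff_idx[h] = d.developmental_effector
        links = parasite_links[h]
        if links is not None:
            infected[h] = True
            det = d.index[links.detector_id]
            eff = d.index[links.effector_id]
            W[h, det, par] = links.detector_coefficient
            if links.target_id is not None:
                W[h, d.index[links.target_id], par] = links.target_coefficient
            W[h, par, par] = links.self_coefficient
            W[h, par, eff] = links.effector_coefficient
            use_extra[h, eff] += 1.0
            use_extra[h, par] = links.out_degree

    if np.any(infected & (infection_steps < 0)):
        raise ValueError("infected host without an infection step")

    k_pos = np.maximum(W, 0.0)
    i_neg = np.maximum(-W, 0.0)
    signal = developmental_signal_series(signal_variant, schedule.development_window)
    dev_start = schedule.development_start
    dev_end = dev_start + schedule.development_window
    life = schedule.life_steps
    rows = np.arange(n_hosts)

    imm_series = np.zeros((n_hosts, life))
    dev_series = np.zeros((n_hosts, life))
    par_series = np.zeros((n_hosts, life))

    p = exists * float(initial_active)

    def advance(p, par_active, sig):
        up = np.matmul(k_pos, p[:, :, None])[:, :, 0]
        if sig is not None:
            up = up + sig * dev_det
        down = np.matmul(i_neg, p[:, :, None])[:, :, 0]
        use = use_coef * (outdeg + par_active[:, None] * use_extra)
        raw = (1.0 - p) * up - p * down - use
        delta = raw * exists
        delta[:, par] = raw[:, par] * par_active
        positive = np.maximum(delta, 0.0)
        total = positive.sum(axis=1)
        scale = np.where(
            total > resource_limit, resource_limit / np.where(total > 0, total, 1.0), 1.0
        )
        delta = np.where(delta > 0, delta * scale[:, None], delta)
        return np.clip(p + delta, 0.0, 1.0)

    inactive = np.zeros(n_hosts)
    for _ in range(equilibrium_steps):
        p = advance(p, inactive, None)

    for t in range(life):
        newly = infected & (infection_steps == t)
        if np.any(newly):
            p[newly, par] = float(inoculum)
        par_active = (infected & (infection_steps <= t)).astype(float)
        sig = float(signal[t - dev_start]) if dev_start <= t < dev_end else None
        p = advance(p, par_active, sig)
        imm_series[:, t] = p[rows, imm_eff_idx]
        dev_series[:, t] = p[rows, dev_eff_idx]
        par_series[:, t] = p[:, par]

    imm_area = imm_series.mean(axis=1)

    # mean parasite abundance from each host's infection step to end of life
    tail_means = np.cumsum(par_series[:, ::-1], axis=1)[:, ::-1]
    start = np.where(infected, np.maximum(infection_steps, 0), 0)
    par_area = np.where(
        infected, tail_means[rows, start] / (life - start), 0.0
    )

    out = dev_series[:, dev_start:dev_end]
    diff = np.abs(out - signal[None, :]).mean(axis=1)
    s_out = out.std(axis=1)
    s_sig = signal.std()
    cov = ((out - out.mean(axis=1, keepdims=True)) * (signal - signal.mean())).mean(axis=1)
    denom = np.where(s_out > 0, s_out, 1.0) * (s_sig if s_sig > 0 else 1.0)
    corr = np.where((s_out > 0) & (s_sig > 0), cov / denom, 0.0)
    dev_cost = (1.0 - corr) + diff

    fitness = np.exp(-(imm_area + par_area + dev_cost))
    result = PopulationLifeResult(
        immune_effector_area=imm_area,
        parasite_area=par_area,
        developmental_cost=dev_cost,
        fitness=fitness,
        parasite_final=par_series[:, -1].copy(),
    )
    if record_series:
        result.immune_effector_series = imm_series
        result.developmental_effector_series = dev_series
        result.parasite_series = par_series
    return result
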