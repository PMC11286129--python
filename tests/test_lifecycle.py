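"""Life simulation: signal, windows, infection, areas, costs, fitness."""

import math

import numpy as np
import pytest

from conftest import oracle_step
from pleionet import lifecycle as lc
from pleionet import model_core as mc


class TestDevelopmentalSignal:
    def test_endpoints_of_the_grid(self):
        # sin(0) = 0 at the first grid point, sin(4*pi) = 0 at the last
        assert lc.developmental_signal(0) == pytest.approx(0.5, abs=1e-15)
        assert lc.developmental_signal(49) == pytest.approx(0.5, abs=1e-12)

    def test_interior_point_against_direct_evaluation(self):
        # x_12 = 12 * 8*pi / 49 on the 50-point inclusive grid
        expected = math.sin((12 * 8 * math.pi / 49) / 2.0) + 0.5
        assert lc.developmental_signal(12) == pytest.approx(expected, abs=1e-14)

    def test_half_amplitude_variant(self):
        expected = math.sin(12 * 8 * math.pi / 49) / 2.0 + 0.5
        assert lc.developmental_signal(12, variant="half-amplitude") == pytest.approx(
            expected, abs=1e-14
        )

    def test_out_of_range_index_rejected(self):
        with pytest.raises(IndexError):
            lc.developmental_signal(50)

    def test_signal_may_leave_unit_interval(self):
        series = lc.developmental_signal_series()
        assert series.min() < 0 or series.max() > 1  # range of sin(x/2)+0.5


class TestSchedule:
    @pytest.mark.parametrize(
        "synchrony,order,window",
        [
            ("synchronous", "development-first", (0, 49)),
            ("asynchronous", "development-first", (50, 99)),
            ("synchronous", "development-last", (100, 149)),
            ("asynchronous", "development-last", (0, 49)),
        ],
    )
    def test_infection_windows(self, synchrony, order, window):
        schedule = lc.SignallingSchedule(synchrony=synchrony, order=order)
        assert schedule.infection_window() == window

    def test_development_last_windows_partition_the_life(self):
        schedule = lc.SignallingSchedule(order="development-last")
        dev = set(schedule.development_steps())
        assert dev == set(range(100, 150))
        assert dev | set(range(100)) == set(range(150))

    def test_synchronous_draws_inside_development_window(self, rng):
        schedule = lc.SignallingSchedule(synchrony="synchronous")
        dev = set(schedule.development_steps())
        draws = {schedule.draw_infection_step(rng) for _ in range(10_000)}
        assert draws <= dev
        assert len(draws) == 50  # every step of the window is reachable

    def test_asynchronous_draws_outside_development_window(self, rng):
        for order in ("development-first", "development-last"):
            schedule = lc.SignallingSchedule(synchrony="asynchronous", order=order)
            dev = set(schedule.development_steps())
            draws = {schedule.draw_infection_step(rng) for _ in range(10_000)}
            assert draws.isdisjoint(dev)


class TestAttachParasite:
    def test_effector_link_is_minus_one(self, rng):
        host = mc.init_host(mc.SHARED, rng)
        links = lc.attach_parasite(host, mc.init_parasite(rng))
        assert links.effector_coefficient == -1.0
        assert links.effector_id == host.immune_effector.id

    def test_target_resolved_modulo_immune_signalling(self, rng):
        host = mc.init_host(mc.INDEPENDENT, rng)  # immune signalling ids 1, 2, 3
        low = lc.attach_parasite(host, mc.Parasite(0, 0.5))
        wrapped = lc.attach_parasite(host, mc.Parasite(5, 0.5))
        assert low.target_id == 1  # lowest-id immune signalling protein
        assert wrapped.target_id == 3  # 5 mod 3 == 2 -> third of (1, 2, 3)

    def test_non_disrupting_parasite_has_no_target(self, rng):
        host = mc.init_host(mc.SHARED, rng)
        links = lc.non_disrupting_links(host)
        assert links.target_id is None
        assert links.out_degree == 2


class TestEquilibrate:
    def test_edgeless_host_stays_at_half(self):
        host = mc.Host(
            mc.INDEPENDENT,
            tuple(mc.Protein(i, mc.SIGNAL, mc.IMMUNE) for i in range(4)),
            (),
        )
        state = lc.equilibrate(host, 0.1)
        assert all(v == 0.5 for v in state.active.values())

    def test_state_stays_in_unit_box(self, rng):
        for _ in range(10):
            host = mc.init_host(mc.INDEPENDENT, rng)
            state = lc.equilibrate(host, 0.1)
            assert all(0 <= v <= 1 for v in state.active.values())

    def test_self_loop_matches_hand_iteration(self):
        host = mc.Host(
            mc.INDEPENDENT,
            (mc.Protein(0, mc.SIGNAL, mc.IMMUNE),),
            (mc.RegulatoryEdge(0, 0, 1.0),),
        )
        state = lc.equilibrate(host, 0.1)
        active = {0: 0.5}
        for _ in range(5):
            active = oracle_step([0], active, [(0, 0, 1.0)], 0.01, 0.1)
        assert state.active[0] == pytest.approx(active[0], abs=1e-12)


def _record_from_series(host, effector_values, dev_values, signal, par=None, t0=None):
    """Assemble a LifeRecord with prescribed life trajectories."""
    eq = 5
    active = {p.id: np.zeros(eq + 150) for p in host.proteins}
    active[host.immune_effector.id][eq:] = effector_values
    active[host.developmental_effector.id][eq:] = dev_values
    par_series = None
    if par is not None:
        par_series = np.zeros(eq + 150)
        par_series[eq + t0:] = par
    return lc.LifeRecord(
        host=host,
        active=active,
        parasite_series=par_series,
        infection_step=t0,
        signal=signal,
        development_start=0,
        equilibrium_steps=eq,
        life_steps=150,
    )


@pytest.fixture
def independent_host(rng):
    return mc.init_host(mc.INDEPENDENT, rng)


class TestAreasAndFitness:
    def test_immune_effector_area_of_constant(self, independent_host):
        sig = lc.developmental_signal_series()
        rec = _record_from_series(independent_host, 0.5, 0.0, sig)
        assert lc.immune_effector_area(rec) == pytest.approx(0.5)

    def test_immune_effector_area_half_on(self, independent_host):
        sig = lc.developmental_signal_series()
        values = np.zeros(150)
        values[:75] = 1.0
        rec = _record_from_series(independent_host, values, 0.0, sig)
        assert lc.immune_effector_area(rec) == pytest.approx(0.5)

    def test_parasite_area_zero_when_uninfected(self, independent_host):
        rec = _record_from_series(
            independent_host, 0.0, 0.0, lc.developmental_signal_series()
        )
        assert lc.parasite_area(rec) == 0.0
        with pytest.raises(ValueError):
            lc.parasite_fitness(rec)

    @pytest.mark.parametrize("t0", [10, 120])
    def test_parasite_area_normalized_to_infection_window(self, independent_host, t0):
        """Constant abundance gives the same area whatever the window length."""
        sig = lc.developmental_signal_series()
        rec = _record_from_series(independent_host, 0.0, 0.0, sig, par=0.5, t0=t0)
        assert lc.parasite_area(rec) == pytest.approx(0.5)
        assert lc.parasite_fitness(rec) == pytest.approx(0.5)

    def test_fitness_of_costless_life_is_one(self, independent_host):
        sig = lc.developmental_signal_series()
        dev = np.zeros(150)
        dev[:50] = sig  # perfect tracking: corr 1, zero difference
        rec = _record_from_series(independent_host, 0.0, dev, sig)
        assert lc.record_developmental_cost(rec) == pytest.approx(0.0, abs=1e-12)
        assert lc.host_fitness(rec) == pytest.approx(1.0)

    def test_fitness_decreases_in_each_component(self, independent_host):
        sig = lc.developmental_signal_series()
        dev = np.zeros(150)
        dev[:50] = sig
        baseline = lc.host_fitness(_record_from_series(independent_host, 0.0, dev, sig))
        worse_immune = lc.host_fitness(
            _record_from_series(independent_host, 0.2, dev, sig)
        )
        worse_parasite = lc.host_fitness(
            _record_from_series(independent_host, 0.0, dev, sig, par=0.4, t0=50)
        )
        worse_dev = lc.host_fitness(
            _record_from_series(independent_host, 0.0, np.zeros(150), sig)
        )
        assert worse_immune < baseline
        assert worse_parasite < baseline
        assert worse_dev < baseline

    def test_fitness_equals_exponential_of_summed_costs(self, independent_host):
        sig = lc.developmental_signal_series()
        rec = _record_from_series(
            independent_host, 0.5, 0.25, sig, par=0.2, t0=60
        )
        total = (
            lc.immune_effector_area(rec)
            + lc.parasite_area(rec)
            + lc.record_developmental_cost(rec)
        )
        assert lc.host_fitness(rec) == pytest.approx(np.exp(-total))


class TestDevelopmentalCost:
    def test_perfect_tracking_costs_nothing(self):
        sig = lc.developmental_signal_series()
        assert lc.developmental_cost(sig, sig.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_flat_output_gets_zero_correlation(self):
        sig = lc.developmental_signal_series()
        flat = np.full_like(sig, 0.5)
        expected = 1.0 + np.abs(sig - 0.5).mean()
        assert lc.developmental_cost(sig, flat) == pytest.approx(expected)

    def test_anticorrelated_output_pays_two_in_the_correlation_term(self):
        sig = lc.developmental_signal_series()
        flipped = 1.5 - sig
        mean_abs = np.abs(sig - flipped).mean()
        assert lc.developmental_cost(sig, flipped) == pytest.approx(2.0 + mean_abs)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lc.developmental_cost(np.zeros(50), np.zeros(49))


class TestSimulateLife:
    def test_uninfected_record_has_no_parasite_series(self, independent_host, schedule):
        rec = lc.simulate_life(
            independent_host, schedule=schedule, resource_limit=0.1
        )
        assert rec.parasite_series is None
        assert rec.infection_step is None
        assert lc.parasite_area(rec) == 0.0

    def test_series_cover_equilibrium_plus_life(self, independent_host, schedule):
        rec = lc.simulate_life(independent_host, schedule=schedule, resource_limit=0.1)
        for series in rec.active.values():
            assert len(series) == 155
            assert np.all((series >= 0) & (series <= 1))

    def test_same_seed_gives_identical_record(self, independent_host, schedule):
        parasite = mc.init_parasite(np.random.default_rng(3))
        records = []
        for _ in range(2):
            rec = lc.simulate_life(
                independent_host,
                parasite,
                schedule=schedule,
                resource_limit=0.1,
                rng=np.random.default_rng(11),
            )
            records.append(rec)
        assert records[0].infection_step == records[1].infection_step
        for pid in records[0].active:
            assert np.array_equal(records[0].active[pid], records[1].active[pid])
        assert np.array_equal(
            records[0].parasite_series, records[1].parasite_series
        )


class TestBatchEngine:
    @staticmethod
    def _populate(rng, schedule):
        hosts, links, steps = [], [], []
        for i in range(10):
            architecture = mc.SHARED if i % 2 else mc.INDEPENDENT
            host = mc.init_host(architecture, rng)
            hosts.append(host)
            if i % 3 != 0:
                parasite = mc.init_parasite(rng)
                links.append(lc.attach_parasite(host, parasite))
                steps.append(schedule.draw_infection_step(rng))
            else:
                links.append(None)
                steps.append(-1)
        return hosts, links, steps

    def _compare(self, rng, schedule, tolerance):
        hosts, links, steps = self._populate(rng, schedule)
        batch = lc.simulate_population(
            hosts, links, np.array(steps), schedule=schedule, resource_limit=0.1
        )
        for i, host in enumerate(hosts):
            rec = lc.simulate_life(
                host,
                parasite_links=links[i],
                schedule=schedule,
                resource_limit=0.1,
                infection_step=steps[i] if steps[i] >= 0 else None,
            )
            assert batch.immune_effector_area[i] == pytest.approx(
                lc.immune_effector_area(rec), abs=tolerance
            )
            assert batch.parasite_area[i] == pytest.approx(
                lc.parasite_area(rec), abs=tolerance
            )
            assert batch.developmental_cost[i] == pytest.approx(
                lc.record_developmental_cost(rec), abs=10 * tolerance
            )
            assert batch.fitness[i] == pytest.approx(
                lc.host_fitness(rec), abs=10 * tolerance
            )

    def test_population_batch_matches_single_host_reference(self, rng):
        """Strict agreement over a horizon short enough that rounding cannot
        be amplified by the (chaotic) clamped dynamics."""
        schedule = lc.SignallingSchedule(
            synchrony="asynchronous", life_steps=30, development_window=10
        )
        self._compare(rng, schedule, 1e-10)

    def test_population_batch_tracks_reference_over_a_full_life(self, rng):
        """Over 150 steps the clamp/cap branch points amplify float rounding
        exponentially, so full-life agreement is held to a loose bound that
        still catches any semantic divergence."""
        self._compare(rng, lc.SignallingSchedule(synchrony="asynchronous"), 2e-3)

    def test_development_window_is_exactly_the_first_fifty_steps(self, rng):
        """With development-first scheduling the signal acts on steps 0-49 only."""
        host = mc.init_host(mc.INDEPENDENT, rng)
        schedule = lc.SignallingSchedule()
        rec = lc.simulate_life(host, schedule=schedule, resource_limit=0.1)
        assert rec.development_start == 0
        assert len(rec.signal) == 50
        assert len(rec.dev_output()) == 50
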