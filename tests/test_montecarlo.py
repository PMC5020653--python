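"""Metropolis engine: acceptance rule, bookkeeping, annealing, determinism."""

import numpy as np
import pytest

from memcurv import AnnealSchedule, EnergyParams, McState, anneal, total_energy
from memcurv._kernels import accept_trials, two_state_occupancy


class TestMetropolisRule:
    def test_downhill_always_accepted(self):
        assert accept_trials(-0.7, 1.0, 1000, 1) == 1000
        assert accept_trials(0.0, 1.0, 1000, 1) == 1000

    def test_acceptance_at_unit_barrier(self):
        """P(accept | dE = 1, T = 1) = 1/e within binomial 3 sigma."""
        n = 100_000
        p = np.exp(-1.0)
        acc = accept_trials(1.0, 1.0, n, 12345)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(acc - n * p) < 3 * sigma

    def test_two_state_boltzmann_occupancy(self):
        """Long-run occupancy ratio of a two-level system is exp(-dE/T)."""
        n = 200_000
        count = two_state_occupancy(1.0, 1.0, n, 99)
        p = np.exp(-1.0) / (1 + np.exp(-1.0))
        # correlated samples: generous 5x binomial band
        assert abs(count / n - p) < 5 * np.sqrt(p * (1 - p) / n)

    def test_temperature_dependence(self):
        n = 50_000
        a_cold = accept_trials(1.0, 0.25, n, 7) / n
        a_warm = accept_trials(1.0, 4.0, n, 7) / n
        assert a_cold == pytest.approx(np.exp(-4.0), abs=0.01)
        assert a_warm == pytest.approx(np.exp(-0.25), abs=0.01)


class TestBookkeeping:
    def test_running_totals_match_recompute(self, small_mc_state):
        st = small_mc_state
        st.run(30, 1.0)
        st.verify()  # raises CorruptedStateError on any mismatch

    def test_breakdown_equals_reference(self, small_mc_state):
        st = small_mc_state
        st.run(20, 0.5)
        got = st.energy_breakdown()
        ref = total_energy(st.to_mesh(), st.particles, st.params)
        assert got.bending == pytest.approx(ref.bending, abs=1e-6)
        assert got.area_constraint == pytest.approx(ref.area_constraint, abs=1e-6)
        assert got.volume_constraint == pytest.approx(ref.volume_constraint, abs=1e-6)

    def test_tether_bounds_after_run(self, small_mc_state):
        st = small_mc_state
        st.run(50, 1.0)
        el = np.linalg.norm(st.pos[st.edge_v[:, 1]] - st.pos[st.edge_v[:, 0]], axis=1)
        assert el.min() >= st.params.l * (1 - 1e-9)
        assert el.max() <= st.params.l_max * (1 + 1e-9)

    def test_counters_accumulate(self, small_mc_state):
        st = small_mc_state
        st.run(5, 1.0)
        assert st.counters[0, 0] > 0
        fr = st.acceptance_fractions()
        assert 0 < fr["vertex"] <= 1


class TestDeterminism:
    def test_same_seed_bit_identical_traces(self, sphere_642):
        m = sphere_642.measure()
        params = EnergyParams(kappa=21.0).with_targets(1.05 * m.total_area, m.enclosed_volume)
        tr = []
        for _ in range(2):
            st = McState.from_mesh(sphere_642, [], params, seed=42)
            tr.append(st.run(20, 1.0))
        assert np.array_equal(tr[0].to_numpy(), tr[1].to_numpy())

    def test_different_seeds_differ(self, sphere_642):
        m = sphere_642.measure()
        params = EnergyParams(kappa=21.0).with_targets(1.05 * m.total_area, m.enclosed_volume)
        a = McState.from_mesh(sphere_642, [], params, seed=1).run(5, 1.0)
        b = McState.from_mesh(sphere_642, [], params, seed=2).run(5, 1.0)
        assert not np.array_equal(a.to_numpy(), b.to_numpy())


class TestAnneal:
    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            AnnealSchedule(final_temperature=0.0)
        with pytest.raises(ValueError):
            AnnealSchedule(initial_temperature=0.1, final_temperature=0.5)
        with pytest.raises(ValueError):
            AnnealSchedule(sweeps_per_stage=0)

    def test_temperatures_geometric_and_decreasing(self):
        sched = AnnealSchedule(1.0, 0.01, 11, 5)
        temps = sched.temperatures()
        assert len(temps) == 11
        assert temps[0] == pytest.approx(1.0)
        assert temps[-1] == pytest.approx(0.01)
        ratios = temps[1:] / temps[:-1]
        assert np.allclose(ratios, ratios[0])
        assert np.all(np.diff(temps) < 0)

    def test_zero_stages_is_identity(self, small_mc_state):
        st = small_mc_state
        pos0 = st.pos.copy()
        stages = anneal(st, AnnealSchedule(1.0, 0.5, 0, 10))
        assert len(stages) == 0
        assert np.array_equal(st.pos, pos0)

    def test_cooling_lowers_energy_statistically(self, small_mc_state):
        st = small_mc_state
        st.run(300, 1.0)  # equilibrate warm
        stages = anneal(st, AnnealSchedule(1.0, 0.02, 12, 40))
        first = stages["mean_total"].iloc[:3].mean()
        last = stages["mean_total"].iloc[-3:].mean()
        assert last < first

    def test_floppy_vesicle_bending_bounded_below_by_sphere(self, small_mc_state):
        """Annealed quasi-spherical vesicle keeps E_bend >= 8 pi kappa."""
        st = small_mc_state
        anneal(st, AnnealSchedule(0.5, 0.01, 15, 40))
        assert st.energy_breakdown().bending >= 8 * np.pi * st.params.kappa
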