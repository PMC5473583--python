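"""Closed-loop engine: excitation solving, stepping, protocols."""

import numpy as np
import pytest

from mufatigue import (
    PoolParameters,
    Protocol,
    build_pool,
    run_protocol,
    solve_excitation,
    total_capacity,
)


def rested_state(pool):
    n = len(pool)
    return dict(
        PE=pool.P.copy(),
        CT=pool.CT_rested.copy(),
        t=0.0,
        TR=np.zeros(n),
        recruited=np.zeros(n, dtype=bool),
    )


class TestSolveExcitation:
    def test_initial_excitation_for_20pct_target(self, pool, params):
        """20% MVC needs 27.9% of maximal excitation from rest."""
        target = 0.20 * pool.rested_max_force()
        E, attained = solve_excitation(pool, target=target, params=params, **rested_state(pool))
        assert attained
        assert E / params.E_max * 100 == pytest.approx(27.9, abs=0.15)

    def test_zero_target_needs_no_excitation(self, pool, params):
        E, attained = solve_excitation(pool, target=0.0, params=params, **rested_state(pool))
        assert (E, attained) == (0.0, True)

    def test_full_mvc_requires_maximal_excitation(self, pool, params):
        target = pool.rested_max_force()
        E, attained = solve_excitation(
            pool, target=target * (1 - 1e-12), params=params, **rested_state(pool)
        )
        assert attained and E == pytest.approx(params.E_max)

    def test_bisection_matches_bottom_up_scan(self, pool, params):
        """Grid bisection returns the same smallest step a linear scan finds."""
        from mufatigue.model import _pool_force

        st = rested_state(pool)
        for frac in (0.05, 0.33, 0.61):
            target = frac * pool.rested_max_force()
            E, attained = solve_excitation(pool, target=target, params=params, **st)
            assert attained
            k = 0
            while True:
                Ek = 1.0 + k * params.dE
                if _pool_force(Ek, pool, st["PE"], st["CT"], st["t"], st["TR"],
                               st["recruited"], params) >= target:
                    break
                k += 1
            assert E == pytest.approx(Ek, abs=1e-9)

    def test_unattainable_flag_when_capacity_below_target(self, pool, params):
        st = rested_state(pool)
        st["PE"] = pool.P * 0.01  # nearly exhausted pool
        E, attained = solve_excitation(
            pool, target=0.5 * pool.rested_max_force(), params=params, **st
        )
        assert not attained and E == params.E_max


class TestTotalCapacity:
    def test_rested_capacity_is_mvc(self, pool, params):
        cap = total_capacity(pool, params=params, **rested_state(pool))
        assert cap == pytest.approx(pool.rested_max_force(), rel=1e-12)

    def test_exhausted_pool_has_zero_capacity(self, pool, params):
        st = rested_state(pool)
        st["PE"] = np.zeros(len(pool))
        assert total_capacity(pool, params=params, **st) == 0.0


class TestRunProtocol:
    def test_steady_state_without_fatigue_or_adaptation(self):
        """With fatigue negligible and adaptation off, a target is held
        indefinitely at constant excitation."""
        p = PoolParameters(FAT_first=1e-12, adaptation_enabled=False)
        trace = run_protocol(Protocol.sustained(40, max_duration=20.0), p, record_units=False)
        assert trace.endurance_time is None
        assert np.all(trace.excitation == trace.excitation[0])
        assert np.all(trace.total_force >= trace.target_force - 1e-9)

    def test_force_meets_target_until_endurance(self):
        trace = run_protocol(Protocol.sustained(60), record_units=False)
        before_end = trace.time < trace.endurance_time
        assert np.all(trace.total_force[before_end] >= trace.target_force[before_end] - 1e-9)

    def test_excitation_nondecreasing_for_constant_target(self):
        trace = run_protocol(Protocol.sustained(60), record_units=False)
        assert np.all(np.diff(trace.excitation) >= -1e-12)

    def test_per_unit_capacity_never_increases(self):
        trace = run_protocol(Protocol.sustained(70))
        assert np.all(np.diff(trace.PE, axis=0) <= 1e-12)

    def test_contraction_time_never_decreases_and_stays_bounded(self, pool, params):
        trace = run_protocol(Protocol.sustained(70))
        assert np.all(np.diff(trace.CT, axis=0) >= -1e-12)
        assert np.all(trace.CT >= pool.CT_rested - 1e-12)
        assert np.all(trace.CT <= pool.CT_rested * (1 + params.ct_slope) + 1e-12)

    def test_terminal_fatigue_peaks_in_upper_middle_units(self):
        """Relative capacity loss is worst between the pool extremes."""
        trace = run_protocol(Protocol.sustained(60))
        rel = trace.final_relative_capacity
        worst = int(np.argmin(rel)) + 1
        assert 40 < worst < 120
        assert rel[0] > rel[worst - 1]
        assert rel[-1] > rel[worst - 1]

    def test_maximal_protocol_pins_excitation(self, params):
        trace = run_protocol(Protocol.maximal(5.0), record_units=False)
        assert np.all(trace.excitation == params.E_max)
        assert trace.time[-1] == pytest.approx(5.0)
        # force equals capacity when drive is maximal
        np.testing.assert_allclose(trace.total_force, trace.capacity, rtol=1e-12)

    def test_capacity_floor_run_extends_past_endurance(self):
        trace = run_protocol(Protocol.to_capacity_floor(85, 60), record_units=False)
        assert trace.endurance_time is not None
        assert trace.time[-1] > trace.endurance_time
        assert trace.total_force[-1] < 0.60 * trace.mvc
        # after endurance the drive is pinned at maximum
        post = trace.time > trace.endurance_time
        assert np.all(trace.excitation[post] == trace.params.E_max)

    def test_staircase_target_time_course(self):
        proto = Protocol.staircase_task([20, 40, 60])
        assert proto.target_fraction(0.0) == pytest.approx(0.20)
        assert proto.target_fraction(31.9) == pytest.approx(0.20)
        assert proto.target_fraction(34.5) == pytest.approx(0.30)  # mid-ramp
        assert proto.target_fraction(37.0) == pytest.approx(0.40)
        assert proto.target_fraction(74.0) == pytest.approx(0.60)
        assert proto.target_fraction(1e4) == pytest.approx(0.60)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            Protocol.sustained(0.0)
        with pytest.raises(ValueError):
            Protocol.sustained(120.0)
        with pytest.raises(ValueError):
            Protocol.staircase_task([40, 20])
        with pytest.raises(ValueError):
            Protocol.to_capacity_floor(50, 0.0)
        with pytest.raises(ValueError):
            Protocol("nonsense")


def test_time_axis_is_uniform(params):
    trace = run_protocol(Protocol.sustained(80), record_units=False)
    np.testing.assert_allclose(np.diff(trace.time), params.dt, rtol=1e-9)


def test_small_pool_runs():
    """The engine is not tied to the default pool size."""
    p = PoolParameters(n=10)
    trace = run_protocol(Protocol.sustained(50, max_duration=600.0), p, record_units=False)
    assert trace.endurance_time is not None
    assert trace.mvc == pytest.approx(build_pool(p).rested_max_force())
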