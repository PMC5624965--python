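"""Impact-oscillator core: forcing evaluation, simulation, invariants."""

import math

import numpy as np
import pytest

from conftest import FROZEN_IMPULSIVE_IMPACTS, FROZEN_PERIODIC_IMPACTS

from woodknock import (
    ForcingSpec,
    ImpactEvent,
    InitialConditions,
    IntegrationError,
    OscillatorParams,
    SolverSettings,
    Trajectory,
    ValidationError,
    evaluate_forcing,
    extract_impact_train,
    preset_config,
    simulate,
)


class TestEvaluateForcing:
    @pytest.mark.parametrize(
        "spec, t, expected",
        [
            (ForcingSpec(variant="periodic"), math.pi, 0.0),  # before the window opens
            (ForcingSpec(variant="periodic"), 2.5 * math.pi, 1.0),  # sine max inside
            (ForcingSpec(variant="periodic"), 25 * math.pi, 0.0),  # after the window
            (ForcingSpec(variant="impulsive"), 20 * math.pi, 1.0),  # Gaussian peak
            (ForcingSpec(variant="impulsive"), 20 * math.pi + 1, math.exp(-1)),
            (ForcingSpec(variant="none"), 3.0, 0.0),
        ],
    )
    def test_values(self, spec, t, expected):
        assert evaluate_forcing(spec, t) == pytest.approx(expected, abs=1e-12)

    def test_window_is_open(self):
        spec = ForcingSpec(variant="periodic")
        assert evaluate_forcing(spec, 2 * math.pi) == 0.0
        assert evaluate_forcing(spec, 20 * math.pi) == 0.0

    def test_custom_callable(self):
        spec = ForcingSpec(variant="custom", custom=lambda t: 2 * t)
        assert evaluate_forcing(spec, 3.0) == 6.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"variant": "periodic", "t_on": 5.0, "t_off": 1.0},
            {"variant": "impulsive", "width_w": 0.0},
            {"variant": "custom"},
            {"variant": "banana"},
        ],
    )
    def test_malformed_spec_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ForcingSpec(**kwargs)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"restitution_alpha": 0.0},
            {"restitution_alpha": 1.2},
            {"wall_x0": -0.1},
            {"damping_p": -0.2},
            {"stiffness_q": 0.0},
        ],
    )
    def test_bad_oscillator_params(self, kwargs):
        with pytest.raises(ValidationError):
            OscillatorParams(**kwargs)

    def test_initial_displacement_beyond_wall(self):
        with pytest.raises(ValidationError):
            simulate(
                OscillatorParams(),
                ForcingSpec(variant="none"),
                InitialConditions(x0_init=0.5),
                SolverSettings(t_end=1.0),
            )


class TestSimulate:
    def test_unforced_rest_state_stays_at_rest(self):
        traj = simulate(
            OscillatorParams(),
            ForcingSpec(variant="none"),
            InitialConditions(),
            SolverSettings(t_end=20.0),
        )
        assert len(traj.impacts) == 0
        assert np.max(np.abs(traj.x)) < 1e-10

    def test_undamped_suborbital_matches_closed_form(self):
        # p = 0, start at x = 0.1 below the 0.2 wall: x(t) = 0.1 cos(sqrt(q) t)
        q = 0.3
        traj = simulate(
            OscillatorParams(damping_p=0.0, stiffness_q=q),
            ForcingSpec(variant="none"),
            InitialConditions(x0_init=0.1),
            SolverSettings(t_end=30.0),
        )
        assert len(traj.impacts) == 0
        expected = 0.1 * np.cos(np.sqrt(q) * traj.times)
        np.testing.assert_allclose(traj.x, expected, atol=1e-7)

    @pytest.mark.parametrize("preset", ["fig2-periodic", "fig2-impulsive"])
    def test_deterministic(self, preset):
        t1 = simulate(*preset_config(preset))
        t2 = simulate(*preset_config(preset))
        np.testing.assert_array_equal(t1.x, t2.x)
        assert [e.time for e in t1.impacts] == [e.time for e in t2.impacts]

    def test_periodic_regression_against_frozen_oracle(self, periodic_sim):
        _, train = periodic_sim
        frozen_t = np.array([t for t, _ in FROZEN_PERIODIC_IMPACTS])
        frozen_v = np.array([v for _, v in FROZEN_PERIODIC_IMPACTS])
        assert len(train) == len(FROZEN_PERIODIC_IMPACTS)
        np.testing.assert_allclose(train.times, frozen_t, atol=1e-5)
        np.testing.assert_allclose(train.speeds_in, frozen_v, atol=1e-5)

    def test_impulsive_regression_against_frozen_oracle(self, impulsive_sim):
        _, train = impulsive_sim
        frozen_t = np.array([t for t, _ in FROZEN_IMPULSIVE_IMPACTS])
        assert len(train) == len(FROZEN_IMPULSIVE_IMPACTS)
        np.testing.assert_allclose(train.times, frozen_t, atol=1e-5)
        # the whole train is a transient: strictly decreasing impact speeds,
        # starting only once the Gaussian thrust has built up
        assert np.all(np.diff(train.speeds_in) < 0)
        assert np.all(train.times > 20 * math.pi - 3)

    @pytest.mark.parametrize(
        "sim_fixture, oracle_fixture",
        [("periodic_sim", "periodic_oracle"), ("impulsive_sim", "impulsive_oracle")],
    )
    def test_adaptive_agrees_with_live_oracle(self, sim_fixture, oracle_fixture, request):
        """Adaptive event-driven solver vs independent fixed-step RK4+bisection."""
        _, train = request.getfixturevalue(sim_fixture)
        oracle = request.getfixturevalue(oracle_fixture)
        assert len(train) == len(oracle)
        for (t_o, v_o), t_a, v_a in zip(oracle, train.times, train.speeds_in):
            assert abs(t_a - t_o) < 1e-5
            assert abs(v_a - v_o) < 1e-5

    def test_integration_failure_reports_time(self):
        bad = ForcingSpec(variant="custom", custom=lambda t: float("nan"))
        with pytest.raises(IntegrationError):
            simulate(
                OscillatorParams(),
                bad,
                InitialConditions(),
                SolverSettings(t_end=5.0),
            )

    def test_chatter_terminates(self, caplog):
        # A constant thrust whose equilibrium lies beyond the wall presses the
        # bill into the wood: restitution speeds decay geometrically and the
        # chatter guard must stop the cascade instead of looping forever.
        traj = simulate(
            OscillatorParams(restitution_alpha=0.5),
            ForcingSpec(variant="custom", custom=lambda t: 1.0),
            InitialConditions(),
            SolverSettings(t_end=60.0, max_chatter_impacts=50),
        )
        assert np.isfinite(traj.times[-1])
        assert len(traj.impacts) < 10_000


class TestInvariants:
    @pytest.mark.parametrize("sim_fixture", ["periodic_sim", "impulsive_sim"])
    def test_wall_constraint(self, sim_fixture, request):
        traj, _ = request.getfixturevalue(sim_fixture)
        settings = SolverSettings()
        assert np.max(traj.x) <= traj.params.wall_x0 + 10 * settings.abs_tol

    @pytest.mark.parametrize("sim_fixture", ["periodic_sim", "impulsive_sim"])
    def test_restitution_exact(self, sim_fixture, request):
        traj, _ = request.getfixturevalue(sim_fixture)
        alpha = traj.params.restitution_alpha
        for e in traj.impacts:
            assert e.speed_in >= 0
            assert abs(e.speed_out / e.speed_in - alpha) < 1e-12

    def test_energy_dissipates_without_forcing(self):
        # launch toward the wall; E = v^2/2 + q x^2/2 must never increase,
        # and the impact itself removes exactly the factor alpha^2 of KE
        params = OscillatorParams()
        traj = simulate(
            params,
            ForcingSpec(variant="none"),
            InitialConditions(x0_init=0.0, v0_init=1.0),
            SolverSettings(t_end=40.0),
        )
        assert len(traj.impacts) >= 2
        energy = 0.5 * traj.v**2 + 0.5 * params.stiffness_q * traj.x**2
        impact_times = np.array([e.time for e in traj.impacts])
        # compare consecutive samples that do not straddle an impact
        mid = 0.5 * (traj.times[1:] + traj.times[:-1])
        straddles = np.min(np.abs(mid[:, None] - impact_times[None, :]), axis=1) < 0.01
        smooth = ~straddles
        assert np.all(np.diff(energy)[smooth] <= 1e-10)
        for e in traj.impacts:
            ke_in = 0.5 * e.speed_in**2
            ke_out = 0.5 * e.speed_out**2
            assert ke_out / ke_in == pytest.approx(params.restitution_alpha**2, rel=1e-12)

    @pytest.mark.parametrize("preset", ["fig2-periodic", "fig2-impulsive"])
    def test_tolerance_halving_convergence(self, preset):
        params, forcing, ic, settings = preset_config(preset)
        coarse = simulate(params, forcing, ic, settings)
        tight = simulate(
            params,
            forcing,
            ic,
            SolverSettings(
                t_end=settings.t_end,
                rel_tol=settings.rel_tol / 2,
                abs_tol=settings.abs_tol / 2,
            ),
        )
        t_coarse = [e.time for e in coarse.impacts]
        t_tight = [e.time for e in tight.impacts]
        assert len(t_coarse) == len(t_tight)
        assert max(abs(a - b) for a, b in zip(t_coarse, t_tight)) < 1e-6

    def test_periodic_regime_structure(self, periodic_sim):
        """Drumming: no impacts before forcing onset, a steady run while the
        drive is on, and a short transient after it switches off."""
        _, train = periodic_sim
        t_on, t_off = 2 * math.pi, 20 * math.pi
        assert np.all(train.times > t_on)
        after = train.times[train.times > t_off]
        assert len(after) >= 1
        during = train.times[(train.times > t_on) & (train.times < t_off)]
        steady = np.diff(during[3:])  # skip the onset transient
        assert len(during[3:]) >= 5
        assert np.std(steady) / np.mean(steady) <= 0.1


class TestExtractImpactTrain:
    @staticmethod
    def _traj_with_impacts(times):
        events = tuple(ImpactEvent(time=t, speed_in=1.0, speed_out=0.8) for t in times)
        return Trajectory(
            times=np.array([0.0, 1e-9 + (times[-1] if times else 1.0)]),
            x=np.zeros(2),
            v=np.zeros(2),
            impacts=events,
            params=OscillatorParams(),
            forcing=ForcingSpec(variant="none"),
        )

    def test_empty(self):
        train = extract_impact_train(self._traj_with_impacts([]))
        assert len(train) == 0
        assert train.intervals.size == 0

    def test_intervals_arithmetic(self):
        train = extract_impact_train(self._traj_with_impacts([1.0, 3.0, 6.0]))
        np.testing.assert_array_equal(train.intervals, [2.0, 3.0])

    def test_matches_simulation(self, periodic_sim):
        traj, train = periodic_sim
        assert len(train) == len(traj.impacts)
        np.testing.assert_array_equal(train.times, [e.time for e in traj.impacts])
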