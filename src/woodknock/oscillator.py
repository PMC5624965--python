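"""Vibro-impact harmonic oscillator model of a drumming woodpecker.

A perched woodpecker anchors itself with feet and tail; tension through the
neck and body acts as a restoring force that accelerates the head and bill
toward the wood.  Between impacts the displacement x(t) of the bill obeys a
damped, forced harmonic oscillator

    x'' + p x' + q x = R(t),

where p is a damping rate, q sets the natural frequency and R(t) is the
forcing supplied by the bird's body.  When the bill reaches the wood surface
at x = x0 (moving toward it), it rebounds instantaneously with a coefficient
of restitution alpha:

    x' -> -alpha * x',   0 < alpha <= 1.

Drumming corresponds to a periodic R(t) (a sine burst); the double knock of
Campephilus woodpeckers is hypothesised to be the transient response to a
single impulsive thrust, modelled as a Gaussian pulse.  The system is a
hybrid continuous/discrete dynamical system: smooth ODE flow punctuated by
instantaneous velocity resets at impact events.

All quantities are dimensionless; the model illustrates the qualitative
regimes (sustained periodic impact trains versus short decaying transients)
rather than fitting physical bill/neck mechanics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

logger = logging.getLogger("woodknock")

__all__ = [
    "ValidationError",
    "IntegrationError",
    "OscillatorParams",
    "ForcingSpec",
    "InitialConditions",
    "SolverSettings",
    "ImpactEvent",
    "ImpactTrain",
    "Trajectory",
    "evaluate_forcing",
    "simulate",
    "extract_impact_train",
    "PRESETS",
    "preset_config",
]


class ValidationError(ValueError):
    """A parameter or input violates its documented invariant."""


class IntegrationError(RuntimeError):
    """The ODE integration failed or produced a non-finite state."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OscillatorParams:
    """Oscillator coefficients and the impact rule.

    Parameters
    ----------
    damping_p : float
        Damping coefficient (rate of energy loss), >= 0.
    stiffness_q : float
        Restoring-force coefficient; sqrt(q) is the undamped natural
        angular frequency.  Must be > 0.
    restitution_alpha : float
        Coefficient of restitution in (0, 1]: fraction of impact speed
        retained after the bill rebounds.
    wall_x0 : float
        Displacement of the wood surface, > 0.  Positive x points toward
        the wood.
    """

    damping_p: float = 0.2
    stiffness_q: float = 0.3
    restitution_alpha: float = 0.8
    wall_x0: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.restitution_alpha <= 1.0):
            raise ValidationError(
                f"restitution_alpha must be in (0, 1], got {self.restitution_alpha}"
            )
        if self.wall_x0 <= 0:
            raise ValidationError(f"wall_x0 must be > 0, got {self.wall_x0}")
        if self.damping_p < 0:
            raise ValidationError(f"damping_p must be >= 0, got {self.damping_p}")
        if self.stiffness_q <= 0:
            raise ValidationError(f"stiffness_q must be > 0, got {self.stiffness_q}")


@dataclass(frozen=True)
class ForcingSpec:
    """Forcing function R(t).

    Variants
    --------
    ``"periodic"``
        amplitude * sin(angular_frequency * t) on the open window
        (t_on, t_off), zero outside.  Defaults reproduce the sine burst
        sin(t) for 2*pi < t < 20*pi.
    ``"impulsive"``
        amplitude * exp(-((t - center_tc) / width_w)**2), a Gaussian pulse;
        defaults give exp(-(t - 20*pi)**2).
    ``"none"``
        identically zero (free damped oscillation).
    ``"custom"``
        an arbitrary callable t -> force.
    """

    variant: Literal["periodic", "impulsive", "none", "custom"] = "none"
    amplitude: float = 1.0
    angular_frequency: float = 1.0
    t_on: float = 2.0 * math.pi
    t_off: float = 20.0 * math.pi
    center_tc: float = 20.0 * math.pi
    width_w: float = 1.0
    custom: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("periodic", "impulsive", "none", "custom"):
            raise ValidationError(f"unknown forcing variant {self.variant!r}")
        if self.variant == "periodic" and not self.t_on < self.t_off:
            raise ValidationError(
                f"periodic forcing requires t_on < t_off, got ({self.t_on}, {self.t_off})"
            )
        if self.variant == "impulsive" and self.width_w <= 0:
            raise ValidationError(f"width_w must be > 0, got {self.width_w}")
        if self.variant == "custom" and not callable(self.custom):
            raise ValidationError("custom forcing requires a callable")

    def breakpoints(self) -> tuple[float, ...]:
        """Times at which R(t) switches or becomes non-negligible.

        The integrator splits its segments here so the adaptive solver can
        neither step across the discontinuous window edges of the periodic
        burst nor over a narrow Gaussian pulse while the state is at rest.
        """
        if self.variant == "periodic":
            return (self.t_on, self.t_off)
        if self.variant == "impulsive":
            return (self.center_tc - 6.0 * self.width_w, self.center_tc)
        return ()


@dataclass(frozen=True)
class InitialConditions:
    x0_init: float = 0.0
    v0_init: float = 0.0
    t_start: float = 0.0

    def validate_against(self, params: OscillatorParams) -> None:
        if self.x0_init > params.wall_x0:
            raise ValidationError(
                f"initial displacement {self.x0_init} exceeds wall at {params.wall_x0}"
            )


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for :func:`simulate`.

    ``event_tol`` bounds the time-localization error of an impact;
    ``chatter_speed_eps`` is the impact speed below which the bill is
    considered to have come to rest on the wood (Zeno-chatter cutoff).
    """

    t_end: float = 30.0 * math.pi
    rel_tol: float = 1e-9
    abs_tol: float = 1e-12
    max_step: float = 0.1
    event_tol: float = 1e-9
    chatter_speed_eps: float = 1e-6
    sample_dt: float = 0.01
    max_chatter_impacts: int = 100

    def __post_init__(self) -> None:
        for name in ("rel_tol", "abs_tol", "max_step", "event_tol", "sample_dt"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.chatter_speed_eps < 0:
            raise ValidationError("chatter_speed_eps must be >= 0")


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImpactEvent:
    """One bill-wood impact: time, approach speed and rebound speed."""

    time: float
    speed_in: float
    speed_out: float


@dataclass(frozen=True)
class ImpactTrain:
    """Ordered impact times with inter-impact intervals and speeds."""

    times: np.ndarray
    intervals: np.ndarray
    speeds_in: np.ndarray
    speeds_out: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Trajectory:
    """Dense solution of the impact oscillator.

    ``times`` is strictly increasing, ``x``/``v`` are displacement and
    velocity sampled on it, and ``impacts`` lists the impact events in
    chronological order.
    """

    times: np.ndarray
    x: np.ndarray
    v: np.ndarray
    impacts: tuple[ImpactEvent, ...]
    params: OscillatorParams
    forcing: ForcingSpec

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.x) == len(self.v)):
            raise ValidationError("times, x, v must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("trajectory times must be strictly increasing")


# ---------------------------------------------------------------------------
# Forcing evaluation
# ---------------------------------------------------------------------------

def evaluate_forcing(spec: ForcingSpec, t: float) -> float:
    """Evaluate the forcing R(t) at time ``t``.

    The periodic window is open at both endpoints: the sine burst is
    applied only for t_on < t < t_off, exactly as the switching condition
    is written.
    """
    if spec.variant == "periodic":
        if spec.t_on < t < spec.t_off:
            return spec.amplitude * math.sin(spec.angular_frequency * t)
        return 0.0
    if spec.variant == "impulsive":
        z = (t - spec.center_tc) / spec.width_w
        return spec.amplitude * math.exp(-z * z)
    if spec.variant == "none":
        return 0.0
    return float(spec.custom(t))  # type: ignore[misc]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(
    params: OscillatorParams,
    forcing: ForcingSpec,
    ic: InitialConditions = InitialConditions(),
    settings: SolverSettings = SolverSettings(),
) -> Trajectory:
    """Integrate the impact oscillator and return a dense :class:`Trajectory`.

    The ODE is integrated with an adaptive Runge-Kutta scheme between
    impacts; the impact surface x = x0 is an integration event (crossing
    with positive velocity, localized on the solver's dense output).  At
    each impact the displacement is kept continuous and the velocity is
    replaced by -alpha * v.  Impacts slower than ``chatter_speed_eps`` set
    the velocity to zero instead (the bill rests on the wood); more than
    ``max_chatter_impacts`` consecutive such micro-impacts terminate the
    run with a warning rather than chattering forever.

    Deterministic for fixed inputs.
    """
    ic.validate_against(params)
    if settings.t_end <= ic.t_start:
        raise ValidationError("t_end must exceed t_start")

    p, q, alpha, wall = (
        params.damping_p,
        params.stiffness_q,
        params.restitution_alpha,
        params.wall_x0,
    )

    def rhs(t: float, y: np.ndarray) -> list[float]:
        return [y[1], evaluate_forcing(forcing, t) - p * y[1] - q * y[0]]

    def hit_wall(t: float, y: np.ndarray) -> float:
        return y[0] - wall

    hit_wall.terminal = True  # type: ignore[attr-defined]
    hit_wall.direction = 1  # type: ignore[attr-defined]

    # Sample grid for the dense output, including both endpoints.
    n_samples = int(math.floor((settings.t_end - ic.t_start) / settings.sample_dt))
    grid = ic.t_start + settings.sample_dt * np.arange(n_samples + 1)
    if grid[-1] < settings.t_end - 1e-12:
        grid = np.append(grid, settings.t_end)

    breaks = sorted(
        b for b in forcing.breakpoints() if ic.t_start < b < settings.t_end
    ) + [settings.t_end]

    t = ic.t_start
    y = np.array([ic.x0_init, ic.v0_init], dtype=float)
    impacts: list[ImpactEvent] = []
    xs = np.empty_like(grid)
    vs = np.empty_like(grid)
    xs[0], vs[0] = y
    filled = 1  # grid[0] == t_start already stored
    chatter_run = 0

    while t < settings.t_end - 1e-12:
        t_stop = next(b for b in breaks if b > t + 1e-12)
        sol = solve_ivp(
            rhs,
            (t, t_stop),
            y,
            method="RK45",
            events=hit_wall,
            dense_output=True,
            rtol=settings.rel_tol,
            atol=settings.abs_tol,
            max_step=settings.max_step,
        )
        if not sol.success:
            raise IntegrationError(f"integration failed near t = {t:.6g}: {sol.message}")

        seg_end = sol.t[-1]
        hi = np.searchsorted(grid, seg_end, side="right")
        if hi > filled:
            seg = sol.sol(grid[filled:hi])
            xs[filled:hi], vs[filled:hi] = seg[0], seg[1]
            filled = hi

        if not np.all(np.isfinite(sol.y[:, -1])):
            raise IntegrationError(f"non-finite state at t = {seg_end:.6g}")

        if sol.t_events[0].size:
            te = float(sol.t_events[0][0])
            speed_in = float(sol.y_events[0][0][1])
            speed_in = max(speed_in, 0.0)
            speed_out = alpha * speed_in
            impacts.append(ImpactEvent(time=te, speed_in=speed_in, speed_out=speed_out))
            if speed_in < settings.chatter_speed_eps:
                chatter_run += 1
                y = np.array([wall, 0.0])
                if chatter_run > settings.max_chatter_impacts:
                    logger.warning(
                        "chatter termination: %d consecutive impacts below "
                        "speed %.1e at t = %.6g; bill treated as resting",
                        chatter_run,
                        settings.chatter_speed_eps,
                        te,
                    )
                    break
            else:
                chatter_run = 0
                y = np.array([wall, -speed_out])
            t = te
        else:
            t = seg_end
            y = sol.y[:, -1].copy()

    times = grid[:filled]
    traj = Trajectory(
        times=times,
        x=xs[:filled],
        v=vs[:filled],
        impacts=tuple(impacts),
        params=params,
        forcing=forcing,
    )
    logger.debug(
        "simulate: %s forcing, t in [%g, %g], %d impacts",
        forcing.variant,
        ic.t_start,
        settings.t_end,
        len(impacts),
    )
    return traj


def extract_impact_train(traj: Trajectory) -> ImpactTrain:
    """Reduce a trajectory to its impact train (times, intervals, speeds)."""
    times = np.array([e.time for e in traj.impacts])
    speeds_in = np.array([e.speed_in for e in traj.impacts])
    speeds_out = np.array([e.speed_out for e in traj.impacts])
    return ImpactTrain(
        times=times,
        intervals=np.diff(times),
        speeds_in=speeds_in,
        speeds_out=speeds_out,
    )


# ---------------------------------------------------------------------------
# Presets: the two illustrated forcing regimes
# ---------------------------------------------------------------------------

def _fig2_periodic() -> tuple[OscillatorParams, ForcingSpec, InitialConditions, SolverSettings]:
    return (
        OscillatorParams(),
        ForcingSpec(variant="periodic"),
        InitialConditions(),
        SolverSettings(),
    )


def _fig2_impulsive() -> tuple[OscillatorParams, ForcingSpec, InitialConditions, SolverSettings]:
    return (
        OscillatorParams(),
        ForcingSpec(variant="impulsive"),
        InitialConditions(),
        SolverSettings(),
    )


#: Named configurations: "fig2-periodic" is the drumming regime (sine burst on
#: 2*pi < t < 20*pi); "fig2-impulsive" is the double-knock regime (unit
#: Gaussian thrust centred at t = 20*pi).  Both start from rest at the
#: equilibrium point and integrate to t = 30*pi.
PRESETS: dict[str, Callable[[], tuple[OscillatorParams, ForcingSpec, InitialConditions, SolverSettings]]] = {
    "fig2-periodic": _fig2_periodic,
    "fig2-impulsive": _fig2_impulsive,
}


def preset_config(name: str) -> tuple[OscillatorParams, ForcingSpec, InitialConditions, SolverSettings]:
    """Return (params, forcing, initial conditions, solver settings) for a preset."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
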