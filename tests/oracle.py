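"""Independent fixed-step reference integrator for the impact oscillator.

Classic RK4 with a fixed step; an impact is located by bisecting the step
length until the crossing of the wall is bracketed to ``tol`` in time, then
the restitution rule is applied.  Deliberately shares no code with
woodknock.oscillator: plain-float arithmetic, no scipy, no events — it
exists solely to cross-check the adaptive event-driven solver.
"""

from __future__ import annotations

from typing import Callable


def rk4_impact_oracle(
    forcing: Callable[[float], float],
    t_end: float,
    p: float = 0.2,
    q: float = 0.3,
    alpha: float = 0.8,
    wall: float = 0.2,
    h: float = 1e-3,
    tol: float = 1e-10,
) -> list[tuple[float, float]]:
    """Return [(impact_time, impact_speed), ...] starting from rest at 0."""

    def deriv(t: float, x: float, v: float) -> tuple[float, float]:
        return v, forcing(t) - p * v - q * x

    def step(t: float, x: float, v: float, h: float) -> tuple[float, float]:
        k1x, k1v = deriv(t, x, v)
        k2x, k2v = deriv(t + h / 2, x + h / 2 * k1x, v + h / 2 * k1v)
        k3x, k3v = deriv(t + h / 2, x + h / 2 * k2x, v + h / 2 * k2v)
        k4x, k4v = deriv(t + h, x + h * k3x, v + h * k3v)
        return (
            x + h / 6 * (k1x + 2 * k2x + 2 * k3x + k4x),
            v + h / 6 * (k1v + 2 * k2v + 2 * k3v + k4v),
        )

    t, x, v = 0.0, 0.0, 0.0
    impacts: list[tuple[float, float]] = []
    while t < t_end:
        h_eff = min(h, t_end - t)
        xn, vn = step(t, x, v, h_eff)
        if xn >= wall and x < wall:
            lo, hi = 0.0, h_eff
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                xm, _ = step(t, x, v, mid)
                if xm >= wall:
                    hi = mid
                else:
                    lo = mid
            _, v_in = step(t, x, v, hi)
            t += hi
            impacts.append((t, v_in))
            x, v = wall, -alpha * v_in
        else:
            t, x, v = t + h_eff, xn, vn
    return impacts
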