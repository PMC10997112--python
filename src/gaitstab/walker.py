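"""Core walking-system dynamics.

The walker is a linearized single-link inverted pendulum: a point-mass CoM
on a rigid, massless leg pivoting about a ground contact point ``p``.  The
linearized equations of motion are

    dx/dt = v,    dv/dt = omega**2 * (x - p),

with eigenfrequency ``omega = sqrt(g / l)`` for leg length ``l``.  Between
steps the contact point is constant and the solution is the closed-form
hyperbolic flow implemented in :func:`propagate`; no numerical integration
is used anywhere in the library path.

Steps are instantaneous shifts of the contact point taken every ``t_step``
seconds.  The new placement is chosen by a proportional-derivative control
law driven by the CoM state relative to the contact point at *midstance*,
the temporal midpoint between two steps.  Two stepping patterns are
supported: *progressive* (anterior-posterior walking; constant placement
offset ``b_o`` each step) and *alternating* (medial-lateral sway; the
offset sign flips every step).

Time convention: ``t = 0`` is a midstance, steps occur at
``t = (n + 1/2) * t_step`` and midstances at ``t = n * t_step``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import GaitstabError

GRAVITY = 9.81  # m s^-2

Mode = Literal["progressive", "alternating"]

_MODES = ("progressive", "alternating")


def eigenfrequency_from_leg_length(leg_length: float) -> float:
    """Pendulum eigenfrequency ``omega = sqrt(g / l)`` in s^-1.

    Parameters
    ----------
    leg_length : float
        Effective leg length (vertical CoM-to-contact distance), m.  Must
        be positive.
    """
    if not leg_length > 0:
        raise ValueError(f"leg length must be positive, got {leg_length}")
    return math.sqrt(GRAVITY / leg_length)


def half_step_constants(omega: float, t_step: float) -> tuple[float, float]:
    """Hyperbolic half-step constants ``c = cosh(omega*t_step/2)``, ``s = sinh(...)``.

    These appear throughout the step-to-step analysis; they satisfy the
    identity ``c**2 - s**2 == 1`` to machine precision.
    """
    if not omega > 0:
        raise ValueError(f"omega must be positive, got {omega}")
    if not t_step > 0:
        raise ValueError(f"t_step must be positive, got {t_step}")
    a = 0.5 * omega * t_step
    return math.cosh(a), math.sinh(a)


@dataclass(frozen=True)
class WalkerParams:
    """Full parameterization of one walking system.

    Parameters
    ----------
    omega : float
        Pendulum eigenfrequency, s^-1 (authoritative even when constructed
        from a leg length).
    b_o : float
        Constant foot-placement offset, m.  Sets average step length
        (progressive) or width (alternating); has no effect on stability.
    b_p : float
        Proportional gain on the midstance relative CoM position
        (dimensionless).
    b_d : float
        Derivative gain on the midstance CoM velocity, s.
    t_step : float
        Step duration, s.
    mode : {"progressive", "alternating"}
        Stepping pattern; selects the sign behaviour of ``b_o``.
    leg_length : float, optional
        Leg length the eigenfrequency was derived from, m (bookkeeping
        only).
    """

    omega: float
    b_o: float
    b_p: float
    b_d: float
    t_step: float
    mode: Mode = "progressive"
    leg_length: float | None = None

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        if not self.t_step > 0:
            raise ValueError(f"t_step must be positive, got {self.t_step}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")

    @classmethod
    def from_leg_length(
        cls,
        leg_length: float,
        b_o: float,
        b_p: float,
        b_d: float,
        t_step: float,
        mode: Mode = "progressive",
    ) -> "WalkerParams":
        """Construct with ``omega = sqrt(g / leg_length)``."""
        return cls(
            omega=eigenfrequency_from_leg_length(leg_length),
            b_o=b_o,
            b_p=b_p,
            b_d=b_d,
            t_step=t_step,
            mode=mode,
            leg_length=leg_length,
        )

    def half_step_constants(self) -> tuple[float, float]:
        return half_step_constants(self.omega, self.t_step)

    def offset(self, n: int) -> float:
        """Placement offset applied at the step leaving midstance ``n``."""
        if self.mode == "alternating":
            return self.b_o if n % 2 == 0 else -self.b_o
        return self.b_o


@dataclass(frozen=True)
class PendulumState:
    """Continuous hybrid state: time, absolute CoM position/velocity, contact point, step index."""

    t: float
    x: float
    v: float
    p: float
    n: int = 0

    @property
    def q(self) -> float:
        """CoM position relative to the current contact point, m."""
        return self.x - self.p


@dataclass(frozen=True)
class MidstanceState:
    """Discrete state at midstance ``t = n * t_step``: relative position, velocity, step index."""

    q: float
    v: float
    n: int = 0


@dataclass(frozen=True)
class PerturbationEvent:
    """Instantaneous additive offset to the CoM state at a given time."""

    time: float
    dx: float = 0.0
    dv: float = 0.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"perturbation time must be >= 0, got {self.time}")
        if not (math.isfinite(self.dx) and math.isfinite(self.dv)):
            raise ValueError("perturbation offsets must be finite")


@dataclass
class Trajectory:
    """Sampled solution of a walking system.

    Attributes
    ----------
    t, x, v, p : ndarray
        Uniformly sampled time, CoM position, velocity and contact point.
        The contact point is piecewise constant; a sample exactly at a step
        event carries the post-step value.
    step_idx : ndarray of int
        Index of the step interval each sample belongs to.
    step_events : list of (time, old_p, new_p, step_index)
    midstances : list of MidstanceState
        The exact midstance states recorded during simulation (closed
        form, independent of the sampling grid).
    params : WalkerParams
    """

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    p: np.ndarray
    step_idx: np.ndarray
    step_events: list[tuple[float, float, float, int]]
    midstances: list[MidstanceState]
    params: WalkerParams

    @property
    def q(self) -> np.ndarray:
        return self.x - self.p

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a DataFrame with unit-suffixed columns."""
        return pd.DataFrame(
            {
                "t_s": self.t,
                "x_m": self.x,
                "v_mps": self.v,
                "p_m": self.p,
                "q_m": self.q,
                "step_idx": self.step_idx,
            }
        )


def _propagate_arrays(q0, v0, omega, dt):
    """Closed-form hyperbolic flow of the relative state over dt (vectorized)."""
    ch = np.cosh(omega * dt)
    sh = np.sinh(omega * dt)
    q = q0 * ch + (v0 / omega) * sh
    v = q0 * omega * sh + v0 * ch
    return q, v


def propagate(state: PendulumState, dt: float, omega: float) -> PendulumState:
    """Advance the pendulum state by ``dt`` with the contact point fixed.

    Uses the exact hyperbolic solution

        x(t+dt) = p + (x-p) cosh(w dt) + (v/w) sinh(w dt)
        v(t+dt) = (x-p) w sinh(w dt) + v cosh(w dt)

    The caller must ensure no step event lies inside the interval.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    q, v = _propagate_arrays(state.x - state.p, state.v, omega, dt)
    return replace(state, t=state.t + dt, x=state.p + q, v=v)


def foot_placement(params: WalkerParams, ms: MidstanceState, p_n: float) -> float:
    """New contact point chosen by the PD control law at midstance ``ms``.

    progressive:  p_{n+1} = p_n + b_o + b_p*q_n + b_d*v_n
    alternating:  p_{n+1} = p_n + (-1)**n * b_o + b_p*q_n + b_d*v_n
    """
    return p_n + params.offset(ms.n) + params.b_p * ms.q + params.b_d * ms.v


def midstance_map(params: WalkerParams, ms: MidstanceState) -> MidstanceState:
    """Exact affine step-to-step map from midstance ``n`` to midstance ``n+1``.

    Propagates half a step, applies the foot-placement law, re-expresses
    the position relative to the new contact point, and propagates the
    remaining half step.  The Jacobian of this map (constant, since the
    map is affine) is the step-to-step transition matrix.
    """
    c, s = params.half_step_constants()
    w = params.omega
    # half step to the step event
    q_mid = ms.q * c + ms.v * s / w
    v_mid = ms.q * w * s + ms.v * c
    # instantaneous contact-point shift
    dp = params.offset(ms.n) + params.b_p * ms.q + params.b_d * ms.v
    q_post = q_mid - dp
    # half step to the next midstance
    q_next = q_post * c + v_mid * s / w
    v_next = q_post * w * s + v_mid * c
    return MidstanceState(q=q_next, v=v_next, n=ms.n + 1)


def simulate(
    params: WalkerParams,
    init: PendulumState,
    n_steps: int,
    dt: float = 0.005,
    perturbations: Sequence[PerturbationEvent] = (),
) -> Trajectory:
    """Event-driven simulation of the hybrid walking system.

    Starting from ``init`` (which must be at ``t = 0``, a midstance), the
    state is advanced with the closed-form flow between events.  Events
    are, in time order: perturbations (instantaneous state offsets),
    midstance recordings at ``t = n*t_step`` (the controller's sensing
    instants), and step events at ``t = (n+1/2)*t_step``.  A perturbation
    scheduled exactly at a midstance or step event is applied *first*, so
    the controller senses the perturbed state.

    The trajectory is sampled on the uniform ``dt`` grid over
    ``[0, n_steps*t_step]``; the dynamics carry no discretization error,
    so the sampled states are exact regardless of ``dt``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if abs(init.t) > 1e-12:
        raise ValueError("initial state must be at t = 0 (a midstance)")

    T = params.t_step
    t_end = n_steps * T
    for ev in perturbations:
        if ev.time > t_end + 1e-12:
            raise ValueError(
                f"perturbation at t={ev.time} lies beyond the simulated horizon {t_end}"
            )

    # event queue: (time, priority, kind, payload); perturbations first on ties
    events: list[tuple[float, int, str, object]] = []
    for ev in perturbations:
        events.append((ev.time, 0, "perturb", ev))
    for k in range(n_steps + 1):
        events.append((k * T, 1, "midstance", k))
    for k in range(n_steps):
        events.append(((k + 0.5) * T, 2, "step", k))
    events.sort(key=lambda e: (e[0], e[1]))

    n_samples = int(round(t_end / dt)) + 1
    sample_t = dt * np.arange(n_samples)
    out_x = np.empty(n_samples)
    out_v = np.empty(n_samples)
    out_p = np.empty(n_samples)
    out_n = np.empty(n_samples, dtype=int)

    state = init
    step_events: list[tuple[float, float, float, int]] = []
    midstances: list[MidstanceState] = []
    last_sensed: MidstanceState | None = None
    i = 0  # next sample to emit

    def emit_until(t_limit: float, inclusive: bool) -> None:
        nonlocal i, state
        tol = 1e-9 * max(1.0, abs(t_limit))
        while i < n_samples and (
            sample_t[i] < t_limit - tol or (inclusive and sample_t[i] <= t_limit + tol)
        ):
            st = propagate(state, max(sample_t[i] - state.t, 0.0), params.omega)
            out_x[i], out_v[i], out_p[i], out_n[i] = st.x, st.v, st.p, st.n
            i += 1

    for t_ev, _prio, kind, payload in events:
        emit_until(t_ev, inclusive=False)
        state = propagate(state, max(t_ev - state.t, 0.0), params.omega)
        if kind == "perturb":
            ev = payload  # type: ignore[assignment]
            state = replace(state, x=state.x + ev.dx, v=state.v + ev.dv)
        elif kind == "midstance":
            last_sensed = MidstanceState(q=state.q, v=state.v, n=state.n)
            midstances.append(last_sensed)
        else:  # step
            if last_sensed is None or last_sensed.n != state.n:
                raise GaitstabError("internal: step event without a sensed midstance")
            p_new = foot_placement(params, last_sensed, state.p)
            step_events.append((t_ev, state.p, p_new, state.n))
            state = replace(state, p=p_new, n=state.n + 1)
    emit_until(t_end, inclusive=True)

    return Trajectory(
        t=sample_t,
        x=out_x,
        v=out_v,
        p=out_p,
        step_idx=out_n,
        step_events=step_events,
        midstances=midstances,
        params=params,
    )


def iterate_midstance_map(
    params: WalkerParams, ms: MidstanceState, n: int
) -> list[MidstanceState]:
    """Iterate the midstance map ``n`` times, returning all n+1 states."""
    states = [ms]
    for _ in range(n):
        ms = midstance_map(params, ms)
        states.append(ms)
    return states
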