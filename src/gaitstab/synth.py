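"""Synthetic gait generation: noisy walkers, perturbation protocols, fixtures.

The generator emulates the statistical structure the regression estimator
assumes: the midstance CoM state linearly drives the next foot placement,
plus additive per-step motor noise on the realized placement.  Optional
sensory noise perturbs only what the controller *senses*; the recorded
true states always satisfy the closed-form between-step dynamics exactly.

Every dataset is a pure function of (parameters, noise spec, seed,
n_steps): independent named substreams per noise channel mean that
toggling sensory noise never shifts the motor-noise draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DivergenceError
from .estimation import StepTable, collect_step_table
from .stability import orbit_reference, periodic_orbit
from .walker import (
    MidstanceState,
    PendulumState,
    PerturbationEvent,
    Trajectory,
    WalkerParams,
    simulate,
)

#: Abort a noisy walk when |q| exceeds this many metres.
DEFAULT_DIVERGENCE_BOUND = 10.0

# substream labels (spawn keys) for the independent noise channels
_MOTOR, _SENSE_Q, _SENSE_V = 0, 1, 2


@dataclass(frozen=True)
class NoiseSpec:
    """Noise configuration for synthetic gait.

    sigma_p is the s.d. of the additive Gaussian motor noise on each
    realized foot placement (m).  sigma_sense_q / sigma_sense_v corrupt
    only the controller's sensed midstance position (m) and velocity
    (m/s).  All zero reproduces the deterministic system bitwise.
    """

    sigma_p: float = 0.0
    sigma_sense_q: float = 0.0
    sigma_sense_v: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_p", "sigma_sense_q", "sigma_sense_v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def streams(self) -> dict[str, np.random.Generator]:
        root = np.random.SeedSequence(self.seed)
        motor, sq, sv = root.spawn(3)
        return {
            "motor": np.random.default_rng(motor),
            "sense_q": np.random.default_rng(sq),
            "sense_v": np.random.default_rng(sv),
        }


def generate_noisy_walk(
    params: WalkerParams,
    noise: NoiseSpec,
    n_steps: int,
    dt: float = 0.01,
    divergence_bound: float = DEFAULT_DIVERGENCE_BOUND,
) -> tuple[Trajectory, StepTable]:
    """Simulate a walker with per-step motor (and optional sensory) noise.

    The walk starts on the deterministic periodic orbit.  At each step the
    realized placement is the control-law value computed from the (possibly
    noisily sensed) midstance state, plus motor noise
    ``eps ~ Normal(0, sigma_p^2)``.  Between steps the true state follows
    the exact closed-form flow.

    Returns the densely sampled trajectory and the per-step table of true
    midstance states and placements.

    Raises
    ------
    DivergenceError
        When |q| at any midstance exceeds ``divergence_bound`` (unstable
        parameters with noise eventually escape).
    """
    if n_steps < 2:
        raise ValueError(f"n_steps must be >= 2, got {n_steps}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    rngs = noise.streams()
    eps_motor = rngs["motor"].normal(0.0, noise.sigma_p, size=n_steps) if noise.sigma_p else np.zeros(n_steps)
    eps_q = rngs["sense_q"].normal(0.0, noise.sigma_sense_q, size=n_steps) if noise.sigma_sense_q else np.zeros(n_steps)
    eps_v = rngs["sense_v"].normal(0.0, noise.sigma_sense_v, size=n_steps) if noise.sigma_sense_v else np.zeros(n_steps)

    ref = periodic_orbit(params)
    c, s = params.half_step_constants()
    w = params.omega
    T = params.t_step

    q, v, p = ref.q, ref.v, 0.0
    x0 = p + q

    n_per_step = max(1, int(round(T / dt)))
    dt_eff = T / n_per_step  # exact closed form; grid snapped to divide t_step
    tau = dt_eff * np.arange(n_per_step)
    half = T / 2.0

    t_list, x_list, v_list, p_list, n_list = [], [], [], [], []
    step_events: list[tuple[float, float, float, int]] = []
    midstances: list[MidstanceState] = []
    records = []

    for n in range(n_steps):
        if abs(q) > divergence_bound:
            raise DivergenceError(
                f"walker diverged (|q| = {abs(q):.3g} m > {divergence_bound} m) "
                f"at step {n}",
                step=n,
            )
        midstances.append(MidstanceState(q=q, v=v, n=n))
        # controller acts on the sensed state; record keeps the true one
        q_sense = q + eps_q[n]
        v_sense = v + eps_v[n]
        dp = params.offset(n) + params.b_p * q_sense + params.b_d * v_sense + eps_motor[n]
        p_next = p + dp

        # dense samples over [n*T, (n+1)*T): first half with p, second with p_next
        ch, sh = np.cosh(w * tau), np.sinh(w * tau)
        q_arc = q * ch + (v / w) * sh
        v_arc = q * w * sh + v * ch
        t_arc = n * T + tau
        in_first_half = tau < half - 1e-12
        p_arc = np.where(in_first_half, p, p_next)
        # state at the step instant, then re-expressed about the new contact
        chh, shh = math.cosh(w * half), math.sinh(w * half)
        q_step = q * chh + (v / w) * shh
        v_step = q * w * shh + v * chh
        q_post = q_step - dp
        tau2 = tau[~in_first_half] - half
        ch2, sh2 = np.cosh(w * tau2), np.sinh(w * tau2)
        q_arc2 = q_post * ch2 + (v_step / w) * sh2
        v_arc2 = q_post * w * sh2 + v_step * ch2
        x_arc = np.where(in_first_half, p + q_arc, 0.0)
        x_arc[~in_first_half] = p_next + q_arc2
        v_out = v_arc.copy()
        v_out[~in_first_half] = v_arc2
        t_list.append(t_arc)
        x_list.append(x_arc)
        v_list.append(v_out)
        p_list.append(p_arc)
        n_list.append(np.where(in_first_half, n, n + 1))

        step_events.append(((n + 0.5) * T, p, p_next, n))
        records.append(
            {
                "n": n,
                "t_mid_s": n * T,
                "q_m": q,
                "v_mps": v,
                "p_m": p,
                "p_next_m": p_next,
                "delta_p_m": dp,
                "parity": 1 if n % 2 == 0 else -1,
            }
        )
        # next true midstance: half-step flow from the post-step state
        q = q_post * chh + (v_step / w) * shh
        v = q_post * w * shh + v_step * chh
        p = p_next

    midstances.append(MidstanceState(q=q, v=v, n=n_steps))
    # closing sample at t = n_steps * T
    t_list.append(np.array([n_steps * T]))
    x_list.append(np.array([p + q]))
    v_list.append(np.array([v]))
    p_list.append(np.array([p]))
    n_list.append(np.array([n_steps]))

    traj = Trajectory(
        t=np.concatenate(t_list),
        x=np.concatenate(x_list),
        v=np.concatenate(v_list),
        p=np.concatenate(p_list),
        step_idx=np.concatenate(n_list).astype(int),
        step_events=step_events,
        midstances=midstances,
        params=params,
    )
    return traj, StepTable.from_records(records)


def noise_input_matrix(params: WalkerParams) -> np.ndarray:
    """Column vector g mapping placement noise into the next midstance deviation.

    A placement error eps shifts the post-step relative position by -eps,
    which after the remaining half step contributes (-c*eps, -omega*s*eps)
    to the next midstance (q, v).  The stationary midstance deviation
    covariance of a stable noisy walker solves the discrete Lyapunov
    equation  Sigma = A Sigma A' + sigma_p^2 g g'.
    """
    c, s = params.half_step_constants()
    return np.array([[-c], [-params.omega * s]])


def perturbation_experiment(
    params_list: list[WalkerParams],
    perturbation: PerturbationEvent,
    n_steps: int = 20,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Shared-orbit perturbation protocol: deviation norms per midstance.

    Each system starts on its own periodic orbit, receives the same
    instantaneous perturbation, and the Euclidean deviation
    ``||delta_n|| = ||(q_n - q_ref(n), v_n - v_ref)||`` is recorded at
    every midstance.  Returns a long DataFrame with columns
    (system, b_p, b_d, n, t_mid_s, deviation_norm).
    """
    rows = []
    for k, params in enumerate(params_list):
        ref0 = periodic_orbit(params)
        init = PendulumState(t=0.0, x=ref0.q, v=ref0.v, p=0.0, n=0)
        traj = simulate(
            params, init, n_steps=n_steps, dt=dt, perturbations=[perturbation]
        )
        for ms in traj.midstances:
            ref = orbit_reference(params, ms.n)
            dev = math.hypot(ms.q - ref.q, ms.v - ref.v)
            rows.append(
                {
                    "system": k,
                    "b_p": params.b_p,
                    "b_d": params.b_d,
                    "n": ms.n,
                    "t_mid_s": ms.n * params.t_step,
                    "deviation_norm": dev,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture registry: small, deterministic, generated on demand

_EXAMPLE_OMEGA = 3.13  # s^-1, leg length ~1 m
_EXAMPLE_TSTEP = 0.5  # s (cadence 120 steps/min)


def _fixture_stable_noisy_small():
    params = WalkerParams(
        omega=_EXAMPLE_OMEGA, b_o=0.02, b_p=2.5, b_d=0.6,
        t_step=_EXAMPLE_TSTEP, mode="alternating",
    )
    noise = NoiseSpec(sigma_p=0.01, seed=1)
    _, table = generate_noisy_walk(params, noise, n_steps=200)
    return table, {"params": params, "noise": noise, "n_steps": 200}


def _fixture_hof_walker():
    from .stability import hof_gains

    bp, bd = hof_gains(_EXAMPLE_OMEGA, _EXAMPLE_TSTEP)
    params = WalkerParams(
        omega=_EXAMPLE_OMEGA, b_o=0.02, b_p=bp, b_d=bd,
        t_step=_EXAMPLE_TSTEP, mode="alternating",
    )
    noise = NoiseSpec(sigma_p=0.01, seed=7)
    _, table = generate_noisy_walk(params, noise, n_steps=1000)
    return table, {"params": params, "noise": noise, "n_steps": 1000}


def _fixture_fig_quartet():
    quartet = [
        WalkerParams(
            omega=_EXAMPLE_OMEGA, b_o=0.02, b_p=2.5, b_d=bd,
            t_step=_EXAMPLE_TSTEP, mode="alternating",
        )
        for bd in (0.3, 0.6, 1.1, 1.5)
    ]
    pert = PerturbationEvent(time=1.0, dx=0.01)
    df = perturbation_experiment(quartet, pert, n_steps=20)
    return df, {"params_list": quartet, "perturbation": pert, "n_steps": 20}


FIXTURES = {
    "stable-noisy-small": _fixture_stable_noisy_small,
    "hof-walker": _fixture_hof_walker,
    "fig4-quartet": _fixture_fig_quartet,
}


def fixture_dataset(name: str):
    """Deterministic, seed-pinned demo dataset from the registry.

    Returns ``(data, config)`` where ``data`` is a StepTable (walk
    fixtures) or DataFrame (perturbation quartet) and ``config`` records
    exactly how it was generated.
    """
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return builder()
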