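"""Periodic orbits and step-to-step stability of the walking system.

Every walking system (away from two measure-zero parameter lines) has a
periodic orbit of the relative state ``(q, v)``: period ``t_step`` for
progressive stepping and ``2*t_step`` for alternating stepping.  Small
midstance deviations ``delta_n`` from that orbit propagate linearly,
``delta_{n+1} = A @ delta_n``, through the constant 2x2 transition matrix

    A = [[c^2 + s^2 - c*b_p,   (2s/w - b_d)*c     ],
         [(2c - b_p)*s*w,      c^2 + s^2 - s*w*b_d]]

with ``c = cosh(w*t_step/2)``, ``s = sinh(w*t_step/2)``.  The orbit is
asymptotically stable iff the spectral radius ``rho(A) < 1``, which holds
exactly on the open triangle

    b_p < 2c,    b_d > 2s/w,    b_d < b_p*c/(w*s)

in the gain plane.  The offset ``b_o`` never enters ``A``: it shifts the
orbit but not its stability.  Both stepping modes share the same ``A``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SingularOrbitError
from .walker import MidstanceState, WalkerParams, half_step_constants

#: A system is called asymptotically stable only if rho < 1 - STABILITY_TOL;
#: points with |rho - 1| <= STABILITY_TOL are flagged marginal.
STABILITY_TOL = 1e-12

_SINGULAR_TOL = 1e-12


def periodic_orbit(params: WalkerParams) -> MidstanceState:
    """Closed-form midstance reference state of the periodic orbit.

    progressive:  q_ref = 0,  v_ref = b_o / (2s/w - b_d),  period t_step
    alternating:  q_ref(n) = (-1)^n * b_o / (2c - b_p),  v_ref = 0,
                  period 2*t_step

    Returns the parity-0 (n even) branch for alternating systems.

    Raises
    ------
    SingularOrbitError
        If the denominator vanishes (progressive: ``b_d == 2s/w``;
        alternating: ``b_p == 2c``), where no such orbit exists.
    """
    c, s = params.half_step_constants()
    w = params.omega
    if params.mode == "progressive":
        denom = 2 * s / w - params.b_d
        if abs(denom) < _SINGULAR_TOL:
            raise SingularOrbitError(
                f"progressive orbit is singular: b_d = 2s/omega = {2 * s / w:.6g}"
            )
        return MidstanceState(q=0.0, v=params.b_o / denom, n=0)
    denom = 2 * c - params.b_p
    if abs(denom) < _SINGULAR_TOL:
        raise SingularOrbitError(
            f"alternating orbit is singular: b_p = 2c = {2 * c:.6g}"
        )
    return MidstanceState(q=params.b_o / denom, v=0.0, n=0)


def orbit_reference(params: WalkerParams, n: int) -> MidstanceState:
    """Reference midstance state at step ``n`` (handles alternating parity)."""
    ref = periodic_orbit(params)
    if params.mode == "alternating" and n % 2 == 1:
        return MidstanceState(q=-ref.q, v=-ref.v, n=n)
    return MidstanceState(q=ref.q, v=ref.v, n=n)


def transition_matrix(params: WalkerParams) -> np.ndarray:
    """Step-to-step error-propagation matrix ``A`` (2x2).

    Identical for progressive and alternating modes; independent of ``b_o``.
    """
    c, s = params.half_step_constants()
    w = params.omega
    bp, bd = params.b_p, params.b_d
    return np.array(
        [
            [c * c + s * s - c * bp, (2 * s / w - bd) * c],
            [(2 * c - bp) * s * w, c * c + s * s - s * w * bd],
        ]
    )


def _rho_from_trace_det(tr, det):
    """Spectral radius of a real 2x2 matrix from its trace and determinant.

    Closed form via the characteristic polynomial; vectorized.  For a
    complex conjugate pair (negative discriminant) the common modulus is
    sqrt(det).
    """
    tr = np.asarray(tr, dtype=float)
    det = np.asarray(det, dtype=float)
    disc = tr * tr - 4.0 * det
    real = disc >= 0
    sq = np.sqrt(np.where(real, disc, 0.0))
    rho_real = np.maximum(np.abs(tr + sq), np.abs(tr - sq)) / 2.0
    rho_cplx = np.sqrt(np.maximum(det, 0.0))
    out = np.where(real, rho_real, rho_cplx)
    return out if out.ndim else float(out)


def eigenvalues_2x2(A: np.ndarray) -> tuple[complex, complex]:
    """Eigenvalues of a real 2x2 matrix from the quadratic formula.

    Exact on boundary cases (e.g. an eigenvalue of exactly +-1 on the
    stability-region edges), unlike iterative factorizations.
    """
    tr = A[0, 0] + A[1, 1]
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    disc = tr * tr - 4.0 * det
    if disc >= 0:
        sq = np.sqrt(disc)
        return (tr - sq) / 2.0, (tr + sq) / 2.0
    sq = np.sqrt(-disc)
    return complex(tr / 2.0, -sq / 2.0), complex(tr / 2.0, sq / 2.0)


def spectral_norm(A: np.ndarray) -> float:
    """Largest eigenvalue modulus (spectral radius) of a real 2x2 matrix."""
    A = np.asarray(A, dtype=float)
    tr = A[0, 0] + A[1, 1]
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    return float(_rho_from_trace_det(tr, det))


@dataclass(frozen=True)
class StabilityReport:
    """Stability verdict for one walking system.

    ``inequality_flags`` are the three closed-form triangle conditions
    (b_p < 2c, b_d > 2s/w, b_d < b_p*c/(w*s)); ``stable`` is the
    independent eigenvalue criterion ``rho < 1 - STABILITY_TOL``.
    ``marginal`` flags |rho - 1| <= STABILITY_TOL.
    """

    A: np.ndarray
    trace: float
    det: float
    eigenvalues: tuple[complex, complex]
    rho: float
    inequality_flags: tuple[bool, bool, bool]
    stable: bool
    marginal: bool

    @property
    def inequalities_hold(self) -> bool:
        return all(self.inequality_flags)

    def to_dict(self) -> dict:
        """Flat key-value representation (machine parseable)."""
        lam1, lam2 = self.eigenvalues
        return {
            "A11": self.A[0, 0],
            "A12": self.A[0, 1],
            "A21": self.A[1, 0],
            "A22": self.A[1, 1],
            "trace": self.trace,
            "det": self.det,
            "eig1_re": complex(lam1).real,
            "eig1_im": complex(lam1).imag,
            "eig2_re": complex(lam2).real,
            "eig2_im": complex(lam2).imag,
            "rho": self.rho,
            "ineq_bp": int(self.inequality_flags[0]),
            "ineq_bd_lower": int(self.inequality_flags[1]),
            "ineq_bd_upper": int(self.inequality_flags[2]),
            "stable": int(self.stable),
            "marginal": int(self.marginal),
        }


def is_stable(params: WalkerParams) -> StabilityReport:
    """Evaluate both stability criteria for one parameter set.

    The three triangle inequalities and the eigenvalue criterion are
    computed independently; they agree everywhere off the region boundary.
    """
    c, s = params.half_step_constants()
    w = params.omega
    A = transition_matrix(params)
    tr = float(A[0, 0] + A[1, 1])
    det = float(A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0])
    eig = eigenvalues_2x2(A)
    rho = float(_rho_from_trace_det(tr, det))
    flags = (
        2 * c - params.b_p > 0,
        2 * s / w - params.b_d < 0,
        params.b_d < params.b_p * c / (w * s),
    )
    return StabilityReport(
        A=A,
        trace=tr,
        det=det,
        eigenvalues=eig,
        rho=rho,
        inequality_flags=flags,
        stable=rho < 1.0 - STABILITY_TOL,
        marginal=abs(rho - 1.0) <= STABILITY_TOL,
    )


def region_vertices(omega: float, t_step: float) -> np.ndarray:
    """Corner points of the triangular stability region in the (b_p, b_d) plane.

    The three boundary lines ``b_p = 2c``, ``b_d = 2s/w`` and
    ``b_d = b_p*c/(w*s)`` intersect pairwise at

        (2s^2/c, 2s/w),  (2c, 2s/w),  (2c, 2c^2/(w*s)).

    Returns an array of shape (3, 2), rows in that order.
    """
    c, s = half_step_constants(omega, t_step)
    return np.array(
        [
            [2 * s * s / c, 2 * s / omega],
            [2 * c, 2 * s / omega],
            [2 * c, 2 * c * c / (omega * s)],
        ]
    )


def region_area(omega: float, t_step: float) -> float:
    """Area of the stability triangle in the gain plane."""
    v = region_vertices(omega, t_step)
    return 0.5 * abs(
        (v[1, 0] - v[0, 0]) * (v[2, 1] - v[0, 1])
        - (v[2, 0] - v[0, 0]) * (v[1, 1] - v[0, 1])
    )


@dataclass
class StabilityRegion:
    """Sampled stability landscape over a rectangular gain grid.

    ``rho`` has shape ``(len(bd), len(bp))`` so that it maps directly onto
    a heatmap with ``b_p`` on the horizontal axis.
    """

    omega: float
    t_step: float
    vertices: np.ndarray
    bp_interval: tuple[float, float]
    bd_interval: tuple[float, float]
    bp: np.ndarray | None = None
    bd: np.ndarray | None = None
    rho: np.ndarray | None = None

    @property
    def stable_mask(self) -> np.ndarray | None:
        return None if self.rho is None else self.rho < 1.0

    def to_frame(self) -> pd.DataFrame:
        """Long-format (b_p, b_d, rho, stable) table."""
        if self.rho is None:
            raise ValueError("region has no sampled grid")
        BP, BD = np.meshgrid(self.bp, self.bd)
        return pd.DataFrame(
            {
                "b_p": BP.ravel(),
                "b_d": BD.ravel(),
                "rho": self.rho.ravel(),
                "stable": (self.rho.ravel() < 1.0).astype(int),
            }
        )


def _intervals(omega: float, t_step: float):
    c, s = half_step_constants(omega, t_step)
    return (2 * s * s / c, 2 * c), (2 * s / omega, 2 * c * c / (omega * s))


def region_grid(
    omega: float,
    t_step: float,
    bp_range: tuple[float, float] = (0.0, 3.5),
    bd_range: tuple[float, float] = (0.0, 1.6),
    resolution: int | tuple[int, int] = (351, 161),
) -> StabilityRegion:
    """Sample the spectral radius over a rectangular (b_p, b_d) grid.

    Vectorized closed-form evaluation; suitable for heatmap export.  The
    default window and resolution resolve the full triangle for typical
    human-scale parameters.
    """
    if np.isscalar(resolution):
        n_bp = n_bd = int(resolution)
    else:
        n_bp, n_bd = map(int, resolution)
    if n_bp < 2 or n_bd < 2:
        raise ValueError("resolution must be >= 2 per axis")
    if not (bp_range[1] > bp_range[0] and bd_range[1] > bd_range[0]):
        raise ValueError("grid ranges must be nonempty")
    c, s = half_step_constants(omega, t_step)
    bp = np.linspace(*bp_range, n_bp)
    bd = np.linspace(*bd_range, n_bd)
    BP, BD = np.meshgrid(bp, bd)
    a11 = c * c + s * s - c * BP
    a12 = (2 * s / omega - BD) * c
    a21 = (2 * c - BP) * s * omega
    a22 = c * c + s * s - s * omega * BD
    rho = _rho_from_trace_det(a11 + a22, a11 * a22 - a12 * a21)
    bp_iv, bd_iv = _intervals(omega, t_step)
    return StabilityRegion(
        omega=omega,
        t_step=t_step,
        vertices=region_vertices(omega, t_step),
        bp_interval=bp_iv,
        bd_interval=bd_iv,
        bp=bp,
        bd=bd,
        rho=rho,
    )


def region_vs_cadence(
    omega: float,
    cadence_range: tuple[float, float] | float,
    resolution: int = 81,
) -> pd.DataFrame:
    """Stability-interval endpoints as a function of stepping cadence.

    Cadence is in steps per minute; ``t_step = 60 / cadence``.  For each
    cadence the triangle is projected onto the gain axes:
    ``b_p in [2s^2/c, 2c]`` and ``b_d in [2s/w, 2c^2/(w*s)]``.  All four
    endpoints decrease with cadence (slower walking needs higher gains).
    """
    if np.isscalar(cadence_range):
        cadences = np.array([float(cadence_range)])
    else:
        lo, hi = cadence_range
        cadences = np.linspace(lo, hi, resolution) if hi > lo else np.array([lo])
    if np.any(cadences <= 0):
        raise ValueError("cadences must be positive")
    rows = []
    for cad in cadences:
        t_step = 60.0 / cad
        (bp_lo, bp_hi), (bd_lo, bd_hi) = _intervals(omega, t_step)
        rows.append(
            {
                "cadence_spm": cad,
                "t_step_s": t_step,
                "bp_min": bp_lo,
                "bp_max": bp_hi,
                "bd_min": bd_lo,
                "bd_max": bd_hi,
            }
        )
    return pd.DataFrame(rows)


def recurrence_period(
    params: WalkerParams,
    t_max: float | None = None,
    dt: float = 0.005,
    tol: float = 1e-6,
) -> float:
    """Minimal recurrence period of the relative state ``(q, v)`` by simulation.

    Starts on the closed-form periodic orbit, simulates with the exact
    hyperbolic flow, and returns the smallest sampled ``t > 0`` at which
    both ``q`` and ``v`` return to their initial midstance values within
    ``tol``.  The expected result is ``t_step`` for progressive and
    ``2*t_step`` for alternating stepping.
    """
    from .walker import PendulumState, simulate

    if t_max is None:
        t_max = 4.0 * params.t_step
    ref = periodic_orbit(params)
    init = PendulumState(t=0.0, x=ref.q, v=ref.v, p=0.0, n=0)
    n_steps = max(1, int(np.ceil(t_max / params.t_step)))
    traj = simulate(params, init, n_steps=n_steps, dt=dt)
    q, v = traj.q, traj.v
    hit = np.nonzero(
        (np.abs(q - q[0]) < tol) & (np.abs(v - v[0]) < tol) & (traj.t > 0)
    )[0]
    if len(hit) == 0:
        raise ValueError(f"no recurrence within t_max = {t_max} s at tol = {tol}")
    return float(traj.t[hit[0]])


def hof_gains(omega: float, t_step: float) -> tuple[float, float]:
    """Gains equivalent to a constant-offset-from-XCoM placement rule.

    Placing each foot at a fixed offset from the extrapolated center of
    mass corresponds, after shifting the sensing instant to midstance, to
    ``b_p = c + s`` and ``b_d = (c + s) / omega``.  These gains lie well
    inside the stability triangle.
    """
    c, s = half_step_constants(omega, t_step)
    return c + s, (c + s) / omega


def xcom(q, v, omega: float):
    """Extrapolated center of mass relative to the contact point: ``q + v/omega``."""
    if not omega > 0:
        raise ValueError(f"omega must be positive, got {omega}")
    return q + np.asarray(v) / omega if isinstance(q, np.ndarray) else q + v / omega
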