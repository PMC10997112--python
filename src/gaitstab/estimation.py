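"""Control-gain estimation from step-level gait data.

If foot placement follows the walker's PD control law, the step-to-step
placement shift ``delta_p = p_{n+1} - p_n`` is a linear function of the
midstance relative CoM position ``q_n`` and velocity ``v_n``:

    progressive:  delta_p = b_o        + b_p * q_n + b_d * v_n
    alternating:  delta_p = (-1)^n b_o + b_p * q_n + b_d * v_n

so ordinary least squares of ``delta_p`` on ``(q, v)`` — with an intercept
for progressive data or an explicit parity regressor for alternating data
— recovers the gains as slopes.  :class:`FootPlacementModel` exposes this
the way statsmodels exposes a regression model: build it from a
:class:`StepTable`, call :meth:`~FootPlacementModel.fit`, and read the
estimates, standard errors and adjusted R-squared off the returned
:class:`GainEstimate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import SingularDesignError
from .walker import Mode, Trajectory

STEP_TABLE_COLUMNS = [
    "n",
    "t_mid_s",
    "q_m",
    "v_mps",
    "p_m",
    "p_next_m",
    "delta_p_m",
    "parity",
]

_ZERO_VAR_TOL = 1e-13


@dataclass
class StepTable:
    """Per-step records feeding the regression estimator.

    One row per completed step ``n``: midstance time, exact midstance
    relative position and velocity, current and next contact point, their
    difference ``delta_p``, and the parity sign ``(-1)^n``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in STEP_TABLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"step table missing columns: {missing}")
        self.frame = self.frame[STEP_TABLE_COLUMNS].reset_index(drop=True)
        n = self.frame["n"].to_numpy()
        if len(n) and np.any(np.diff(n) != 1):
            raise ValueError("step indices must be consecutive")
        resid = self.frame["delta_p_m"] - (
            self.frame["p_next_m"] - self.frame["p_m"]
        )
        if len(n) and np.max(np.abs(resid)) > 1e-9:
            raise ValueError("delta_p_m inconsistent with p_m and p_next_m")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_records(cls, records: list[dict]) -> "StepTable":
        return cls(pd.DataFrame.from_records(records, columns=STEP_TABLE_COLUMNS))


def collect_step_table(traj: Trajectory) -> StepTable:
    """Extract the per-step regression records from a simulated trajectory.

    Midstance states are taken from the exact closed-form states recorded
    during simulation (never interpolated from the sampling grid); the
    placement pairs come from the step-event log.  One record per
    completed step: midstance ``n`` paired with the placement taken at
    ``(n + 1/2) * t_step``.
    """
    if len(traj.step_events) < 2:
        raise ValueError(
            "trajectory must contain at least 2 steps to build a step table"
        )
    T = traj.params.t_step
    mid_by_n = {ms.n: ms for ms in traj.midstances}
    records = []
    for t_ev, p_old, p_new, n in traj.step_events:
        ms = mid_by_n.get(n)
        if ms is None:
            continue
        records.append(
            {
                "n": n,
                "t_mid_s": n * T,
                "q_m": ms.q,
                "v_mps": ms.v,
                "p_m": p_old,
                "p_next_m": p_new,
                "delta_p_m": p_new - p_old,
                "parity": 1 if n % 2 == 0 else -1,
            }
        )
    return StepTable.from_records(records)


@dataclass
class GainEstimate:
    """Results of a foot-placement regression.

    Attributes
    ----------
    bp_hat, bd_hat : float
        Estimated proportional and derivative gains (slopes on q and v).
    bo_hat : float
        Estimated offset: the intercept (progressive) or the parity
        coefficient (alternating), m.
    bp_se, bd_se, bo_se : float
        Standard errors of the above.
    r2_adj : float
        Adjusted R-squared of the full model (may be negative for tiny n).
    r2_q_only, r2_v_only : float
        Adjusted R-squared of the single-predictor refits.
    n_steps : int
        Number of step records used.
    """

    mode: Mode
    bp_hat: float
    bd_hat: float
    bo_hat: float
    bp_se: float
    bd_se: float
    bo_se: float
    r2_adj: float
    r2_q_only: float
    r2_v_only: float
    n_steps: int
    _sm_results: object = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "bp_hat": self.bp_hat,
            "bd_hat": self.bd_hat,
            "bo_hat": self.bo_hat,
            "bp_se": self.bp_se,
            "bd_se": self.bd_se,
            "bo_se": self.bo_se,
            "r2_adj": self.r2_adj,
            "r2_q_only": self.r2_q_only,
            "r2_v_only": self.r2_v_only,
            "n_steps": self.n_steps,
        }

    def summary(self):
        """statsmodels-style summary table of the underlying OLS fit."""
        return self._sm_results.summary()


class FootPlacementModel:
    """OLS regression of foot placement on the midstance CoM state.

    Parameters
    ----------
    table : StepTable
        Per-step gait records.
    mode : {"progressive", "alternating"}
        Selects the offset structure: a plain intercept, or a parity
        column whose coefficient estimates the alternating offset.
    """

    def __init__(self, table: StepTable, mode: Mode = "progressive"):
        if mode not in ("progressive", "alternating"):
            raise ValueError(f"unknown mode {mode!r}")
        min_n = 4 if mode == "alternating" else 3
        if len(table) < min_n:
            raise ValueError(
                f"need at least {min_n} step records for {mode} estimation, "
                f"got {len(table)}"
            )
        self.table = table
        self.mode = mode
        f = table.frame
        self.endog = f["delta_p_m"].to_numpy(float)
        cols = {"const": np.ones(len(f))}
        if mode == "alternating":
            cols["parity"] = f["parity"].to_numpy(float)
        cols["q_m"] = f["q_m"].to_numpy(float)
        cols["v_mps"] = f["v_mps"].to_numpy(float)
        self.exog = pd.DataFrame(cols)

    # offset column: intercept for progressive, parity sign for alternating
    @property
    def _offset_col(self) -> str:
        return "parity" if self.mode == "alternating" else "const"

    def _check_design(self, exog: pd.DataFrame) -> None:
        bad = [
            c
            for c in exog.columns
            if c != "const" and float(np.std(exog[c])) < _ZERO_VAR_TOL
        ]
        rank = np.linalg.matrix_rank(exog.to_numpy())
        if bad or rank < exog.shape[1]:
            if not bad:
                bad = list(exog.columns)
            raise SingularDesignError(
                "regression design is rank deficient; offending columns: "
                + ", ".join(bad),
                columns=tuple(bad),
            )

    def _ols(self, columns: list[str]):
        exog = self.exog[columns]
        self._check_design(exog)
        return sm.OLS(self.endog, exog).fit()

    def fit(self) -> GainEstimate:
        """Fit the full model and the two single-predictor diagnostics."""
        base = ["const", "parity"] if self.mode == "alternating" else ["const"]
        full = self._ols(base + ["q_m", "v_mps"])
        r2_q = self._ols(base + ["q_m"]).rsquared_adj
        r2_v = self._ols(base + ["v_mps"]).rsquared_adj
        off = self._offset_col
        return GainEstimate(
            mode=self.mode,
            bp_hat=float(full.params["q_m"]),
            bd_hat=float(full.params["v_mps"]),
            bo_hat=float(full.params[off]),
            bp_se=float(full.bse["q_m"]),
            bd_se=float(full.bse["v_mps"]),
            bo_se=float(full.bse[off]),
            r2_adj=float(full.rsquared_adj),
            r2_q_only=float(r2_q),
            r2_v_only=float(r2_v),
            n_steps=len(self.table),
            _sm_results=full,
        )

    @classmethod
    def from_trajectory(
        cls, traj: Trajectory, mode: Mode | None = None
    ) -> "FootPlacementModel":
        """Build directly from a simulated trajectory (mode defaults to the walker's)."""
        return cls(collect_step_table(traj), mode or traj.params.mode)


def estimate_gains(table: StepTable, mode: Mode = "progressive") -> GainEstimate:
    """Convenience wrapper: ``FootPlacementModel(table, mode).fit()``."""
    return FootPlacementModel(table, mode).fit()


def single_predictor_r2(
    table: StepTable, mode: Mode = "progressive"
) -> tuple[float, float]:
    """Adjusted R-squared of the q-only and v-only regressions."""
    est = FootPlacementModel(table, mode).fit()
    return est.r2_q_only, est.r2_v_only
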