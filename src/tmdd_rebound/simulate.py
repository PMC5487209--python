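"""Stiff integration of the TMDD variants and trajectory-based rebound
detection.

All integration is done in dimensionless form (state order (x, z, y)
or (x, z, y, w), time tau = kon*R0*t) with an implicit solver and an
analytic Jacobian; dimensional time is recovered through the stored
time scale.  Rebound detection declares rebound when the receptor,
after first dipping below ``1 - delta``, later exceeds ``1 + delta``;
the threshold ``delta`` bounds the smallest reportable rebound (the
magnitude vanishes as the feedback speed goes to zero, so some cut-off
is unavoidable) and is carried in every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .feedback import FeedbackFunction, make_constant, secant_bounds
from .model_core import (
    DimensionalParams,
    DimensionlessParams,
    initial_state,
    nondimensionalize,
    rhs_basic,
    rhs_direct,
    rhs_full,
    rhs_receptor_only,
    steady_state,
)

__all__ = [
    "Trajectory",
    "ReboundResult",
    "IntegrationError",
    "integrate",
    "detect_rebound",
    "scan_alpha",
    "find_rebound_endpoint",
    "monitor_invariants",
]

DEFAULT_RTOL = 1e-10
DEFAULT_ATOL = 1e-12
DEFAULT_DELTA = 1e-6
STEADY_TOL = 1e-10
TAU_MAX = 1e7
NEG_TOL = 1e-6


class IntegrationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """A dimensionless solution with piecewise dense interpolants."""

    kind: str
    tau: np.ndarray
    states: np.ndarray          # shape (len(tau), n_state)
    q: DimensionlessParams
    time_scale: float | None = None   # kon*R0 (1/day); tau / time_scale = t
    segments: list = field(default_factory=list, repr=False)
    meta: dict = field(default_factory=dict)

    @property
    def y_index(self) -> int:
        return 0 if self.kind == "receptor_only" else 2

    @property
    def y(self) -> np.ndarray:
        return self.states[:, self.y_index]

    @property
    def t_days(self) -> np.ndarray | None:
        if self.time_scale is None:
            return None
        return self.tau / self.time_scale

    def eval(self, tau: float) -> np.ndarray:
        """Evaluate the dense solution at a single tau."""
        for t0, t1, sol in self.segments:
            if t0 <= tau <= t1:
                return sol(tau)
        raise ValueError(f"tau={tau} outside integrated range")

    def to_frame(self) -> pd.DataFrame:
        cols = {"receptor_only": ["y", "w"],
                "basic": ["x", "z", "y"],
                "direct": ["x", "z", "y"],
                "full": ["x", "z", "y", "w"]}[self.kind]
        df = pd.DataFrame(self.states[:, : len(cols)], columns=cols)
        df.insert(0, "tau", self.tau)
        if self.time_scale is not None:
            df.insert(1, "t_days", self.t_days)
        return df


@dataclass(frozen=True)
class ReboundResult:
    rebound: bool
    rmax_over_r0: float
    tau_max: float | None
    tmax_days: float | None
    nadir: float
    threshold_used: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "rebound": self.rebound,
            "rmax_over_r0": self.rmax_over_r0,
            "tau_max": self.tau_max,
            "tmax_days": self.tmax_days,
            "nadir": self.nadir,
            "threshold_used": self.threshold_used,
            "degenerate": self.degenerate,
        }


def _rhs_and_jac(kind: str, q: DimensionlessParams, h: FeedbackFunction):
    mu, k1, k2, k3, k4, eps = q.mu, q.k1, q.k2, q.k3, q.k4, q.eps

    if kind == "basic":
        def fun(_t, s):
            return rhs_basic(s, q)

        def jac(_t, s):
            x, z, y = s
            return np.array([
                [-k1 - y, mu * k2, -x],
                [y / mu, -(k2 + k4), x / mu],
                [-y / mu, k2, -k3 - x / mu],
            ])
        return fun, jac

    if kind == "direct":
        def fun(_t, s):
            return rhs_direct(s, q, h)

        def jac(_t, s):
            x, z, y = s
            hp = float(h.derivative(y))
            return np.array([
                [-k1 - y, mu * k2, -x],
                [y / mu, -(k2 + k4), x / mu],
                [-y / mu, k2, k3 * (hp - 1.0) - x / mu],
            ])
        return fun, jac

    if kind == "full":
        def fun(_t, s):
            return rhs_full(s, q, h)

        def jac(_t, s):
            x, z, y, _w = s
            hp = float(h.derivative(y))
            return np.array([
                [-k1 - y, mu * k2, -x, 0.0],
                [y / mu, -(k2 + k4), x / mu, 0.0],
                [-y / mu, k2, -k3 - x / mu, k3],
                [0.0, 0.0, eps * hp, -eps],
            ])
        return fun, jac

    if kind == "receptor_only":
        def fun(_t, s):
            return rhs_receptor_only(s, k3, eps, h)

        def jac(_t, s):
            y, _w = s
            hp = float(h.derivative(y))
            return np.array([[-k3, k3], [eps * hp, -eps]])
        return fun, jac

    raise ValueError(f"unknown model kind {kind!r}")


def integrate(
    kind: str,
    q: DimensionlessParams,
    h: FeedbackFunction | None = None,
    ic: np.ndarray | None = None,
    horizon: float | str = "to_steady_state",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    time_scale: float | None = None,
) -> Trajectory:
    """Integrate a model variant with an implicit stiff solver.

    ``horizon`` is either a final tau or ``"to_steady_state"``, which
    extends the integration in doubling chunks until the state is
    within ``1e-10`` (sup norm) of the attracting baseline or
    ``tau = 1e7`` is reached.  Raises :class:`IntegrationError` on
    solver failure and flags invariant breaches (components below
    ``-1e-6``) as model errors.
    """
    if h is None:
        h = make_constant()
    fun, jac = _rhs_and_jac(kind, q, h)
    y0 = np.asarray(ic, dtype=float) if ic is not None else initial_state(kind)
    ss = steady_state(kind)

    taus: list[np.ndarray] = []
    states: list[np.ndarray] = []
    segments = []
    t0 = 0.0
    chunk = 100.0
    while True:
        t1 = min(t0 + chunk, TAU_MAX) if horizon == "to_steady_state" else float(horizon)
        sol = solve_ivp(fun, (t0, t1), y0, method="Radau", jac=jac,
                        rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:
            raise IntegrationError(
                f"solver failed for kind={kind} on [{t0}, {t1}]: {sol.message}")
        if sol.y.min() < -NEG_TOL:
            raise IntegrationError(
                f"invariant breach: state component reached {sol.y.min():.3e} < -{NEG_TOL}")
        start = 1 if taus else 0  # drop duplicated junction point
        taus.append(sol.t[start:])
        states.append(sol.y[:, start:].T)
        segments.append((t0, sol.t[-1], sol.sol))
        y0 = sol.y[:, -1]
        t0 = sol.t[-1]
        if horizon != "to_steady_state":
            break
        if np.max(np.abs(y0 - ss)) < STEADY_TOL or t0 >= TAU_MAX:
            break
        chunk *= 2.0

    tau = np.concatenate(taus)
    traj = Trajectory(kind=kind, tau=tau, states=np.vstack(states), q=q,
                      time_scale=time_scale, segments=segments,
                      meta={"rtol": rtol, "atol": atol, "horizon": horizon})
    return traj


def _refine_max(traj: Trajectory, i: int) -> tuple[float, float]:
    """Refine a grid maximum of y using the dense interpolant."""
    yi = traj.y_index
    lo = traj.tau[max(i - 1, 0)]
    hi = traj.tau[min(i + 1, len(traj.tau) - 1)]
    if hi <= lo:
        return traj.tau[i], traj.y[i]
    res = minimize_scalar(lambda t: -float(traj.eval(t)[yi]),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": max(1e-12, 1e-10 * hi)})
    t_star = float(res.x)
    y_star = float(traj.eval(t_star)[yi])
    if y_star < traj.y[i]:
        return float(traj.tau[i]), float(traj.y[i])
    return t_star, y_star


def detect_rebound(traj: Trajectory, delta: float = DEFAULT_DELTA) -> ReboundResult:
    """Post-nadir receptor maximum relative to baseline.

    Rebound is declared when the maximum of ``y`` after the first time
    ``y < 1 - delta`` exceeds ``1 + delta``.  A trajectory that never
    dips (no effective dose) is flagged degenerate.
    """
    y = traj.y
    below = np.nonzero(y < 1.0 - delta)[0]
    if below.size == 0:
        return ReboundResult(False, float(np.max(y)), None, None,
                             float(np.min(y)), delta, degenerate=True)
    start = below[0]
    seg = y[start:]
    i_rel = int(np.argmax(seg))
    tau_max, ymax = _refine_max(traj, start + i_rel)
    nadir = float(np.min(y))
    tmax_days = tau_max / traj.time_scale if traj.time_scale else None
    return ReboundResult(bool(ymax > 1.0 + delta), float(ymax), tau_max,
                         tmax_days, nadir, delta)


def _run_alpha(p: DimensionalParams, h: FeedbackFunction, alpha: float,
               delta: float, rtol: float, atol: float) -> ReboundResult:
    q = nondimensionalize(p.with_alpha(alpha))
    traj = integrate("full", q, h, time_scale=p.time_scale,
                     rtol=rtol, atol=atol)
    return detect_rebound(traj, delta)


def scan_alpha(
    p: DimensionalParams,
    h: FeedbackFunction,
    alphas,
    delta: float = DEFAULT_DELTA,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> pd.DataFrame:
    """Rebound magnitude and timing across feedback speeds alpha (1/day)."""
    rows = []
    for a in np.asarray(alphas, dtype=float):
        if not a > 0:
            raise ValueError(f"alpha values must be > 0, got {a}")
        r = _run_alpha(p, h, a, delta, rtol, atol)
        rows.append((a, r.rmax_over_r0, r.tmax_days, r.rebound))
    return pd.DataFrame(rows, columns=["alpha", "rmax_over_r0", "tmax_days", "rebound"])


def find_rebound_endpoint(
    p: DimensionalParams,
    h: FeedbackFunction,
    alpha_lo: float = 1e-2,
    alpha_hi: float = 1.2,
    delta: float = DEFAULT_DELTA,
    xtol: float = 1e-3,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float:
    """Largest alpha at which simulated rebound still occurs.

    A coarse pre-scan (16 log-spaced speeds) brackets the last
    rebound-to-no-rebound transition, which is then refined by
    bisection to absolute tolerance ``xtol``.
    """
    grid = np.geomspace(alpha_lo, alpha_hi, 16)
    flags = [_run_alpha(p, h, a, delta, rtol, atol).rebound for a in grid]
    if not any(flags):
        raise ValueError("no rebound anywhere in the pre-scan bracket")
    if all(flags):
        return float(grid[-1])
    last_true = max(i for i, f in enumerate(flags) if f)
    lo, hi = grid[last_true], grid[last_true + 1]
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if _run_alpha(p, h, mid, delta, rtol, atol).rebound:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def monitor_invariants(
    traj: Trajectory,
    h: FeedbackFunction | None = None,
    plane_tol: float = 1e-8,
) -> dict:
    """Check the flow invariants along a computed trajectory.

    Reports negativity breaches, the side of the total-receptor plane
    ``v = y + z = 1`` when the secant bounds place the parameters in a
    one-sided regime, and — for the full model — whether the moderator
    dipped to or below baseline (which predicts rebound).
    """
    report: dict = {"min_component": float(traj.states.min()),
                    "negativity_ok": bool(traj.states.min() >= -1e-9)}
    q = traj.q
    if traj.kind in ("basic", "direct", "full"):
        v = traj.states[:, 1] + traj.states[:, 2]  # z + y
        report["v_max"] = float(v.max())
        report["v_min"] = float(v.min())
        if h is not None:
            b = secant_bounds(h)
            if q.k4 >= q.k3 * (1.0 + b.M):
                report["v_le_1_expected"] = True
                report["v_le_1_ok"] = bool(v.max() <= 1.0 + plane_tol)
            if q.k4 <= q.k3 * (1.0 + b.m):
                report["v_ge_1_expected"] = True
                report["v_ge_1_ok"] = bool(v.min() >= 1.0 - plane_tol)
    if traj.kind == "full":
        w = traj.states[:, 3]
        y = traj.y
        interior = traj.tau > 0
        w_below = interior & (w <= 1.0)
        report["w_crossed_below_1"] = bool(w_below.any())
        report["predicts_rebound"] = bool(w_below.any())
        # moderator-sign consistency: while y <= 1 throughout, w must stay > 1
        if (y[interior] <= 1.0).all() and q.eps > 0 and (h is None or h.h0 > 0):
            report["moderator_sign_ok"] = bool((w[interior] > 1.0).all())
    return report
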