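"""Feedback functions for receptor-synthesis homeostasis.

The receptor production rate ``kin`` is modulated by a dimensionless
feedback function ``h(y)`` of the normalised receptor level ``y = R/R0``
(dimensionally ``H(R) = h(R/R0)``).  Negative feedback requires

* (h1) ``h(y) > 0`` for all ``y >= 0``,
* (h2) ``h(1) = 1`` (baseline is a steady state),
* (h3) ``h(y) > 1`` below baseline and ``0 < h(y) < 1`` above it,
* (h4) ``h`` is twice continuously differentiable.

The local feedback strength is ``h0 = -h'(1) >= 0``.  The secant slopes
``(h(y) - 1)/(1 - y)`` over ``y in [0, 1)`` have infimum ``m`` and
supremum ``M``; these bound ``h`` between two straight lines through
``(1, 1)`` and enter every rebound criterion for nonlinear feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "FeedbackFunction",
    "SecantBounds",
    "AssumptionReport",
    "make_constant",
    "make_mainly_linear",
    "make_hyperbolic",
    "make_custom",
    "validate_assumptions",
    "secant_bounds",
    "from_spec",
]

_H1_TOL = 1e-12  # tolerance on h(1) = 1


@dataclass(frozen=True)
class FeedbackFunction:
    """A dimensionless feedback function ``h(y)`` with its derivative.

    Attributes
    ----------
    family:
        One of ``constant``, ``mainly_linear``, ``hyperbolic``, ``custom``.
    evaluate, derivative:
        Vectorised callables for ``h`` and ``h'`` on ``y >= 0``.
    h0:
        Local feedback strength ``-h'(1)``.
    params:
        Family-specific constants (slope ``h0``, kink offset ``beta``,
        hyperbolic baseline fraction ``F0``).
    """

    family: str
    evaluate: Callable[[np.ndarray], np.ndarray]
    derivative: Callable[[np.ndarray], np.ndarray]
    h0: float
    params: dict = field(default_factory=dict)

    def __call__(self, y):
        return self.evaluate(y)


@dataclass(frozen=True)
class SecantBounds:
    """Infimum/supremum of the secant slopes of ``h`` over ``[0, 1)``.

    Satisfies ``0 <= m <= h0 <= M``.
    """

    m: float
    M: float
    h0: float

    def __iter__(self):
        return iter((self.m, self.M))


@dataclass(frozen=True)
class AssumptionCheck:
    name: str
    passed: bool
    detail: str = ""
    first_violation: float | None = None


@dataclass(frozen=True)
class AssumptionReport:
    family: str
    checks: tuple[AssumptionCheck, ...]

    @property
    def all_pass(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[AssumptionCheck]:
        return [c for c in self.checks if not c.passed]


def make_constant() -> FeedbackFunction:
    """No-feedback limit ``h(y) = 1`` (the basic TMDD model)."""

    def _eval(y):
        return np.ones_like(np.asarray(y, dtype=float))

    def _deriv(y):
        return np.zeros_like(np.asarray(y, dtype=float))

    return FeedbackFunction("constant", _eval, _deriv, h0=0.0, params={})


def make_mainly_linear(h0: float, beta: float) -> FeedbackFunction:
    """Feedback linear on an interval containing ``[0, 1]``.

    ``h(y) = 1 + h0*(1 - y)`` for ``y <= 1 + beta/h0`` with a smooth
    monotone tail that takes the value ``1 - beta`` with slope ``-h0``
    and zero curvature at the junction and stays inside
    ``((1-beta)/2, 1-beta]`` beyond it, so (h1)-(h4) hold globally.

    Parameters
    ----------
    h0:
        Slope magnitude of the linear branch, ``> 0``.
    beta:
        Depth below 1 reached at the junction, in ``(0, 1)``.
    """
    if not h0 > 0:
        raise ValueError(f"mainly-linear slope h0 must be > 0, got {h0}")
    if not 0 < beta < 1:
        raise ValueError(f"kink offset beta must be in (0, 1), got {beta}")

    y_kink = 1.0 + beta / h0
    sigma = (1.0 - beta) / (2.0 * h0)

    def _eval(y):
        y = np.asarray(y, dtype=float)
        s = y - y_kink
        linear = 1.0 + h0 * (1.0 - y)
        tail = (1.0 - beta) - h0 * sigma * np.tanh(np.maximum(s, 0.0) / sigma)
        return np.where(s <= 0.0, linear, tail)

    def _deriv(y):
        y = np.asarray(y, dtype=float)
        s = y - y_kink
        tail = -h0 / np.cosh(np.maximum(s, 0.0) / sigma) ** 2
        return np.where(s <= 0.0, -h0, tail)

    return FeedbackFunction(
        "mainly_linear", _eval, _deriv, h0=float(h0),
        params={"h0": float(h0), "beta": float(beta)},
    )


def make_hyperbolic(F0: float) -> FeedbackFunction:
    """Hyperbolic feedback ``h(y) = 1 / (F0 + (1 - F0) y)``.

    This is the form induced by a Michaelis-type moderator production
    ``Kmc03 / (Kmc03 + X3)`` after normalisation; ``F0`` is the baseline
    moderator fraction, in ``(0, 1)``, and ``h0 = 1 - F0``.
    """
    if not 0 < F0 < 1:
        raise ValueError(f"baseline fraction F0 must be in (0, 1), got {F0}")

    def _eval(y):
        y = np.asarray(y, dtype=float)
        return 1.0 / (F0 + (1.0 - F0) * y)

    def _deriv(y):
        y = np.asarray(y, dtype=float)
        return -(1.0 - F0) / (F0 + (1.0 - F0) * y) ** 2

    return FeedbackFunction(
        "hyperbolic", _eval, _deriv, h0=1.0 - float(F0), params={"F0": float(F0)}
    )


def make_custom(
    evaluate: Callable,
    derivative: Callable,
    h0: float | None = None,
    params: dict | None = None,
) -> FeedbackFunction:
    """Wrap user-supplied callables as a feedback function.

    ``h0`` defaults to ``-derivative(1)``.  The result should be passed
    through :func:`validate_assumptions` before use.
    """
    if h0 is None:
        h0 = float(-np.asarray(derivative(1.0)))
    return FeedbackFunction("custom", evaluate, derivative, h0=float(h0),
                            params=dict(params or {}))


def from_spec(spec: dict) -> FeedbackFunction:
    """Build a feedback function from a config mapping.

    Recognised keys: ``family`` plus ``h0``/``beta`` (mainly_linear) or
    ``F0`` (hyperbolic).
    """
    family = spec.get("family", "constant")
    if family == "constant":
        return make_constant()
    if family == "mainly_linear":
        return make_mainly_linear(spec["h0"], spec.get("beta", 0.5))
    if family == "hyperbolic":
        return make_hyperbolic(spec["F0"])
    raise ValueError(f"unknown feedback family {family!r} (custom functions "
                     "must be constructed programmatically)")


def validate_assumptions(
    h: FeedbackFunction,
    grid: np.ndarray | None = None,
) -> AssumptionReport:
    """Check (h1)-(h4) on a dense sample grid.

    The constant family declares the no-feedback case and is exempt from
    the strict inequalities of (h3).  ``h(1) = 1`` is checked to absolute
    tolerance 1e-12.
    """
    if grid is None:
        grid = np.concatenate([np.linspace(0.0, 2.0, 2001), np.linspace(2.0, 10.0, 801)])
    grid = np.asarray(grid, dtype=float)
    vals = np.asarray(h.evaluate(grid), dtype=float)
    derivs = np.asarray(h.derivative(grid), dtype=float)

    checks: list[AssumptionCheck] = []

    bad = ~(vals > 0)
    checks.append(_check("h1: h(y) > 0 for y >= 0", bad, grid))

    h1 = float(h.evaluate(1.0))
    checks.append(AssumptionCheck(
        "h2: h(1) = 1", abs(h1 - 1.0) <= _H1_TOL, detail=f"h(1) = {h1!r}"))

    if h.family == "constant":
        checks.append(AssumptionCheck(
            "h3: sign condition", True,
            detail="constant family: declared no-feedback case, h ≡ 1"))
    else:
        below = grid < 1.0 - 1e-12
        above = grid > 1.0 + 1e-12
        bad3 = (below & ~(vals > 1.0)) | (above & ~((vals > 0.0) & (vals < 1.0)))
        checks.append(_check("h3: h > 1 on [0,1), 0 < h < 1 on (1,inf)", bad3, grid))

    finite = np.isfinite(vals) & np.isfinite(derivs)
    checks.append(_check("h4: h, h' finite on grid", ~finite, grid))
    # continuity surrogate: no jump larger than grid-scale * local slope bound
    dy = np.diff(grid)
    jumps = np.abs(np.diff(vals))
    slope_bound = (np.abs(derivs[:-1]) + np.abs(derivs[1:]) + 1.0)
    bad_cont = jumps > slope_bound * dy * 10.0
    checks.append(_check("h4: no jumps (continuity surrogate)",
                         np.append(bad_cont, False), grid))

    return AssumptionReport(h.family, tuple(checks))


def _check(name: str, bad_mask: np.ndarray, grid: np.ndarray) -> AssumptionCheck:
    if bad_mask.any():
        idx = int(np.argmax(bad_mask))
        return AssumptionCheck(name, False, first_violation=float(grid[idx]),
                               detail=f"first violation at y = {grid[idx]:.6g}")
    return AssumptionCheck(name, True)


def secant_bounds(h: FeedbackFunction, n_grid: int = 2048) -> SecantBounds:
    """Compute ``m = inf`` and ``M = sup`` of ``(h(y)-1)/(1-y)`` on ``[0,1)``.

    Closed forms are used where the family admits them; otherwise a dense
    grid on ``[0, 1)`` with local refinement is used, and the ``y -> 1``
    limit ``h0`` is injected explicitly (the interval is half-open, so the
    limit value is attained only in the closure).
    """
    if h.family == "constant":
        return SecantBounds(0.0, 0.0, 0.0)
    if h.family == "mainly_linear":
        h0 = h.params["h0"]
        return SecantBounds(h0, h0, h0)
    if h.family == "hyperbolic":
        F0 = h.params["F0"]
        # secant slope (1-F0)/(F0+(1-F0)y) decreases on [0,1):
        # sup at y=0, inf is the y->1 limit h0 = 1-F0
        return SecantBounds(1.0 - F0, (1.0 - F0) / F0, 1.0 - F0)

    y = np.linspace(0.0, 1.0, n_grid, endpoint=False)
    sec = (np.asarray(h.evaluate(y), dtype=float) - 1.0) / (1.0 - y)
    if not np.all(np.isfinite(sec)):
        raise FloatingPointError("non-finite secant slope evaluations")
    sec = np.append(sec, h.h0)  # y -> 1 limit
    lo, hi = float(np.min(sec)), float(np.max(sec))
    # bounded local refinement around the grid extremes
    for target, which in ((np.argmin(sec[:-1]), "min"), (np.argmax(sec[:-1]), "max")):
        i = int(target)
        a = y[max(i - 1, 0)]
        b = y[min(i + 1, n_grid - 1)]
        yy = np.linspace(a, b, 257)
        yy = yy[yy < 1.0]
        ss = (np.asarray(h.evaluate(yy), dtype=float) - 1.0) / (1.0 - yy)
        if which == "min":
            lo = min(lo, float(np.min(ss)))
        else:
            hi = max(hi, float(np.max(ss)))
    return SecantBounds(lo, hi, h.h0)
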