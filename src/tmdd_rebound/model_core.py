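"""TMDD model equations, parameters, and non-dimensionalisation.

The dimensional one-compartment TMDD model tracks ligand L (the drug),
receptor R (the target) and complex P, with binding ``kon``/``koff``,
receptor turnover ``kin``/``kout`` and eliminations ``ke(L)``, ``ke(P)``.
With homeostatic feedback the synthesis term ``kin`` is multiplied by a
moderator F that relaxes toward ``H(R)`` at speed ``alpha``; the
quasi-equilibrium limit ``alpha -> inf`` substitutes ``F = H(R)``
directly ("direct feedback").

Scaling ``x = L/L0``, ``y = R/R0``, ``z = P/R0``, ``w = F`` and
``tau = kon*R0*t`` yields the dimensionless groups

    mu = R0/L0,  k1 = keL/(kon R0),  k2 = koff/(kon R0),
    k3 = kin/(kon R0^2) = kout/(kon R0),  k4 = keP/(kon R0),
    eps = alpha/(kon R0).

State vectors are ordered ``(x, z, y)`` for the basic/direct models and
``(x, z, y, w)`` for the full model, keeping the baseline Jacobian block
lower-triangular in the (x,z)/(y,w) split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .feedback import FeedbackFunction, make_constant

__all__ = [
    "DimensionalParams",
    "DimensionlessParams",
    "nondimensionalize",
    "dimensionalize",
    "rhs_basic",
    "rhs_direct",
    "rhs_full",
    "rhs_receptor_only",
    "initial_state",
    "steady_state",
]

MODEL_KINDS = ("basic", "direct", "full")


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional TMDD rates (per day), concentrations (nM), and dose.

    ``alpha`` is the feedback response speed (1/day, ``>= 0``); ``R0``
    is derived as ``kin/kout``.
    """

    kon: float    # 1/(nM day)
    koff: float   # 1/day
    kin: float    # nM/day
    kout: float   # 1/day
    keL: float    # 1/day, ligand elimination ke(L)
    keP: float    # 1/day, complex elimination ke(P)
    L0: float     # nM, bolus dose
    alpha: float = 0.0  # 1/day, feedback response speed

    def __post_init__(self):
        for name in ("kon", "koff", "kin", "kout", "keL", "keP", "L0"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")

    @property
    def R0(self) -> float:
        """Baseline receptor concentration kin/kout (nM)."""
        return self.kin / self.kout

    @property
    def time_scale(self) -> float:
        """kon*R0: converts dimensional time t (day) to tau = kon*R0*t."""
        return self.kon * self.R0

    def with_alpha(self, alpha: float) -> "DimensionalParams":
        return replace(self, alpha=alpha)


@dataclass(frozen=True)
class DimensionlessParams:
    mu: float
    k1: float
    k2: float
    k3: float
    k4: float
    eps: float = 0.0

    def __post_init__(self):
        for name in ("mu", "k1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.eps < 0:
            raise ValueError(f"eps must be >= 0, got {self.eps}")

    def with_eps(self, eps: float) -> "DimensionlessParams":
        return replace(self, eps=eps)


def nondimensionalize(p: DimensionalParams) -> DimensionlessParams:
    """Map dimensional parameters to the dimensionless groups.

    Both expressions for ``k3`` (``kin/(kon R0^2)`` and ``kout/(kon R0)``)
    agree identically since ``R0 = kin/kout``.
    """
    s = p.kon * p.R0
    return DimensionlessParams(
        mu=p.R0 / p.L0,
        k1=p.keL / s,
        k2=p.koff / s,
        k3=p.kout / s,
        k4=p.keP / s,
        eps=p.alpha / s,
    )


def dimensionalize(q: DimensionlessParams, kon: float, R0: float, L0: float) -> DimensionalParams:
    """Inverse of :func:`nondimensionalize` given the scales kon, R0, L0."""
    if not (kon > 0 and R0 > 0 and L0 > 0):
        raise ValueError("kon, R0 and L0 must be strictly positive")
    s = kon * R0
    kout = q.k3 * s
    return DimensionalParams(
        kon=kon,
        koff=q.k2 * s,
        kin=kout * R0,
        kout=kout,
        keL=q.k1 * s,
        keP=q.k4 * s,
        L0=L0,
        alpha=q.eps * s,
    )


def rhs_basic(state: np.ndarray, q: DimensionlessParams) -> np.ndarray:
    """Right-hand side of the basic (no-feedback) model, state (x, z, y)."""
    x, z, y = state
    xy = x * y / q.mu
    return np.array([
        -q.k1 * x - x * y + q.mu * q.k2 * z,
        xy - (q.k2 + q.k4) * z,
        q.k3 * (1.0 - y) - xy + q.k2 * z,
    ])


def rhs_direct(state: np.ndarray, q: DimensionlessParams, h: FeedbackFunction) -> np.ndarray:
    """Direct-feedback model (quasi-equilibrium moderator), state (x, z, y)."""
    x, z, y = state
    xy = x * y / q.mu
    return np.array([
        -q.k1 * x - x * y + q.mu * q.k2 * z,
        xy - (q.k2 + q.k4) * z,
        q.k3 * (float(h.evaluate(y)) - y) - xy + q.k2 * z,
    ])


def rhs_full(state: np.ndarray, q: DimensionlessParams, h: FeedbackFunction) -> np.ndarray:
    """Full feedback model with dynamic moderator, state (x, z, y, w)."""
    x, z, y, w = state
    xy = x * y / q.mu
    return np.array([
        -q.k1 * x - x * y + q.mu * q.k2 * z,
        xy - (q.k2 + q.k4) * z,
        q.k3 * (w - y) - xy + q.k2 * z,
        q.eps * (float(h.evaluate(y)) - w),
    ])


def rhs_receptor_only(state: np.ndarray, k3: float, eps: float,
                      h: FeedbackFunction | None = None) -> np.ndarray:
    """Receptor(-moderator) dynamics with ligand and complex absent.

    With ``eps == 0`` (or a direct-feedback reading) this is the scalar
    equation ``ydot = k3 (h(y) - y)`` in the first component; with
    ``eps > 0`` the pair (y, w) evolves as ``ydot = k3 (w - y)``,
    ``wdot = eps (h(y) - w)``.
    """
    if h is None:
        h = make_constant()
    if len(state) == 1:
        y = state[0]
        return np.array([k3 * (float(h.evaluate(y)) - y)])
    y, w = state
    return np.array([k3 * (w - y), eps * (float(h.evaluate(y)) - w)])


def initial_state(kind: str, y0: float = 1.0, w0: float = 1.0) -> np.ndarray:
    """Bolus initial condition: x(0)=1, z(0)=0, y(0)=1 (and w(0)=1)."""
    if kind in ("basic", "direct"):
        return np.array([1.0, 0.0, y0])
    if kind == "full":
        return np.array([1.0, 0.0, y0, w0])
    if kind == "receptor_only":
        return np.array([y0, w0])
    raise ValueError(f"unknown model kind {kind!r}")


def steady_state(kind: str) -> np.ndarray:
    """The globally attracting drug-free baseline."""
    if kind in ("basic", "direct"):
        return np.array([0.0, 0.0, 1.0])
    if kind == "full":
        return np.array([0.0, 0.0, 1.0, 1.0])
    if kind == "receptor_only":
        return np.array([1.0, 1.0])
    raise ValueError(f"unknown model kind {kind!r}")
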