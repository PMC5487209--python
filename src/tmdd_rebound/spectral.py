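"""Closed-form spectra of the baseline linearisations.

At the drug-free baseline the Jacobian splits into a ligand–complex
block with eigenvalues

    lambda_{1,2} = ( -(1+k1+k2+k4) ± sqrt((1+k1-k2-k4)^2 + 4 k2) ) / 2

(lambda1 the one nearer zero; both real and negative) and a
receptor–moderator block J0 = [[-k3, k3], [-eps*h0, -eps]] with

    lambda_{3,4} = ( -(k3+eps) ∓ sqrt((k3-eps)^2 - 4 eps k3 h0) ) / 2.

lambda3 and lambda4 are real outside the window eps1- < eps < eps1+,

    eps1± = k3 (1 + 2 h0 ± sqrt(4 h0 (1+h0))),

and a complex pair with real part -(k3+eps)/2 inside it.  At the
collisions the repeated eigenvalue is lambda*± = -(k3+eps1±)/2 =
-k3 (1+h0 ± sqrt(h0(1+h0))); as eps -> inf, lambda4 -> lambda_inf =
-k3 (1+h0) (the direct-feedback receptor eigenvalue) while
lambda3 -> -inf.  The crossing speeds

    eps2 = -lambda1 (lambda1+k3) / (lambda1 + k3 (1+h0))   (real branch)
    eps3 = -(k3 + 2 lambda1)                               (complex branch)

mark where lambda4 (or its real part) overtakes lambda1; which
eigenvalue is nearer zero decides the generic approach direction to
baseline and hence rebound.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, sqrt

import numpy as np

from .model_core import DimensionlessParams

__all__ = [
    "SpectralSummary",
    "EpsThresholds",
    "lambda12",
    "lambda34_direct",
    "lambda34_full",
    "eps_thresholds",
    "jacobian_at_baseline",
    "spectral_summary",
]

_COLLISION_RTOL = 1e-9


def lambda12(k1: float, k2: float, k4: float) -> tuple[float, float]:
    """Eigenvalues of the ligand–complex block; lambda2 < lambda1 < 0."""
    s = 1.0 + k1 + k2 + k4
    d = sqrt((1.0 + k1 - k2 - k4) ** 2 + 4.0 * k2)
    return 0.5 * (-s + d), 0.5 * (-s - d)


def lambda34_direct(k3: float, h0: float) -> float:
    """Receptor eigenvalue -k3*(1+h0) of the direct-feedback model."""
    return -k3 * (1.0 + h0)


def lambda34_full(k3: float, h0: float, eps: float) -> tuple[complex, complex]:
    """Eigenvalues of J0 = [[-k3, k3], [-eps h0, -eps]].

    Returned as (lambda3, lambda4) with Re(lambda3) <= Re(lambda4);
    real floats are returned as complex with zero imaginary part when
    the discriminant is negative, plain reals otherwise.
    """
    D = (k3 - eps) ** 2 - 4.0 * eps * k3 * h0
    half = -(k3 + eps) / 2.0
    if D >= 0.0:
        r = sqrt(D) / 2.0
        return half - r, half + r
    r = sqrt(-D) / 2.0
    return complex(half, -r), complex(half, r)


@dataclass(frozen=True)
class EpsThresholds:
    """Feedback-speed thresholds for the receptor–moderator block.

    ``eps2`` is ``None`` when its denominator ``lambda1 - lambda_inf``
    vanishes (the crossing moves to infinity there); classification
    treats that case as ``+inf``.
    """

    eps1_minus: float
    eps1_plus: float
    eps2: float | None
    eps3: float | None
    lambda_star_minus: float
    lambda_star_plus: float
    lambda_inf: float
    f_star_plus: float

    @property
    def eps2_or_inf(self) -> float:
        return inf if self.eps2 is None else self.eps2


def eps_thresholds(k3: float, h0: float, lambda1: float | None = None) -> EpsThresholds:
    """All eps-thresholds of the (y, w) block, plus collision eigenvalues.

    ``eps2`` and ``eps3`` require ``lambda1`` (they compare the two
    Jacobian blocks); pass ``None`` to omit them.
    """
    root = sqrt(4.0 * h0 * (1.0 + h0))
    e1m = k3 * (1.0 + 2.0 * h0 - root)
    e1p = k3 * (1.0 + 2.0 * h0 + root)
    lam_inf = -k3 * (1.0 + h0)
    lsm = -0.5 * (k3 + e1m)   # = -k3 (1+h0-sqrt(h0(1+h0)))
    lsp = -0.5 * (k3 + e1p)
    fsp = 1.0 + h0 + sqrt(h0 * (1.0 + h0))
    eps2 = eps3 = None
    if lambda1 is not None:
        denom = lambda1 - lam_inf
        if abs(denom) > _COLLISION_RTOL * max(abs(lambda1), abs(lam_inf), 1e-300):
            eps2 = -lambda1 * (lambda1 + k3) / denom
        eps3 = -(k3 + 2.0 * lambda1)
    return EpsThresholds(e1m, e1p, eps2, eps3, lsm, lsp, lam_inf, fsp)


def jacobian_at_baseline(kind: str, q: DimensionlessParams, h0: float) -> np.ndarray:
    """Baseline Jacobian in state order (x, z, y[, w]).

    The full-model matrix is block lower-triangular in the (x,z)/(y,w)
    split; the direct/basic matrices are 3x3 with the receptor row last.
    """
    Jxz = np.array([
        [-(q.k1 + 1.0), q.mu * q.k2],
        [1.0 / q.mu, -(q.k2 + q.k4)],
    ])
    if kind in ("basic", "direct"):
        hh = 0.0 if kind == "basic" else h0
        J = np.zeros((3, 3))
        J[:2, :2] = Jxz
        J[2, 0] = -1.0 / q.mu
        J[2, 1] = q.k2
        J[2, 2] = -q.k3 * (1.0 + hh)
        return J
    if kind == "full":
        J = np.zeros((4, 4))
        J[:2, :2] = Jxz
        J[2, 0] = -1.0 / q.mu
        J[2, 1] = q.k2
        J[2, 2] = -q.k3
        J[2, 3] = q.k3
        J[3, 2] = -q.eps * h0
        J[3, 3] = -q.eps
        return J
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass(frozen=True)
class SpectralSummary:
    """Closed-form spectrum and thresholds at the baseline state."""

    lambda1: float
    lambda2: float
    lambda3: complex
    lambda4: complex
    lambda3_real: bool
    discriminant: float
    thresholds: EpsThresholds

    @property
    def leading(self) -> float:
        """Real part of the eigenvalue nearest zero (governs the tail)."""
        return max(self.lambda1, self.lambda4.real if isinstance(self.lambda4, complex)
                   else self.lambda4)

    def to_dict(self) -> dict:
        t = self.thresholds
        lam3, lam4 = complex(self.lambda3), complex(self.lambda4)
        return {
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "lambda3_re": lam3.real, "lambda3_im": lam3.imag,
            "lambda4_re": lam4.real, "lambda4_im": lam4.imag,
            "lambda34_real": self.lambda3_real,
            "discriminant": self.discriminant,
            "lambda_inf": t.lambda_inf,
            "lambda_star_minus": t.lambda_star_minus,
            "lambda_star_plus": t.lambda_star_plus,
            "eps1_minus": t.eps1_minus,
            "eps1_plus": t.eps1_plus,
            "eps2": t.eps2,
            "eps3": t.eps3,
            "f_star_plus": t.f_star_plus,
        }


def spectral_summary(q: DimensionlessParams, h0: float) -> SpectralSummary:
    lam1, lam2 = lambda12(q.k1, q.k2, q.k4)
    lam3, lam4 = lambda34_full(q.k3, h0, q.eps)
    D = (q.k3 - q.eps) ** 2 - 4.0 * q.eps * q.k3 * h0
    return SpectralSummary(
        lambda1=lam1,
        lambda2=lam2,
        lambda3=lam3,
        lambda4=lam4,
        lambda3_real=D >= 0.0,
        discriminant=D,
        thresholds=eps_thresholds(q.k3, h0, lam1),
    )
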