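"""Theorem-based rebound classification.

Rebound is a post-dose rise of the free receptor above its pre-dose
baseline during the return to steady state.  For each model variant the
classifiers map parameters to ``rebound`` / ``no_rebound`` /
``indeterminate``:

* no feedback: rebound iff ``k4 < k1 and k4 < k3`` (equivalently
  ``keP < keL and keP < kout``);
* direct feedback: no rebound if ``k1 <= k4`` or ``k3 <= k4/(1+M)``;
  rebound if ``k1 > k4`` and ``k3 > min(k4/(1+m), -lambda1/(1+h0))``;
  in between the outcome depends on the particular feedback function
  (for mainly-linear feedback ``m = M = h0`` and the gap closes into an
  iff);
* full feedback (moderator at speed eps): only rebound results are
  proved, organised by which eigenvalue is nearest zero.  The verdict
  is ``rebound`` when eps lies in the guaranteed interval for the
  relevant region and ``indeterminate`` otherwise — never
  ``no_rebound``, since no such theorem exists for eps > 0.

All strict/non-strict inequalities follow the theorem statements;
boundary ties within relative 1e-12 are resolved only where a boundary
result is proved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from math import inf, sqrt

import numpy as np
import pandas as pd

from .feedback import FeedbackFunction, SecantBounds, secant_bounds
from .spectral import eps_thresholds, lambda12

__all__ = [
    "Verdict",
    "ReboundVerdict",
    "classify_nofeedback",
    "classify_direct",
    "classify_full",
    "classify_generalized",
    "region_grid",
]

_TIE_RTOL = 1e-12


class Verdict(str, Enum):
    REBOUND = "rebound"
    NO_REBOUND = "no_rebound"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ReboundVerdict:
    verdict: Verdict
    generic: bool
    region: str
    theorem: str
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict.value,
            "generic": self.generic,
            "region": self.region,
            "theorem": self.theorem,
            "thresholds": dict(self.thresholds),
        }


def _tie(a: float, b: float) -> bool:
    return abs(a - b) <= _TIE_RTOL * max(abs(a), abs(b), 1e-300)


def classify_nofeedback(k1: float, k3: float, k4: float) -> ReboundVerdict:
    """Elimination-rate criterion for the basic TMDD model.

    Rebound iff the complex is eliminated more slowly than both the
    ligand and the receptor; the iff is strict, so boundary equalities
    are no-rebound.
    """
    thr = {"k1": k1, "k3": k3, "k4": k4}
    if k4 < k1 and k4 < k3:
        return ReboundVerdict(Verdict.REBOUND, True, "k4<k1 and k4<k3",
                              "no-feedback iff", thr)
    return ReboundVerdict(Verdict.NO_REBOUND, True, "k4>=k1 or k4>=k3",
                          "no-feedback iff", thr)


def classify_direct(k1: float, k2: float, k3: float, k4: float,
                    bounds: SecantBounds) -> ReboundVerdict:
    """Direct-feedback (quasi-equilibrium) classifier.

    Uses the secant bounds m <= h0 <= M of the feedback function.  When
    ``m == M`` (mainly-linear) the indeterminate band is empty and the
    result is an iff.
    """
    m, M, h0 = bounds.m, bounds.M, bounds.h0
    lam1, _ = lambda12(k1, k2, k4)
    lo = k4 / (1.0 + M)
    hi = min(k4 / (1.0 + m), -lam1 / (1.0 + h0))
    thr = {"lambda1": lam1, "k4_over_1M": lo, "k4_over_1m": k4 / (1.0 + m),
           "neg_lambda1_over_1h0": -lam1 / (1.0 + h0)}

    if k1 <= k4:
        return ReboundVerdict(Verdict.NO_REBOUND, True, "k1<=k4",
                              "direct-feedback no-rebound", thr)
    if k3 > hi or (_tie(k3, -lam1 / (1.0 + h0)) and k3 > k4 / (1.0 + m)):
        # boundary line lambda1 = lambda3 with k3 > k4/(1+m) is proved rebound
        return ReboundVerdict(Verdict.REBOUND, True,
                              "k1>k4 and k3>min(k4/(1+m), -lambda1/(1+h0))",
                              "direct-feedback rebound", thr)
    if k3 <= lo:
        return ReboundVerdict(Verdict.NO_REBOUND, True, "k1>k4 and k3<=k4/(1+M)",
                              "direct-feedback no-rebound", thr)
    return ReboundVerdict(Verdict.INDETERMINATE, False,
                          "k4/(1+M)<k3<=min(k4/(1+m), -lambda1/(1+h0))",
                          "direct-feedback gap (feedback-function dependent)", thr)


def classify_full(k1: float, k2: float, k3: float, k4: float,
                  h0: float, m: float, eps: float) -> ReboundVerdict:
    """Full-model (moderator) classifier, by eigenvalue-ordering region.

    Determines the row from the position of lambda1 relative to
    lambda*-, lambda_inf, lambda*+ of the receptor–moderator block and
    the column from k1 vs k4, then tests whether eps falls inside the
    guaranteed-rebound interval for that cell.  Outside those intervals
    the verdict is indeterminate (no no-rebound results are proved for
    eps > 0).
    """
    if not eps > 0:
        raise ValueError("classify_full requires eps > 0; use "
                         "classify_nofeedback for eps = 0")
    lam1, _ = lambda12(k1, k2, k4)
    t = eps_thresholds(k3, h0, lam1)
    slow = k1 <= k4  # "slow ligand" column of the summary table
    thr = {"lambda1": lam1, "lambda_star_minus": t.lambda_star_minus,
           "lambda_star_plus": t.lambda_star_plus, "lambda_inf": t.lambda_inf,
           "eps1_minus": t.eps1_minus, "eps1_plus": t.eps1_plus,
           "eps2": t.eps2, "eps3": t.eps3, "eps": eps,
           "k4_over_1m": k4 / (1.0 + m)}

    def verdict(is_rebound: bool, region: str, bound_desc: str) -> ReboundVerdict:
        col = "k1<=k4" if slow else "k1>k4"
        label = f"row: {region}; col: {col}"
        if is_rebound:
            return ReboundVerdict(Verdict.REBOUND, True, label,
                                  f"full-model rebound ({bound_desc})", thr)
        return ReboundVerdict(Verdict.INDETERMINATE, False, label,
                              f"full-model unproved ({bound_desc})", thr)

    eps2 = t.eps2_or_inf

    if t.lambda_star_minus <= lam1:                    # row 1
        if not slow:
            return verdict(True, "lambda*-<=lambda1<0", "all eps>0")
        return verdict(eps < -lam1, "lambda*-<=lambda1<0", "0<eps<-lambda1")

    if t.lambda_inf <= lam1:                           # row 2
        if not slow:
            return verdict(True, "lambda_inf<=lambda1<=lambda*-", "all eps>0")
        bound = t.eps3
        if lam1 > -k3:
            bound = max(bound, -lam1)
        return verdict(eps < bound, "lambda_inf<=lambda1<=lambda*-",
                       "0<eps<max(eps3, -lambda1 if lambda1>-k3)")

    if t.lambda_star_plus <= lam1:                     # row 3
        if slow:
            return verdict(eps < t.eps3, "lambda*+<=lambda1<lambda_inf",
                           "0<eps<eps3")
        if k3 > k4 / (1.0 + m):
            return verdict(True, "lambda*+<=lambda1<lambda_inf",
                           "all eps>0 (k3>k4/(1+m))")
        reb = eps < eps2 or _tie(eps, eps2)  # boundary eps=eps2 proved
        return verdict(reb, "lambda*+<=lambda1<lambda_inf", "0<eps<=eps2")

    # row 4: lambda1 < lambda*+
    if k3 > k4 / (1.0 + m):
        return verdict(True, "lambda1<lambda*+", "all eps>0 (k3>k4/(1+m))")
    return verdict(eps < t.eps1_plus, "lambda1<lambda*+", "0<eps<eps1+")


def _lambda_n(k3: float, g1: float, g2: float, eps: float) -> complex:
    """Leading (nearest-zero) eigenvalue of [[-k3, k3], [-eps g1, -eps g2]]."""
    tr = -(k3 + eps * g2)
    D = tr * tr - 4.0 * eps * k3 * (g1 + g2)
    if D >= 0.0:
        return 0.5 * (tr + sqrt(D))
    return complex(0.5 * tr, 0.5 * sqrt(-D))


def classify_generalized(lead_pk_eig: float, k3: float,
                         g: float | tuple[float, float],
                         eps: float) -> ReboundVerdict:
    """Slow-feedback rebound criterion for generalised models.

    Covers multi-compartment PK blocks (leading eigenvalue
    ``lead_pk_eig`` < 0, on the same dimensionless time scale) and
    general moderator dynamics ``wdot = eps*g(y, w)`` with local slopes
    ``g1 = -dg/dy``, ``g2 = -dg/dw`` at baseline (the linear moderator
    is ``g = (h0, 1)``).  Rebound is guaranteed generically for
    ``0 < eps < eps0 = min(eps1-, eps2~)`` where ``eps2~`` is the speed
    at which the moderator-block leading eigenvalue crosses
    ``lead_pk_eig``; outside that interval the verdict is indeterminate.
    """
    if isinstance(g, (int, float)):
        g1, g2 = float(g), 1.0
    else:
        g1, g2 = map(float, g)
    if g2 <= 0:
        raise ValueError(f"moderator self-relaxation slope g2 must be > 0, got {g2}")
    if g1 <= 0:
        raise ValueError(f"feedback slope g1 must be > 0, got {g1}")
    if not lead_pk_eig < 0:
        raise ValueError("leading PK-block eigenvalue must be strictly negative")
    if not eps > 0:
        raise ValueError("eps must be > 0")

    eps1_minus = k3 / g2 ** 2 * (2.0 * g1 + g2 - sqrt(4.0 * g1 * (g1 + g2)))
    lam = lead_pk_eig
    denom = g2 * lam + k3 * (g1 + g2)
    eps2t = inf
    if denom > 0:
        cand = -lam * (lam + k3) / denom
        # crossing is valid only if lam is actually the nearest-zero
        # eigenvalue of the moderator block at that speed
        if cand > 0 and np.isfinite(cand):
            ln = _lambda_n(k3, g1, g2, cand)
            if isinstance(ln, float) or ln.imag == 0.0:
                if abs(complex(ln).real - lam) <= 1e-9 * max(abs(lam), 1.0):
                    eps2t = cand
    eps0 = min(eps1_minus, eps2t)
    thr = {"eps1_minus": eps1_minus, "eps2_tilde": eps2t, "eps0": eps0,
           "lead_pk_eig": lam, "eps": eps, "g1": g1, "g2": g2}
    if eps < eps0:
        return ReboundVerdict(Verdict.REBOUND, True, "0<eps<eps0",
                              "generalised slow-feedback rebound", thr)
    return ReboundVerdict(Verdict.INDETERMINATE, False, "eps>=eps0",
                          "generalised model, unproved region", thr)


def region_grid(keL_range, kout_range, keP: float, kon: float, R0: float,
                koff: float, L0: float,
                feedback: FeedbackFunction | None = None,
                eps: float | None = None,
                model: str = "nofeedback",
                n: int = 50) -> tuple[pd.DataFrame, dict]:
    """Classify a grid of the (keL, kout) elimination plane.

    Returns a long-format DataFrame (keL, kout, verdict, region,
    generic) and a metadata dict with the theorem boundary lines for
    overlay plotting.
    """
    keLs = np.linspace(*keL_range, n)
    kouts = np.linspace(*kout_range, n)
    s = kon * R0
    k2 = koff / s
    k4 = keP / s
    mu = R0 / L0

    if model != "nofeedback":
        if feedback is None:
            raise ValueError(f"model={model!r} requires a feedback function")
        b = secant_bounds(feedback)
    rows = []
    for keL in keLs:
        k1 = keL / s
        for kout in kouts:
            k3 = kout / s
            if model == "nofeedback":
                v = classify_nofeedback(k1, k3, k4)
            elif model == "direct":
                v = classify_direct(k1, k2, k3, k4, b)
            elif model == "full":
                if eps is None or not eps > 0:
                    raise ValueError("full-model grid requires eps > 0")
                v = classify_full(k1, k2, k3, k4, b.h0, b.m, eps)
            else:
                raise ValueError(f"unknown model {model!r}")
            rows.append((keL, kout, v.verdict.value, v.region, v.generic))
    df = pd.DataFrame(rows, columns=["keL", "kout", "verdict", "region", "generic"])

    meta = {"keL_eq_keP": keP, "kout_eq_keP": keP}
    if model != "nofeedback":
        meta.update({
            "kout_eq_keP_over_1h0": keP / (1.0 + b.h0),
            "kout_eq_keP_over_1M": keP / (1.0 + b.M),
            "kout_eq_keP_over_1m": keP / (1.0 + b.m),
        })
    return df, meta
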