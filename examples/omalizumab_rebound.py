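"""Omalizumab (anti-IgE): no rebound without feedback, rebound with a
slow feedback moderator.

Builds the packaged omalizumab parameter set, classifies it with the
eigenvalue criteria, then verifies both verdicts by stiff simulation.
"""

import tmdd_rebound as tr
from tmdd_rebound.feedback import secant_bounds
from tmdd_rebound.rebound import classify_direct, classify_full, classify_nofeedback
from tmdd_rebound.simulate import detect_rebound, integrate
from tmdd_rebound.spectral import lambda12

cfg = tr.omalizumab()
p = cfg.build_params()            # keL=0.024, keP=0.201, kout=0.823 /day ...
h = cfg.build_feedback()          # mainly-linear, dimensionless slope h0 = 2.688
q = tr.nondimensionalize(p)
lam1, _ = lambda12(q.k1, q.k2, q.k4)

print(f"dimensionless groups: k1={q.k1:.5f} k2={q.k2:.5f} "
      f"k3={q.k3:.5f} k4={q.k4:.5f} mu={q.mu:.5f}")
print(f"ligand-complex leading eigenvalue lambda1 = {lam1:.4f}")

print("no feedback:     ", classify_nofeedback(q.k1, q.k3, q.k4).verdict.value)
print("direct feedback: ",
      classify_direct(q.k1, q.k2, q.k3, q.k4, secant_bounds(h)).verdict.value)
v = classify_full(q.k1, q.k2, q.k3, q.k4, h.h0, secant_bounds(h).m, q.eps)
print(f"moderator, alpha={p.alpha}/day: {v.verdict.value}  ({v.region})")
print(f"rebound guaranteed for alpha < {-lam1 / 0.625:.3f}/day "
      "(slow-feedback bound eps < -lambda1)")

# verify by simulation: keL < keP means no rebound without feedback,
# but the slow moderator overshoots
r0 = detect_rebound(integrate("basic", tr.nondimensionalize(p.with_alpha(0.0))))
r1 = detect_rebound(integrate("full", q, h, time_scale=p.time_scale))
print(f"simulated, no feedback: rebound={r0.rebound}")
print(f"simulated, alpha=0.1:   rebound={r1.rebound}, "
      f"Rmax/R0={r1.rmax_over_r0:.4f} at t={r1.tmax_days:.1f} days")
# Rmax/R0 > 1 is the receptor overshoot relative to its pre-dose baseline
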