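# Methods

## Models

Three nested variants of the one-compartment TMDD model are
implemented, all sharing the binding scheme L + R ⇌ P with first-order
eliminations ke(L), ke(P), receptor turnover kin/kout and a bolus dose
L0 into an initially drug-free steady state R0 = kin/kout:

1. **basic** — constant synthesis (no feedback);
2. **direct** — synthesis multiplied by H(R), the quasi-equilibrium
   (α → ∞) limit of the moderator;
3. **full** — synthesis multiplied by a moderator F with
   dF/dt = α(H(R) − F), F(0) = 1.

All analysis and integration happen in dimensionless variables
(x, z, y, w; τ = kon·R0·t) with groups μ = R0/L0,
k1 = ke(L)/(kon R0), k2 = koff/(kon R0), k3 = kout/(kon R0),
k4 = ke(P)/(kon R0), ε = α/(kon R0).  The state order (x, z, y, w) is
fixed throughout so the baseline Jacobian is block lower-triangular in
the (x, z)/(y, w) split; the ligand–complex block carries λ1, λ2 and
the receptor–moderator block carries λ3, λ4.  Dimensional runs convert
in, integrate, and convert back — this conditions the problem uniformly
and reuses one code path.

**Rebound** means: after the post-dose suppression, the free receptor
y rises above its baseline 1 on the way back to steady state.
"Generic" verdicts assume the trajectory approaches the (globally
attracting) baseline tangent to the eigenvector of the eigenvalue with
real part nearest zero; the exceptional trajectories form a
measure-zero set that is not enumerated.

The five-state efalizumab/%CD11a model keeps its published dimensional
form (amounts per kg body weight; µg/kg for drug, %CD11a for receptor;
days).  Its (X3, X4) block reduces exactly to the receptor–moderator
subsystem with k3 = k30/Vm2, ε = koff/Vm2 and hyperbolic feedback
h(y) = 1/(F0 + (1−F0)y), so the generalised classifier applies with
the drug PK block supplying the competing spectrum.

## Feedback functions

Negative feedback requires h > 0, h(1) = 1, h > 1 below baseline,
0 < h < 1 above it, and C² smoothness.  Three families are packaged:

- **constant** h ≡ 1 — the declared no-feedback case (h0 = m = M = 0);
- **mainly linear** 1 + h0(1−y) up to the kink y = 1 + β/h0, continued
  by the tail (1−β) − h0·σ·tanh(s/σ) with σ = (1−β)/(2h0).  The tail
  matches value, slope −h0 and zero curvature at the junction, is C∞,
  and stays inside ((1−β)/2, 1−β] ⊂ (0, 1) — the simplest closed form
  satisfying every matching condition.  Only the junction conditions
  are theory-constrained; the tail shape never affects rebound
  verdicts because the relevant dynamics live in y ≤ 1 + β/h0.
- **hyperbolic** 1/(F0 + (1−F0)y), the form induced by Michaelis-type
  moderator production; h0 = 1 − F0.

The secant bounds m = inf, M = sup of (h(y)−1)/(1−y) over [0, 1) pinch
h between two straight lines through (1, 1) and satisfy
0 ≤ m ≤ h0 ≤ M.  Closed forms are used for the packaged families
(mainly-linear: m = M = h0; hyperbolic: m = 1−F0, M = (1−F0)/F0);
custom functions fall back to a 2048-point grid on the half-open
interval with local refinement, with the y → 1 limit h0 injected
explicitly.  h(1) = 1 is enforced to 1e−12; the sign conditions are
checked strictly except at y = 1.  Non-monotone h is admissible in
principle; only monotone families are packaged and custom callables
are the escape hatch.

## Classification logic

- **No feedback:** rebound iff k4 < k1 and k4 < k3 (strict; boundary
  equalities are no-rebound).
- **Direct feedback:** no rebound if k1 ≤ k4, or if k1 > k4 and
  k3 ≤ k4/(1+M); rebound if k1 > k4 and
  k3 > min(k4/(1+m), −λ1/(1+h0)), including the collision line
  k3 = −λ1/(1+h0) when k3 > k4/(1+m).  Between the bounds the outcome
  depends on the particular h and the verdict is `indeterminate`.  For
  mainly-linear feedback m = M = h0 closes the gap into an iff with
  boundary kout = ke(P)/(1 + R0·H0).
- **Full model:** the verdict is organised by where λ1 sits relative
  to the moderator-block landmarks λ*− , λ∞, λ*+ (four rows) and
  whether k1 ≤ k4 (two columns).  Each cell has a proved
  guaranteed-rebound ε-interval (e.g. 0 < ε < −λ1 in the top row with
  k1 ≤ k4; all ε > 0 whenever k1 > k4 in the upper rows, or when
  k3 > k4/(1+m) in the lower rows).  Inside the interval the verdict
  is `rebound` (generic); outside it is `indeterminate` — **never**
  `no_rebound`, because no non-existence results are proved for
  ε > 0.  Degenerate eigenvalue collisions (ε = ε1±, λ1 = λ4) are
  detected with relative tolerance 1e−9 and resolved by the proved
  boundary cases; the ε2 pole at λ1 = λ∞ is treated as +∞ for
  classification and reported as undefined.
- **Generalised models:** for a PK block with leading eigenvalue
  λ_pk < 0 and moderator dynamics ẇ = εg(y, w) with local slopes
  g1, g2 > 0, rebound is generic for 0 < ε < min(ε1−, ε̃2), where ε1−
  is the first collision speed of the moderator block and ε̃2 the
  speed at which its leading eigenvalue crosses λ_pk (closed form,
  validated as an actual crossing of the near-zero branch, else +∞).

## Numerics

- **Integration:** `scipy.integrate.solve_ivp` with Radau, analytic
  Jacobians, rtol 1e−10 / atol 1e−12 (1e−10 for the psoriasis model,
  whose states reach 3000 µg/kg).  The default horizon policy
  integrates in doubling chunks until the state is within 1e−10 (sup
  norm) of the attracting baseline or τ = 1e7 — tails near degenerate
  eigenvalues are slow, and rebound shrinks exponentially along them.
- **Detection:** rebound is declared when y, after first dropping
  below 1 − δ, later exceeds 1 + δ, with δ = 1e−6 by default.  The
  magnitude of rebound tends to 0 as ε → 0, so a threshold is
  unavoidable; δ is surfaced in every result.  The post-nadir maximum
  is refined on the dense interpolant.  Trajectories that never dip
  are flagged degenerate rather than classified.
- **α-scan endpoint:** a 16-point log-spaced pre-scan brackets the
  last rebound→no-rebound transition, refined by bisection to 1e−3
  absolute.  The endpoint moves by < 5e−3 when δ changes from 1e−6 to
  1e−7 on the omalizumab fixture.
- **Oracles:** every closed-form eigenvalue/eigenvector is tested
  against a dense `numpy.linalg.eig` decomposition of the literal
  Jacobians on randomised parameter sweeps, and the classifiers are
  tested for concordance against simulation on parameter grids (8×8
  per model variant in the suite, chosen away from theorem boundaries
  where the rebound magnitude vanishes below any detection threshold).

## Fixtures and chosen constants

- Omalizumab: ke(L) = 0.024, ke(P) = 0.201, kout = 0.823, koff = 0.9
  /day, kon = 0.592 /(nM·day), R0 = 2.688 nM (so kin = 2.212224
  nM/day), L0 = 14.8148 nM; mainly-linear feedback with dimensional
  slope H0 = 1/nM (dimensionless h0 = R0·H0 = 2.688), β = 0.5, default
  α = 0.1/day.  The guaranteed-rebound bound on α is quoted with the
  example's rounded conversion ε = 0.625·α (exact kon·R0 = 1.591296).
- Psoriasis: the published Ng et al. parameter set with koff =
  0.0154/day by default — the value required to reproduce the reported
  rebound magnitude; the originally reported 0.00154/day ships as a
  named alternative fixture and peaks near 110% of baseline.  `Kmc03`
  is not part of the published list; it is back-solved (≈ 15.33
  %CD11a) from the normalisation that baseline total %CD11a is
  Y0 = 100, the natural choice for a percentage variable and the one
  that reproduces the reduced-model spectrum.  Y0 is an explicit,
  overridable parameter.  Default dose-study horizon is 150 days,
  comfortably past the ~50-day rebound peak set by the ≈0.03/day
  leading eigenvalue.  The published affinity (0.033 µg/mL ≈ 200 pM)
  is inconsistent with koff/kon ≈ 2 pM at a typical kon; this is a
  documented data discrepancy with no computational resolution here.

## Limitations

- The full-model classifier is deliberately one-sided: `indeterminate`
  outside the proved ε-intervals can be resolved empirically by
  simulation, not by theorem.
- No rebound-magnitude theory exists; magnitudes come from simulation
  only, relative to the detection threshold δ.
- Single bolus dosing only; no absorption compartment for the core
  TMDD model (the psoriasis model has its own depot), no
  inter-individual variability, no fitting of H(R) to data, no delayed
  or non-autonomous feedback.
- The elimination-plane grids classify cell centres; the indeterminate
  band boundaries between the proved regions vary with the feedback
  function and are emitted as overlay metadata, not resolved per cell.
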