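"""Rebound classifiers: theorem logic, region grids, and concordance
with direct simulation."""

import itertools

import numpy as np
import pytest

from tmdd_rebound.feedback import (
    SecantBounds,
    make_constant,
    make_hyperbolic,
    make_mainly_linear,
    secant_bounds,
)
from tmdd_rebound.model_core import DimensionlessParams
from tmdd_rebound.rebound import (
    Verdict,
    classify_direct,
    classify_full,
    classify_generalized,
    classify_nofeedback,
    region_grid,
)
from tmdd_rebound.simulate import detect_rebound, integrate
from tmdd_rebound.spectral import lambda12

OMA = dict(k1=0.015082046332046331, k2=0.5655767374517374,
           k3=0.5171885054697555, k4=0.12631213803088803)


class TestNoFeedback:
    def test_omalizumab_no_rebound(self):
        v = classify_nofeedback(OMA["k1"], OMA["k3"], OMA["k4"])
        assert v.verdict is Verdict.NO_REBOUND

    def test_slow_complex_elimination_rebounds(self):
        v = classify_nofeedback(0.2, 0.3, 0.1)
        assert v.verdict is Verdict.REBOUND

    def test_boundary_equality_is_no_rebound(self):
        # the iff is strict
        assert classify_nofeedback(0.1, 0.3, 0.1).verdict is Verdict.NO_REBOUND
        assert classify_nofeedback(0.3, 0.1, 0.1).verdict is Verdict.NO_REBOUND


class TestDirect:
    def test_omalizumab_no_rebound_for_any_feedback(self):
        # k1 <= k4 settles it regardless of the feedback function
        for h in (make_mainly_linear(2.688, 0.5), make_hyperbolic(0.2),
                  make_constant()):
            v = classify_direct(OMA["k1"], OMA["k2"], OMA["k3"], OMA["k4"],
                                secant_bounds(h))
            assert v.verdict is Verdict.NO_REBOUND

    def test_mainly_linear_iff_has_no_gap(self):
        """With m = M = h0 the feedback widens the rebound region to
        k4 < k3 (1+h0) and the indeterminate band is empty."""
        b = secant_bounds(make_mainly_linear(1.0, 0.5))
        for k3 in np.linspace(0.02, 1.0, 40):
            v = classify_direct(0.8, 0.5, k3, 0.3, b)
            expect = Verdict.REBOUND if 0.3 < k3 * 2.0 else Verdict.NO_REBOUND
            assert v.verdict is expect, k3

    def test_nonlinear_gap_is_indeterminate(self):
        # k4/(1+M) < k3 < min(k4/(1+m), -lambda1/(1+h0)) -> white region
        b = SecantBounds(m=0.5, M=6.0, h0=0.8)
        k1, k2, k4 = 0.5, 0.1, 0.2
        lam1, _ = lambda12(k1, k2, k4)
        k3 = 0.05
        assert k4 / 7.0 < k3 < min(k4 / 1.5, -lam1 / 1.8)
        v = classify_direct(k1, k2, k3, k4, b)
        assert v.verdict is Verdict.INDETERMINATE
        assert not v.generic

    def test_deep_green_region(self):
        b = SecantBounds(m=0.5, M=6.0, h0=0.8)
        v = classify_direct(0.5, 0.1, 0.02, 0.2, b)  # k3 <= k4/(1+M)
        assert v.verdict is Verdict.NO_REBOUND

    def test_threshold_ordering(self):
        """0 < k4/(1+M) <= k4/(1+h0) <= k4/(1+m) <= k4 for real families."""
        for F0 in (0.1, 0.3, 0.7, 0.9):
            b = secant_bounds(make_hyperbolic(F0))
            k4 = 0.37
            vals = [k4 / (1 + b.M), k4 / (1 + b.h0), k4 / (1 + b.m), k4]
            assert vals[0] > 0
            assert all(a <= b_ + 1e-15 for a, b_ in zip(vals, vals[1:]))


class TestFull:
    def test_omalizumab_slow_feedback_rebound_window(self):
        """Row lambda*- <= lambda1 < 0 with k1 <= k4: rebound iff eps < -lambda1,
        i.e. alpha below about 0.135 with the printed rounded conversion."""
        lam1, _ = lambda12(OMA["k1"], OMA["k2"], OMA["k4"])
        h0 = m = 2.688
        for eps, expect in ((0.9 * -lam1, Verdict.REBOUND),
                            (1.1 * -lam1, Verdict.INDETERMINATE)):
            v = classify_full(OMA["k1"], OMA["k2"], OMA["k3"], OMA["k4"],
                              h0, m, eps)
            assert v.verdict is expect
        assert (-lam1) / 0.625 == pytest.approx(0.135, abs=1e-3)

    def test_fast_ligand_large_k3_rebounds_for_all_eps(self):
        # k1 > k4 and k3 > min(-lambda1/(1+h0), k4/(1+m)): any eps
        k1, k2, k3, k4 = 1.0, 0.5, 1.0, 0.2
        for eps in (1e-4, 0.1, 10.0, 1e4):
            v = classify_full(k1, k2, k3, k4, 1.0, 1.0, eps)
            assert v.verdict is Verdict.REBOUND

    def test_fast_feedback_small_k3_unproved(self):
        """Bottom row, k1 <= k4, eps above eps1+, k3 <= k4/(1+m): the
        theorems guarantee nothing there."""
        k1, k2, k4 = 0.05, 0.5, 1.5
        h0 = m = 4.0
        lam1, _ = lambda12(k1, k2, k4)
        k3 = 0.02
        from tmdd_rebound.spectral import eps_thresholds
        t = eps_thresholds(k3, h0, lam1)
        assert lam1 < t.lambda_star_plus and k3 <= k4 / (1 + m)
        v = classify_full(k1, k2, k3, k4, h0, m, 1.5 * t.eps1_plus)
        assert v.verdict is Verdict.INDETERMINATE
        v = classify_full(k1, k2, k3, k4, h0, m, 0.5 * t.eps1_plus)
        assert v.verdict is Verdict.REBOUND

    def test_never_returns_no_rebound(self, rng):
        for _ in range(200):
            k1, k2, k3, k4 = 10.0 ** rng.uniform(-2, 2, size=4)
            h0 = 10.0 ** rng.uniform(-2, 1)
            m = h0 * rng.uniform(0.2, 1.0)
            eps = 10.0 ** rng.uniform(-4, 3)
            v = classify_full(k1, k2, k3, k4, h0, m, eps)
            assert v.verdict is not Verdict.NO_REBOUND

    def test_sufficiently_slow_feedback_always_rebounds(self, rng):
        for _ in range(100):
            k1, k2, k3, k4 = 10.0 ** rng.uniform(-1.5, 1.5, size=4)
            h0 = 10.0 ** rng.uniform(-1.5, 1)
            v = classify_full(k1, k2, k3, k4, h0, h0, 1e-9 * k3)
            assert v.verdict is Verdict.REBOUND

    def test_eps_zero_rejected(self):
        with pytest.raises(ValueError):
            classify_full(0.5, 0.5, 0.5, 0.3, 1.0, 1.0, 0.0)


class TestGeneralized:
    def test_linear_moderator_reduces_to_standard_threshold(self):
        from tmdd_rebound.spectral import eps_thresholds
        k3, h0 = 0.3, 1.2
        v = classify_generalized(-0.05, k3, (h0, 1.0), 1e-4)
        assert v.thresholds["eps1_minus"] == pytest.approx(
            eps_thresholds(k3, h0).eps1_minus, rel=1e-12)

    def test_unit_slopes_threshold_value(self):
        v = classify_generalized(-0.05, 1.0, (1.0, 1.0), 1e-3)
        assert v.thresholds["eps1_minus"] == pytest.approx(3 - np.sqrt(8), rel=1e-12)

    def test_verdict_switches_at_eps0(self):
        v = classify_generalized(-0.05, 0.3, (1.2, 1.0), 1e-3)
        assert v.verdict is Verdict.REBOUND
        eps0 = v.thresholds["eps0"]
        v2 = classify_generalized(-0.05, 0.3, (1.2, 1.0), 1.01 * eps0)
        assert v2.verdict is Verdict.INDETERMINATE

    def test_assumption_violations_raise(self):
        with pytest.raises(ValueError):
            classify_generalized(-0.05, 0.3, (1.0, -1.0), 1e-3)
        with pytest.raises(ValueError):
            classify_generalized(0.05, 0.3, (1.0, 1.0), 1e-3)


class TestNesting:
    def test_rebound_regions_nest_across_models(self, rng):
        """no-feedback rebound ⊂ direct-feedback rebound ⊂ small-eps full
        rebound, for mainly-linear feedback."""
        b = secant_bounds(make_mainly_linear(1.0, 0.5))
        for _ in range(150):
            k1, k2, k3, k4 = 10.0 ** rng.uniform(-1.5, 1.5, size=4)
            v0 = classify_nofeedback(k1, k3, k4)
            vd = classify_direct(k1, k2, k3, k4, b)
            vf = classify_full(k1, k2, k3, k4, b.h0, b.m, 1e-9 * k3)
            if v0.verdict is Verdict.REBOUND:
                assert vd.verdict is Verdict.REBOUND
            if vd.verdict is Verdict.REBOUND:
                assert vf.verdict is Verdict.REBOUND


class TestRegionGrid:
    FIXED = dict(keP=0.201, kon=0.592, R0=2.688, koff=0.9, L0=14.8148)

    def test_no_feedback_quadrants(self):
        df, meta = region_grid((0.05, 0.6), (0.05, 0.6), model="nofeedback",
                               n=12, **self.FIXED)
        keP = self.FIXED["keP"]
        for row in df.itertuples():
            expect = "rebound" if (keP < row.keL and keP < row.kout) else "no_rebound"
            assert row.verdict == expect
        assert meta["keL_eq_keP"] == keP

    def test_mainly_linear_boundary_drops(self):
        """Direct feedback lowers the rebound boundary to
        kout = keP/(1 + R0*H0)."""
        h = make_mainly_linear(2.688, 0.5)  # H0 = 1/nM, R0*H0 = 2.688
        df, meta = region_grid((0.25, 0.6), (0.02, 0.6), model="direct",
                               feedback=h, n=12, **self.FIXED)
        keP = self.FIXED["keP"]
        thr = keP / (1.0 + 2.688)
        assert meta["kout_eq_keP_over_1h0"] == pytest.approx(thr)
        sub = df[df.keL > keP]
        for row in sub.itertuples():
            expect = "rebound" if row.kout > thr else "no_rebound"
            assert row.verdict == expect

    def test_boundary_decreasing_in_feedback_strength(self):
        keP = self.FIXED["keP"]
        thresholds = [keP / (1.0 + 2.688 * H0) for H0 in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(thresholds, thresholds[1:]))

    def test_full_model_small_eps_rebounds_everywhere(self):
        h = make_mainly_linear(2.688, 0.5)
        df, _ = region_grid((0.05, 0.6), (0.05, 0.6), model="full",
                            feedback=h, eps=1e-6, n=8, **self.FIXED)
        assert (df.verdict == "rebound").all()


class TestConcordance:
    """Wherever a classifier commits to rebound/no-rebound, stiff
    simulation of the corresponding model must agree (indeterminate
    cells are exempt)."""

    K1S = [0.07, 0.2, 0.7, 1.6]
    K3S = [0.05, 0.2, 0.7, 1.6]
    K2, K4, MU = 0.5, 0.3, 0.2
    DELTA = 1e-7

    @pytest.mark.parametrize("model", ["basic", "direct", "full"])
    def test_grid(self, model):
        h = make_mainly_linear(1.0, 0.5)
        b = secant_bounds(h)
        for k1, k3 in itertools.product(self.K1S, self.K3S):
            eps = 0.02 if model == "full" else 0.0
            q = DimensionlessParams(mu=self.MU, k1=k1, k2=self.K2, k3=k3,
                                    k4=self.K4, eps=eps)
            if model == "basic":
                v = classify_nofeedback(k1, k3, self.K4)
            elif model == "direct":
                v = classify_direct(k1, self.K2, k3, self.K4, b)
            else:
                v = classify_full(k1, self.K2, k3, self.K4, b.h0, b.m, eps)
            if v.verdict is Verdict.INDETERMINATE:
                continue
            hh = make_constant() if model == "basic" else h
            traj = integrate(model, q, hh)
            r = detect_rebound(traj, self.DELTA)
            assert r.rebound == (v.verdict is Verdict.REBOUND), (
                f"{model} k1={k1} k3={k3}: classifier {v.verdict.value} "
                f"({v.region}), simulated rmax={r.rmax_over_r0:.8f}")
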