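"""Analytic fixed points, fold/Hopf/TB geometry, and brute-force fold oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from epimap.bifurcations import (
    cubic_real_roots,
    fixed_points,
    hopf_curve,
    jacobian_fast,
    local_region_config,
    negative_branch_hopf_candidates,
    on_curve,
    sn_curves,
    tb_point,
)
from epimap.models import FastParams

GOLDEN = (1.0 + math.sqrt(5.0)) / 2.0


class TestCubicSolver:
    @given(st.lists(st.floats(min_value=-3.0, max_value=3.0), min_size=3, max_size=3))
    def test_roots_from_factored_form(self, roots):
        """Reconstructing a cubic from known roots recovers them."""
        r1, r2, r3 = sorted(roots)
        c2 = -(r1 + r2 + r3)
        c1 = r1 * r2 + r1 * r3 + r2 * r3
        c0 = -r1 * r2 * r3
        got = cubic_real_roots(1.0, c2, c1, c0)
        # all true roots must be matched by some computed root
        for r in (r1, r2, r3):
            assert min(abs(g - r) for g in got) < 1e-6


class TestFixedPoints:
    def test_default_origin_cell(self, default_fast):
        """At (mu, mbar) = (0, 0): roots -phi, -1 and 1/sqrt(5)."""
        pts = fixed_points(default_fast)
        xs = [p.x for p in pts]
        assert xs == pytest.approx([-GOLDEN, -1.0, 1.0 / math.sqrt(5.0)], abs=1e-12)
        assert [p.stability for p in pts] == [
            "stable-node", "saddle", "stable-focus"]
        for p in pts:
            assert p.y == pytest.approx(-(1.0 - 5.0 * p.x ** 2) / -1.0)

    def test_branch_merge_at_boundary(self, default_fast):
        """mu = nu*y0/N puts a root exactly at the seam x = 0."""
        fp = default_fast.replace(mu=-1.0, mbar=-0.5)
        pts = fixed_points(fp)
        boundary = [p for p in pts if p.branch == "boundary"]
        assert len(boundary) == 1
        assert boundary[0].stability == "non-hyperbolic"

    def test_single_upper_fixed_point_for_large_mu(self, default_fast):
        pts = fixed_points(default_fast.replace(mu=1.0, mbar=2.0))
        assert len(pts) == 1
        assert pts[0].branch == "positive"
        assert pts[0].stability.startswith("unstable")

    def test_degenerate_leading_coefficient_rejected(self):
        with pytest.raises(ValueError):
            FastParams(a=0.0)


class TestJacobian:
    def test_seam_right_limit(self, default_fast):
        J = jacobian_fast(default_fast.replace(mbar=0.7), 0.0)
        np.testing.assert_allclose(J, [[0.7, 1.0], [0.0, -1.0]])
        assert np.linalg.det(J) == pytest.approx(-0.7)

    @given(x=st.floats(min_value=-3.0, max_value=-1e-6))
    def test_negative_branch_det_factorisation(self, x):
        """det J = x * (3aN x + 2N(b - nu*B/N)) on the cubic branch."""
        fp = FastParams()
        J = jacobian_fast(fp, x)
        det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        expected = x * (3 * fp.a * fp.N * x + 2 * fp.N * (fp.b - fp.nu * fp.B / fp.N))
        assert det == pytest.approx(expected, rel=1e-12)

    def test_det_vanishes_on_folds(self, default_fast):
        """At the fold x given by the SN conditions, det J = 0 exactly."""
        fp = default_fast
        x_minus = -2.0 * (fp.b - fp.nu * fp.B / fp.N) / (3.0 * fp.a)
        J = jacobian_fast(fp, x_minus)
        assert J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0] == pytest.approx(0.0, abs=1e-10)
        for mbar in (0.5, 1.0, 2.0):
            x_plus = mbar * fp.N / (2.0 * fp.nu * fp.B)
            J = jacobian_fast(fp.replace(mbar=mbar), x_plus)
            assert J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0] == pytest.approx(0.0, abs=1e-10)


class TestSNCurves:
    def test_default_values(self, default_fast):
        sn = sn_curves(default_fast)
        assert sn.sn_minus == pytest.approx(5.0 / 27.0, abs=1e-12)
        assert sn.sn_zero == pytest.approx(-1.0)
        assert sn.sn_plus(2.0) == pytest.approx(-1.2)

    def test_sn_zero_joins_sn_plus_at_mbar_zero(self, default_fast):
        sn = sn_curves(default_fast)
        assert sn.sn_plus(0.0) == pytest.approx(sn.sn_zero)

    def test_fold_oracle_random_parameters(self):
        """Analytic SN+ and SN- agree with brute-force fold location.

        SN+ oracle: the mu at which the quadratic-branch discriminant
        changes sign.  SN- oracle: bisection on the cubic discriminant
        (double-root condition).
        """
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 200:
            fp = FastParams(
                nu=rng.uniform(0.5, 2.0),
                a=-rng.uniform(0.5, 2.0),
                b=rng.uniform(1.0, 4.0),
                y0=rng.uniform(-2.0, 2.0),
                B=-rng.uniform(1.0, 8.0),
                N=-rng.uniform(0.5, 2.0),
                mbar=rng.uniform(0.2, 3.0),
            )
            sn = sn_curves(fp)
            # SN+ via discriminant sign change of the quadratic branch
            q = -fp.nu * fp.B / fp.N

            def disc_plus(mu):
                return fp.mbar ** 2 - 4.0 * q * (mu - fp.nu * fp.y0 / fp.N)

            mu_plus = float(sn.sn_plus(fp.mbar))
            assert disc_plus(mu_plus) == pytest.approx(0.0, abs=1e-9)
            # SN- via bisection on the cubic discriminant in mu
            c2 = fp.b - fp.nu * fp.B / fp.N

            def cubic_disc(mu):
                c0 = mu - fp.nu * fp.y0 / fp.N
                # discriminant of a x^3 + c2 x^2 + c0
                return (
                    -4.0 * c2 ** 3 * c0 - 27.0 * fp.a ** 2 * c0 ** 2
                )

            lo, hi = sn.sn_minus - 1.0, sn.sn_minus + 1.0
            if cubic_disc(lo) * cubic_disc(hi) > 0:
                continue  # bracket failed for this draw; skip
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if cubic_disc(lo) * cubic_disc(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            assert 0.5 * (lo + hi) == pytest.approx(sn.sn_minus, abs=1e-9)
            checked += 1


class TestHopfAndTB:
    def test_hopf_line_at_minus_N(self, default_fast):
        h = hopf_curve(default_fast)
        assert h.mbar == pytest.approx(1.0)
        assert h.mu_min == pytest.approx(-1.05)
        assert h.valid(-1.0) and not h.valid(-1.1)

    def test_no_negative_branch_hopf(self, default_fast):
        """Trace-zero candidates for x < 0 all fall at x >= 0."""
        cands = negative_branch_hopf_candidates(default_fast)
        assert len(cands) == 2
        assert all(c >= 0.0 for c in cands)
        np.testing.assert_allclose(sorted(cands), [0.18350, 1.81650], atol=1e-4)

    def test_hopf_eigenvalues_purely_imaginary(self, default_fast):
        """On the valid Hopf segment the eigenvalues are +-i*omega."""
        fp = default_fast.replace(mbar=1.0, mu=-0.5)
        upper = [p for p in fixed_points(fp) if p.x >= 0][-1]
        J = jacobian_fast(fp, upper.x)
        eig = np.linalg.eigvals(J)
        assert np.max(np.abs(eig.real)) <= 1e-10
        assert np.all(np.abs(eig.imag) > 0)

    def test_tb_point_defaults(self, default_fast):
        tb = tb_point(default_fast)
        assert (tb.mu, tb.mbar, tb.x) == pytest.approx((-1.05, 1.0, 0.1))

    def test_tb_trace_and_det_vanish(self, default_fast):
        tb = tb_point(default_fast)
        J = jacobian_fast(default_fast.replace(mbar=tb.mbar, mu=tb.mu), tb.x)
        assert abs(J[0, 0] + J[1, 1]) <= 1e-10
        assert abs(J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]) <= 1e-10

    def test_tb_lies_on_both_curves(self, default_fast):
        tb = tb_point(default_fast)
        sn = sn_curves(default_fast)
        h = hopf_curve(default_fast)
        assert tb.mbar == pytest.approx(h.mbar)
        assert tb.mu == pytest.approx(float(sn.sn_plus(tb.mbar)))


class TestRegionCensus:
    def test_origin_has_three_fixed_points(self, default_fast):
        cfg = local_region_config(default_fast)
        assert cfg.n_fp == 3
        assert cfg.has_stable_lc is None

    def test_single_stable_point_above_curves(self, default_fast):
        cfg = local_region_config(default_fast.replace(mu=1.0, mbar=2.0))
        assert (cfg.n_stable_fp, cfg.n_fp) == (0, 1)  # above Hopf: unstable
        cfg = local_region_config(default_fast.replace(mu=1.0, mbar=0.5))
        assert (cfg.n_stable_fp, cfg.n_fp) == (1, 1)

    def test_crossing_sn_minus_changes_count_by_two(self, default_fast):
        sn = sn_curves(default_fast)
        below = local_region_config(default_fast.replace(mu=sn.sn_minus - 0.01, mbar=-1.0))
        above = local_region_config(default_fast.replace(mu=sn.sn_minus + 0.01, mbar=-1.0))
        assert below.n_fp - above.n_fp == 2

    def test_census_inside_vs_outside_50x50(self, default_fast):
        """3 fixed points strictly inside the SN-/SN+/SN0 region, 1 outside."""
        sn = sn_curves(default_fast)
        mus = np.linspace(-2.0, 1.0, 50)
        mbars = np.linspace(-3.0, 2.0, 50)
        margin = 1e-6
        for mu in mus:
            for mbar in mbars:
                left = sn.sn_zero if mbar <= 0 else float(sn.sn_plus(mbar))
                if left + margin < mu < sn.sn_minus - margin:
                    expected = 3
                elif mu > sn.sn_minus + margin or mu < left - margin:
                    expected = 1
                else:
                    continue  # on a curve
                cfg = local_region_config(default_fast.replace(mu=mu, mbar=mbar))
                assert cfg.n_fp == expected, (mu, mbar)

    def test_on_curve_tagging(self, default_fast):
        sn = sn_curves(default_fast)
        assert on_curve(default_fast.replace(mu=sn.sn_minus, mbar=-2.0))
        assert not on_curve(default_fast.replace(mu=0.0, mbar=0.0))
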