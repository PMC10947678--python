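"""Closed-form bifurcation geometry of the piecewise fast subsystem.

The fast subsystem has fixed points on the y-nullcline
``y = -(y0 + B*x**2)/N`` wherever

* ``a*x**3 + (b - nu*B/N)*x**2 + (mu - nu*y0/N) = 0`` with ``x < 0``, or
* ``-(nu*B/N)*x**2 + mbar*x + (mu - nu*y0/N) = 0`` with ``x >= 0``.

Setting the Jacobian determinant to zero on each branch yields two genuine
fold curves in the ``(mu, mbar)`` plane (``SN-`` on the negative branch,
``SN+`` on the positive one) plus a pseudo-fold ``SN0`` at the seam
``x = 0`` where, for ``mbar <= 0``, the two branches of fixed points merge.
``SN0`` is not a true saddle-node -- the one-sided Jacobian limits disagree
at the seam -- but for the bursting dynamics it acts exactly like one, so it
is exported alongside the others with a distinct label.  The trace condition
gives a single Hopf line ``mbar = -N`` on the positive branch (the trace-zero
candidates of the cubic branch never satisfy the fixed-point condition for
the default coefficients), and the Hopf line meets ``SN+`` in a
Takens-Bogdanov point at ``x = mbar*N/(2*nu*B)``.

Cubic roots are computed with the closed-form trigonometric/Cardano method
rather than an iterative solver, so behaviour near the folds (double roots)
is deterministic and does not depend on starting guesses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import FastParams

__all__ = [
    "FixedPoint",
    "RegionConfig",
    "SNCurves",
    "HopfLine",
    "TBPoint",
    "BifurcationSet",
    "cubic_real_roots",
    "fixed_points",
    "jacobian_fast",
    "sn_curves",
    "hopf_curve",
    "tb_point",
    "local_region_config",
    "on_curve",
    "bifurcation_set",
]

#: fixed points closer than this to a bifurcation curve are "on-curve"
CURVE_TOL = 1e-8
#: imaginary parts below this are treated as numerical noise on real roots
IMAG_TOL = 1e-10


@dataclass
class FixedPoint:
    x: float
    y: float
    branch: str  # "negative" | "boundary" | "positive"
    stability: str
    trace: float
    det: float

    @property
    def is_stable(self) -> bool:
        return self.stability in ("stable-node", "stable-focus")


@dataclass
class RegionConfig:
    """Attractor census of one point of the map.

    ``has_stable_lc`` is ``None`` until a simulation-based check (see
    :mod:`epimap.mapgrid`) has been run; the analytic census alone cannot
    decide limit-cycle existence.
    """

    n_stable_fp: int
    n_fp: int
    has_stable_lc: bool | None = None

    def as_tuple(self) -> tuple[int, int, bool | None]:
        return (self.n_stable_fp, self.n_fp, self.has_stable_lc)


@dataclass
class SNCurves:
    """The three saddle-node (and pseudo-saddle-node) loci.

    ``sn_minus`` and ``sn_zero`` are constant-``mu`` lines; ``sn_plus`` is
    the parabola ``mu = sn_plus(mbar)``.  ``sn_zero`` is only meaningful for
    ``mbar <= 0``, where it continues the ``SN+`` parabola past its end at
    ``mbar = 0``.
    """

    sn_minus: float
    sn_plus_coeff: tuple[float, float]  # mu = c0 + c2 * mbar**2
    sn_zero: float

    def sn_plus(self, mbar):
        c0, c2 = self.sn_plus_coeff
        return c0 + c2 * np.asarray(mbar, dtype=float) ** 2


@dataclass
class HopfLine:
    """The Hopf line ``mbar = -N`` with its validity domain.

    The line is a genuine Hopf bifurcation only where the positive-branch
    fixed point has positive determinant, i.e. ``x > mbar*N/(2*nu*B)``;
    equivalently for ``mu > mu_min``, the Takens-Bogdanov ``mu``.
    """

    mbar: float
    mu_min: float

    def valid(self, mu) -> np.ndarray:
        return np.asarray(mu, dtype=float) > self.mu_min


@dataclass
class TBPoint:
    mu: float
    mbar: float
    x: float


@dataclass
class BifurcationSet:
    """Analytic curves plus (optionally) the simulation-inferred SH polyline."""

    sn: SNCurves
    hopf: HopfLine
    tb: TBPoint
    sh: np.ndarray | None = None  # polyline, columns (mbar, mu)


def cubic_real_roots(c3: float, c2: float, c1: float, c0: float) -> list[float]:
    """Real roots of ``c3*x**3 + c2*x**2 + c1*x + c0`` in closed form.

    Uses the depressed-cubic substitution with the trigonometric method for
    three real roots and Cardano's formula otherwise.  Roots whose implied
    imaginary part is below ``IMAG_TOL`` are returned as real.
    """
    if c3 == 0.0:
        raise ValueError("leading cubic coefficient is zero")
    # depressed form t^3 + p t + q with x = t - c2/(3 c3)
    s = c2 / (3.0 * c3)
    p = c1 / c3 - 3.0 * s * s
    q = 2.0 * s ** 3 - s * c1 / c3 + c0 / c3
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    roots: list[float]
    if disc > IMAG_TOL:
        # one real root (Cardano)
        sq = math.sqrt(disc)
        u = math.copysign(abs(-q / 2.0 + sq) ** (1.0 / 3.0), -q / 2.0 + sq)
        v = math.copysign(abs(-q / 2.0 - sq) ** (1.0 / 3.0), -q / 2.0 - sq)
        roots = [u + v]
    elif disc >= -IMAG_TOL and abs(p) < IMAG_TOL:
        # triple root
        roots = [0.0]
    elif disc >= -IMAG_TOL:
        # double root boundary: two distinct values
        u = math.copysign(abs(q / 2.0) ** (1.0 / 3.0), q / 2.0)
        roots = [-2.0 * u, u]
    else:
        # three distinct real roots (trigonometric)
        r = math.sqrt(-p ** 3 / 27.0)
        phi = math.acos(min(1.0, max(-1.0, -q / (2.0 * r))))
        mag = 2.0 * math.sqrt(-p / 3.0)
        roots = [mag * math.cos((phi + 2.0 * math.pi * k) / 3.0) for k in range(3)]
    return sorted(t - s for t in roots)


def _quadratic_real_roots(c2: float, c1: float, c0: float) -> list[float]:
    if c2 == 0.0:
        raise ValueError("leading quadratic coefficient is zero")
    disc = c1 * c1 - 4.0 * c2 * c0
    if disc < -IMAG_TOL:
        return []
    disc = max(disc, 0.0)
    sq = math.sqrt(disc)
    # numerically stable pair
    if c1 >= 0:
        q = -(c1 + sq) / 2.0
    else:
        q = -(c1 - sq) / 2.0
    r1 = q / c2
    roots = [r1] if disc <= IMAG_TOL else sorted([r1, c0 / q if q != 0 else r1])
    return roots


def jacobian_fast(fp: FastParams, x: float) -> np.ndarray:
    """Jacobian of the fast subsystem evaluated on the y-nullcline at ``x``.

    At the seam ``x = 0`` the right (``x >= 0``) limit is returned; the two
    one-sided limits disagree there, which is why ``SN0`` is only a
    pseudo-fold.
    """
    j11 = 3.0 * fp.a * x * x + 2.0 * fp.b * x if x < 0.0 else fp.mbar
    return np.array([[j11, fp.nu], [2.0 * fp.B * x, fp.N]])


def _stability(trace: float, det: float, tol: float = 1e-12) -> str:
    if det < -tol:
        return "saddle"
    if abs(trace) <= tol or abs(det) <= tol:
        return "non-hyperbolic"
    kind = "node" if trace * trace - 4.0 * det >= 0.0 else "focus"
    return f"{'stable' if trace < 0 else 'unstable'}-{kind}"


def fixed_points(fp: FastParams) -> list[FixedPoint]:
    """All fixed points of the fast subsystem, sorted by ``x``.

    Real roots of the cubic branch are kept when ``x < 0`` and of the
    quadratic branch when ``x >= 0``; each gets ``y = -(y0 + B x^2)/N`` and a
    stability label from the trace/determinant of the one-sided Jacobian.
    The boundary point ``x = 0`` (which appears when ``mu = nu*y0/N``) is
    labelled non-hyperbolic because the Jacobian is discontinuous there.
    """
    c0 = fp.mu - fp.nu * fp.y0 / fp.N
    xs: list[float] = []
    xs += [x for x in cubic_real_roots(fp.a, fp.b - fp.nu * fp.B / fp.N, 0.0, c0) if x < 0.0]
    xs += [
        x
        for x in _quadratic_real_roots(-fp.nu * fp.B / fp.N, fp.mbar, c0)
        if x >= 0.0
    ]
    out = []
    for x in sorted(xs):
        y = -(fp.y0 + fp.B * x * x) / fp.N
        J = jacobian_fast(fp, x)
        tr = float(J[0, 0] + J[1, 1])
        det = float(J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0])
        if x == 0.0:
            branch, stab = "boundary", "non-hyperbolic"
        else:
            branch = "negative" if x < 0 else "positive"
            stab = _stability(tr, det)
        out.append(FixedPoint(x=x, y=y, branch=branch, stability=stab, trace=tr, det=det))
    return out


def sn_curves(fp: FastParams) -> SNCurves:
    """The fold curves ``SN-``, ``SN+`` and the pseudo-fold ``SN0``.

    ``SN-`` : ``mu = nu*y0/N - (4/(27 a^2)) (b - nu*B/N)^3`` (constant).
    ``SN+`` : ``mu = nu*y0/N - N*mbar^2/(4*B*nu)`` (parabola in ``mbar``).
    ``SN0`` : ``mu = nu*y0/N`` for ``mbar <= 0``.
    """
    base = fp.nu * fp.y0 / fp.N
    sn_minus = base - 4.0 / (27.0 * fp.a ** 2) * (fp.b - fp.nu * fp.B / fp.N) ** 3
    c2 = -fp.N / (4.0 * fp.B * fp.nu)
    return SNCurves(sn_minus=sn_minus, sn_plus_coeff=(base, c2), sn_zero=base)


def negative_branch_hopf_candidates(fp: FastParams) -> list[float]:
    """Trace-zero ``x`` candidates on the cubic branch: ``3 a x^2 + 2 b x = -N``."""
    return _quadratic_real_roots(3.0 * fp.a, 2.0 * fp.b, fp.N)


def hopf_curve(fp: FastParams) -> HopfLine:
    """The Hopf line ``mbar = -N`` on the positive branch.

    The line is valid (determinant positive at the positive-branch fixed
    point) exactly for ``mu`` beyond the Takens-Bogdanov value, i.e.
    ``mu > sn_plus(-N)``.  Trace-zero candidates on the negative branch are
    checked and rejected: for admissible parameter sets they fall at
    ``x >= 0`` and therefore never satisfy the ``x < 0`` fixed-point
    condition.
    """
    sn = sn_curves(fp)
    mbar_h = -fp.N
    mu_min = float(sn.sn_plus(mbar_h))
    return HopfLine(mbar=mbar_h, mu_min=mu_min)


def tb_point(fp: FastParams) -> TBPoint:
    """Takens-Bogdanov point where the Hopf line meets ``SN+``.

    There ``mbar = -N``, ``x = mbar*N/(2*nu*B)`` and ``mu`` follows from the
    ``SN+`` parabola; trace and determinant of the Jacobian both vanish.
    """
    mbar = -fp.N
    x = mbar * fp.N / (2.0 * fp.nu * fp.B)
    sn = sn_curves(fp)
    mu = float(sn.sn_plus(mbar))
    return TBPoint(mu=mu, mbar=mbar, x=x)


def local_region_config(fp: FastParams) -> RegionConfig:
    """Fixed-point part of the attractor census at ``(mu, mbar)``.

    Limit-cycle existence is left undetermined (``has_stable_lc = None``);
    :func:`epimap.mapgrid.classify_region` fills it by simulation.
    """
    pts = fixed_points(fp)
    return RegionConfig(
        n_stable_fp=sum(p.is_stable for p in pts),
        n_fp=len(pts),
        has_stable_lc=None,
    )


def on_curve(fp: FastParams, tol: float = CURVE_TOL) -> bool:
    """True when ``(mu, mbar)`` lies within ``tol`` of an analytic curve.

    Points this close to a bifurcation are tagged rather than assigned to a
    region, since root multiplicity there is numerically ambiguous.
    """
    sn = sn_curves(fp)
    h = hopf_curve(fp)
    if abs(fp.mu - sn.sn_minus) <= tol:
        return True
    if fp.mbar <= tol and abs(fp.mu - sn.sn_zero) <= tol:
        return True
    if fp.mbar >= -tol and abs(fp.mu - float(sn.sn_plus(fp.mbar))) <= tol:
        return True
    if abs(fp.mbar - h.mbar) <= tol and fp.mu >= h.mu_min - tol:
        return True
    return False


def bifurcation_set(fp: FastParams, sh: np.ndarray | None = None) -> BifurcationSet:
    """Bundle the analytic curves (and an optional SH polyline) together."""
    return BifurcationSet(sn=sn_curves(fp), hopf=hopf_curve(fp), tb=tb_point(fp), sh=sh)
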