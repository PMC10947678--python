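"""Right-hand sides and parameter containers for the three noise-free systems.

Three deterministic ODE systems are defined here:

* the full six-variable Epileptor (fast, intermediate and slow subsystems,
  plus a low-pass filter state ``u``),
* its isolated two-variable fast subsystem with all eight coefficients
  explicit, and
* a three-variable bursting model built on a fixed-``mu2`` layer of the
  degenerate Takens-Bogdanov (DTB) unfolding.

The Epileptor state vector order is fixed as ``(x1, y1, z, x2, y2, u)``; all
writers and readers in :mod:`epimap.io` use it.  The convolution defining the
low-pass filtered drive ``u`` is implemented as a seventh state equation
``du/dt = 0.002*x1 - gamma*u`` with ``u(t0) = 0``, which is exact for the
exponential kernel and avoids storing the trajectory history.

Both piecewise right-hand sides switch branch inside the function (at
``x1 = 0`` for the fast variable and ``x2 = -0.25`` for the intermediate
one).  No event detection is needed: each pair of branches agrees at its
switch surface, so the vector field is continuous there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "EpileptorParams",
    "FastParams",
    "DTBParams",
    "Trajectory",
    "DivergenceError",
    "epileptor_rhs",
    "fast_rhs",
    "dtb_rhs",
    "fast_rhs_grid",
    "dtb_fast_rhs_grid",
    "lfp",
    "EPILEPTOR_COLUMNS",
    "DTB_COLUMNS",
]

EPILEPTOR_COLUMNS = ("x1", "y1", "z", "x2", "y2", "u")
DTB_COLUMNS = ("x", "y", "z")


class DivergenceError(RuntimeError):
    """Raised when a state handed to a right-hand side is not finite."""


@dataclass
class EpileptorParams:
    """Parameters of the full Epileptor.

    ``x0`` is the epileptogenicity: it sets the position of the z-nullcline
    relative to the resting branch and thereby how prone the model is to
    leave the interictal state.  ``m`` shifts the excitability of the fast
    subsystem for ``x1 >= 0`` and ``alpha`` sets the sign/scale of the
    quadratic z-term in the slow drive ``mbar = 0.6*alpha*(z-4)**2 + m - x2``;
    with ``alpha = 1`` the classic equations are recovered, while
    ``alpha = -1`` flips the global slope of the path on the map and gives
    access to the Hopf-onset bursting classes.
    """

    x0: float = -1.6
    y0: float = 1.0
    tau0: float = 2857.0
    tau1: float = 1.0
    tau2: float = 10.0
    Irest1: float = 3.1
    Irest2: float = 0.45
    gamma: float = 0.01
    m: float = 0.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau0 > self.tau2 > self.tau1 > 0):
            raise ValueError(
                "time-scale separation requires tau0 > tau2 > tau1 > 0, got "
                f"tau0={self.tau0}, tau2={self.tau2}, tau1={self.tau1}"
            )
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")

    def replace(self, **kw: float) -> "EpileptorParams":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return EpileptorParams(**d)


@dataclass
class FastParams:
    """Coefficients of the isolated fast subsystem.

    The vector field is

    .. math::

        \\dot x = \\nu y + a x^3 + b x^2 + \\mu \\quad (x < 0), \\qquad
        \\dot x = \\nu y + \\bar m x + \\mu \\quad (x \\ge 0), \\qquad
        \\dot y = y_0 + B x^2 + N y.

    ``mu`` and ``mbar`` are the two slowly-driven parameters that span the
    bifurcation map; the remaining six are fixed coefficients.
    """

    nu: float = 1.0
    a: float = -1.0
    b: float = 3.0
    y0: float = 1.0
    B: float = -5.0
    N: float = -1.0
    mu: float = 0.0
    mbar: float = 0.0

    def __post_init__(self) -> None:
        for name in ("N", "B", "a", "nu"):
            if getattr(self, name) == 0:
                raise ValueError(f"fast parameter {name!r} must be nonzero")

    def replace(self, **kw: float) -> "FastParams":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return FastParams(**d)


@dataclass
class DTBParams:
    """Layer and path parameters of the DTB bursting model.

    The fast subsystem lives on a layer of the DTB unfolding at fixed
    ``mu2 > 0``; the slowly-driven unfolding parameters move along the
    straight line ``mu1(z) = mu1_0 + d_mu1*z``, ``nu(z) = nu_0 + d_nu*z``.
    ``c`` is the slow rate (``0 < c << 1``) and ``x0`` the excitability
    threshold at which the slow variable reverses direction.
    """

    mu2: float = 0.07
    mu1_0: float = 0.0
    nu_0: float = 0.02
    d_mu1: float = -0.01
    d_nu: float = 0.0
    c: float = 0.001
    x0: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.c < 1):
            raise ValueError(f"slow rate c must satisfy 0 < c << 1, got {self.c}")
        if self.mu2 <= 0:
            raise ValueError(f"layer parameter mu2 must be positive, got {self.mu2}")

    def replace(self, **kw: float) -> "DTBParams":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return DTBParams(**d)


@dataclass
class Trajectory:
    """A sampled solution: strictly increasing times and a state matrix."""

    times: np.ndarray
    states: np.ndarray  # shape (n_samples, n_vars)
    model: str = "epileptor"
    columns: tuple[str, ...] = EPILEPTOR_COLUMNS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.states.ndim != 2:
            raise ValueError("times must be 1-D and states 2-D")
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape[1] != len(self.columns):
            raise ValueError(
                f"state dimension {self.states.shape[1]} does not match "
                f"columns {self.columns}"
            )

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, **{c: self[c] for c in self.columns}}
        )


def _check_finite(state) -> None:
    for v in state:
        if not math.isfinite(v):
            raise DivergenceError(f"non-finite state encountered: {list(state)}")


def mbar_of(z: float, x2: float, p: EpileptorParams):
    """Slow drive of the fast excitability: ``0.6*alpha*(z-4)^2 + m - x2``."""
    return 0.6 * p.alpha * (z - 4.0) ** 2 + p.m - x2


def epileptor_rhs(t: float, state, p: EpileptorParams) -> list[float]:
    """Time derivative of the full Epileptor at ``state``.

    The ``x1`` equation switches branch at ``x1 = 0`` (both branches equal
    ``y1 - z + Irest1`` there) and the ``y2`` equation at ``x2 = -0.25``.
    For ``x1 >= 0`` the excitability coefficient is
    ``mbar = 0.6*alpha*(z-4)**2 + m - x2``, which reduces to the printed
    classic form when ``alpha = 1``.
    """
    _check_finite(state)
    x1, y1, z, x2, y2, u = state
    if x1 < 0.0:
        dx1 = y1 - x1 ** 3 + 3.0 * x1 ** 2 - z + p.Irest1
    else:
        dx1 = y1 + mbar_of(z, x2, p) * x1 - z + p.Irest1
    dy1 = p.y0 - 5.0 * x1 ** 2 - y1
    dz = (4.0 * (x1 - p.x0) - z) / p.tau0
    dx2 = -y2 + x2 - x2 ** 3 + p.Irest2 + u - 0.3 * (z - 3.5)
    if x2 < -0.25:
        dy2 = -y2 / p.tau2
    else:
        dy2 = (-y2 + 6.0 * (x2 + 0.25)) / p.tau2
    du = 0.002 * x1 - p.gamma * u
    inv_tau1 = 1.0 / p.tau1
    return [dx1 * inv_tau1, dy1 * inv_tau1, dz, dx2, dy2, du]


def fast_rhs(t: float, state, fp: FastParams) -> list[float]:
    """Time derivative of the isolated fast subsystem at ``(x, y)``."""
    _check_finite(state)
    x, y = state
    if x < 0.0:
        dx = fp.nu * y + fp.a * x ** 3 + fp.b * x ** 2 + fp.mu
    else:
        dx = fp.nu * y + fp.mbar * x + fp.mu
    dy = fp.y0 + fp.B * x ** 2 + fp.N * y
    return [dx, dy]


def dtb_rhs(t: float, state, p: DTBParams) -> list[float]:
    """Time derivative of the DTB bursting model at ``(x, y, z)``."""
    _check_finite(state)
    x, y, z = state
    mu1 = p.mu1_0 + p.d_mu1 * z
    nu = p.nu_0 + p.d_nu * z
    dx = -y
    dy = x ** 3 - p.mu2 * x - mu1 - y * (nu + x + x ** 2)
    dz = p.c * (x - p.x0)
    return [dx, dy, dz]


def fast_rhs_grid(x, y, mu, mbar, fp: FastParams):
    """Vectorised fast-subsystem field for arrays of states and parameters.

    Used by the map builder to integrate every grid cell simultaneously.
    """
    dx = np.where(
        x < 0.0,
        fp.nu * y + fp.a * x ** 3 + fp.b * x ** 2 + mu,
        fp.nu * y + mbar * x + mu,
    )
    dy = fp.y0 + fp.B * x ** 2 + fp.N * y
    return dx, dy


def dtb_fast_rhs_grid(x, y, mu1, nu, mu2: float):
    """Vectorised DTB fast-subsystem field on the fixed-``mu2`` layer."""
    dx = -y
    dy = x ** 3 - mu2 * x - mu1 - y * (nu + x + x ** 2)
    return dx, dy


def lfp(traj: Trajectory) -> np.ndarray:
    """Simulated field potential of the Epileptor: ``x2 - x1`` pointwise."""
    if traj.model != "epileptor":
        raise ValueError(
            f"lfp is defined for full-Epileptor trajectories, got {traj.model!r}"
        )
    return traj["x2"] - traj["x1"]
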