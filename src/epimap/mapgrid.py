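"""Simulation-based amplitude/frequency maps and region classification.

The saddle-homoclinic (SH) offset curve has no closed form for these
piecewise systems (continuation software struggles with the seam), so it is
inferred from simulations: every cell of a ``(mu, mbar)`` rectangle is
integrated from just beside the non-resting fixed point, the transient is
discarded, and the amplitude (max - min of ``x``) and dominant frequency
(Hann-windowed DFT) of the remainder are recorded.  Approaching the SH
boundary the limit-cycle frequency scales to zero, and the oscillatory
region ends; the boundary polyline that this traces out starts at the
Takens-Bogdanov point, as unfolding theory predicts.

The grid engine integrates all cells simultaneously with a fixed-step
classical Runge-Kutta scheme (step 0.02, i.e. five times finer than the 0.1
protocol cap; the isolated fast subsystems are non-stiff).  This keeps a
600-time-unit sweep over hundreds of cells within seconds while remaining
bit-reproducible: identical protocols produce identical matrices.

The same machinery serves both fast subsystems: the Epileptor's (parameters
``(mu, mbar)``) and the DTB layer's (parameters ``(mu1, nu)`` at fixed
``mu2``), which is what exposes their topological equivalence.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import models
from .bifurcations import RegionConfig, cubic_real_roots, fixed_points, hopf_curve
from .models import FastParams

__all__ = [
    "MapProtocol",
    "DTB_MAP_PROTOCOL",
    "MapGrid",
    "EpileptorFastSystem",
    "DTBFastSystem",
    "limit_cycle_stats",
    "build_map",
    "infer_sh_curve",
    "classify_region",
    "region_census",
]


@dataclass(frozen=True)
class MapProtocol:
    """Per-cell simulation protocol for the map sweep.

    Defaults are the Epileptor fast-subsystem protocol (600 time units with
    the first 300 discarded, start offset ``epsilon = 0.05``); the DTB layer
    uses the longer, finer :data:`DTB_MAP_PROTOCOL` because its limit cycle
    and attraction rates are two orders of magnitude smaller.
    ``amp_threshold`` (in ``x`` units) decides "converged to a fixed point":
    1e-3 is two orders below typical limit-cycle amplitudes on these maps.
    """

    t_total: float = 600.0
    t_discard: float = 300.0
    epsilon: float = 0.05
    sample_dt: float = 0.1
    dt: float = 0.02
    amp_threshold: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 < self.t_discard < self.t_total):
            raise ValueError("need 0 < t_discard < t_total")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def freq_floor(self) -> float:
        """Twice the DFT bin width: the lowest trustworthy nonzero frequency."""
        return 2.0 / (self.t_total - self.t_discard)


DTB_MAP_PROTOCOL = MapProtocol(t_total=2000.0, t_discard=500.0, epsilon=0.0005)


class EpileptorFastSystem:
    """The Epileptor fast subsystem as a two-parameter family over (mu, mbar)."""

    name = "epileptor_fast"
    param_names = ("mu", "mbar")
    rest_branch = "lower"  # resting/interictal state is the most negative root

    def __init__(self, base: FastParams | None = None):
        self.base = base if base is not None else FastParams()

    def rhs_grid(self, x, y, p1, p2):
        return models.fast_rhs_grid(x, y, p1, p2, self.base)

    def y_star(self, x):
        b = self.base
        return -(b.y0 + b.B * np.asarray(x) ** 2) / b.N

    def fixed_xs(self, p1: float, p2: float) -> list[float]:
        return [p.x for p in fixed_points(self.base.replace(mu=p1, mbar=p2))]

    def census(self, p1: float, p2: float) -> RegionConfig:
        pts = fixed_points(self.base.replace(mu=p1, mbar=p2))
        return RegionConfig(sum(p.is_stable for p in pts), len(pts))


class DTBFastSystem:
    """The DTB-unfolding layer at fixed ``mu2`` over (mu1, nu)."""

    name = "dtb_fast"
    param_names = ("mu1", "nu")
    rest_branch = "upper"  # resting state is the largest-x root

    def __init__(self, mu2: float = 0.07):
        if mu2 <= 0:
            raise ValueError("mu2 must be positive")
        self.mu2 = mu2

    def rhs_grid(self, x, y, p1, p2):
        return models.dtb_fast_rhs_grid(x, y, p1, p2, self.mu2)

    def y_star(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))

    def fixed_xs(self, p1: float, p2: float) -> list[float]:
        return cubic_real_roots(1.0, 0.0, -self.mu2, -p1)

    def census(self, p1: float, p2: float) -> RegionConfig:
        n_stable = 0
        xs = self.fixed_xs(p1, p2)
        for x in xs:
            tr = -(p2 + x + x * x)
            det = 3.0 * x * x - self.mu2
            if det > 0 and tr < 0:
                n_stable += 1
        return RegionConfig(n_stable, len(xs))


@dataclass
class MapGrid:
    """Amplitude/frequency/region classification over a parameter rectangle.

    Matrices are indexed ``[i, j]`` with ``i`` along ``mu_values`` (first
    parameter) and ``j`` along ``mbar_values`` (second parameter).
    ``frequency`` is in Hz with model time read as seconds, resolvable only
    in multiples of ``1/(t_total - t_discard)`` (refined by quadratic
    interpolation around the spectral peak).
    """

    mu_values: np.ndarray
    mbar_values: np.ndarray
    amplitude: np.ndarray
    frequency: np.ndarray
    converged_to_fp: np.ndarray
    region: np.ndarray  # object array of RegionConfig
    diverged: np.ndarray
    protocol: MapProtocol
    system_name: str = "epileptor_fast"

    def __post_init__(self) -> None:
        shape = (len(self.mu_values), len(self.mbar_values))
        for name in ("amplitude", "frequency", "converged_to_fp", "region", "diverged"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"matrix {name!r} has shape mismatch with axes")
        ok = ~self.diverged
        if np.any(self.amplitude[ok] < 0) or np.any(self.frequency[ok] < 0):
            raise ValueError("amplitude and frequency must be nonnegative")

    def oscillatory(self) -> np.ndarray:
        return ~self.converged_to_fp & ~self.diverged


def _start_states(system, p1_flat, p2_flat, eps):
    """Protocol start: the non-resting fixed point offset by (eps, 0)."""
    x0 = np.empty_like(p1_flat)
    for k in range(p1_flat.size):
        xs = system.fixed_xs(p1_flat[k], p2_flat[k])
        x0[k] = max(xs) if system.rest_branch == "lower" else min(xs)
    return x0 + eps, np.asarray(system.y_star(x0), dtype=float)


def _integrate_grid(system, p1_flat, p2_flat, protocol: MapProtocol):
    """Fixed-step RK4 of all cells at once; returns retained x-samples."""
    x, y = _start_states(system, p1_flat, p2_flat, protocol.epsilon)
    dt = protocol.dt
    nstep = int(round(protocol.t_total / dt))
    keep_every = max(1, int(round(protocol.sample_dt / dt)))
    nkeep = int(round((protocol.t_total - protocol.t_discard) / protocol.sample_dt))
    X = np.full((nkeep, p1_flat.size), np.nan)
    k = 0
    rhs = system.rhs_grid
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(nstep):
            k1x, k1y = rhs(x, y, p1_flat, p2_flat)
            k2x, k2y = rhs(x + 0.5 * dt * k1x, y + 0.5 * dt * k1y, p1_flat, p2_flat)
            k3x, k3y = rhs(x + 0.5 * dt * k2x, y + 0.5 * dt * k2y, p1_flat, p2_flat)
            k4x, k4y = rhs(x + dt * k3x, y + dt * k3y, p1_flat, p2_flat)
            x = x + dt / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
            y = y + dt / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
            if (i + 1) * dt > protocol.t_discard and (i + 1) % keep_every == 0 and k < nkeep:
                X[k] = x
                k += 1
    return X[:k]


def _spectral_peak_frequency(X: np.ndarray, sample_dt: float) -> np.ndarray:
    """Dominant nonzero frequency per column via Hann-windowed DFT.

    The peak bin is refined by quadratic interpolation of the three
    magnitudes around the maximum.
    """
    n = X.shape[0]
    w = np.hanning(n)
    F = np.abs(np.fft.rfft((X - X.mean(axis=0)) * w[:, None], axis=0))
    pk = F[1:].argmax(axis=0) + 1
    cols = np.arange(X.shape[1])
    delta = np.zeros(X.shape[1])
    inner = (pk > 1) & (pk < F.shape[0] - 1)
    if np.any(inner):
        ym = F[pk[inner] - 1, cols[inner]]
        yc = F[pk[inner], cols[inner]]
        yp = F[pk[inner] + 1, cols[inner]]
        denom = ym - 2.0 * yc + yp
        good = denom != 0
        d = np.zeros(ym.shape)
        d[good] = 0.5 * (ym - yp)[good] / denom[good]
        delta[inner] = np.clip(d, -0.5, 0.5)
    return (pk + delta) / (n * sample_dt)


def limit_cycle_stats(
    fp: FastParams, protocol: MapProtocol | None = None
) -> tuple[float, float, bool]:
    """Amplitude, frequency and convergence flag at one point of the map.

    Integrates the fast subsystem from the non-resting fixed point offset by
    ``(epsilon, 0)``, drops the transient, and measures amplitude as
    max - min of ``x`` and frequency as the dominant Hann-windowed DFT peak.
    ``converged_to_fp`` is true when the amplitude of the trailing fifth of
    the retained window falls below ``amp_threshold``.
    """
    protocol = protocol or MapProtocol()
    system = EpileptorFastSystem(fp)
    grid = build_map(system, [fp.mu], [fp.mbar], protocol)
    return (
        float(grid.amplitude[0, 0]),
        float(grid.frequency[0, 0]),
        bool(grid.converged_to_fp[0, 0]),
    )


def build_map(
    system,
    mu_values,
    mbar_values,
    protocol: MapProtocol | None = None,
) -> MapGrid:
    """Sweep the per-cell protocol over a parameter rectangle.

    ``system`` may be an :class:`EpileptorFastSystem`, a
    :class:`DTBFastSystem`, or a :class:`~epimap.models.FastParams` (taken as
    the base of an Epileptor fast system).  Cells whose integration blows up
    are flagged in ``diverged`` rather than raising.  The sweep is fully
    deterministic.
    """
    if isinstance(system, FastParams):
        system = EpileptorFastSystem(system)
    protocol = protocol or MapProtocol()
    mu_values = np.asarray(mu_values, dtype=float)
    mbar_values = np.asarray(mbar_values, dtype=float)
    if mu_values.size == 0 or mbar_values.size == 0:
        raise ValueError("parameter ranges must be non-degenerate")
    P1, P2 = np.meshgrid(mu_values, mbar_values, indexing="ij")
    p1, p2 = P1.ravel(), P2.ravel()
    X = _integrate_grid(system, p1, p2, protocol)

    diverged = ~np.isfinite(X).all(axis=0)
    amp = np.where(diverged, np.nan, X.max(axis=0) - X.min(axis=0))
    ntail = max(2, X.shape[0] // 5)
    tail = X[-ntail:]
    amp_tail = np.where(diverged, np.nan, tail.max(axis=0) - tail.min(axis=0))
    converged = np.where(diverged, False, amp_tail < protocol.amp_threshold)

    freq = np.zeros(p1.size)
    osc = ~diverged & ~converged.astype(bool)
    if np.any(osc):
        freq[osc] = _spectral_peak_frequency(X[:, osc], protocol.sample_dt)
    freq[diverged] = np.nan

    shape = P1.shape
    region = np.empty(p1.size, dtype=object)
    for k in range(p1.size):
        cfg = system.census(p1[k], p2[k])
        cfg.has_stable_lc = None if diverged[k] else bool(osc[k])
        region[k] = cfg

    return MapGrid(
        mu_values=mu_values,
        mbar_values=mbar_values,
        amplitude=amp.reshape(shape),
        frequency=freq.reshape(shape),
        converged_to_fp=converged.astype(bool).reshape(shape),
        region=region.reshape(shape),
        diverged=diverged.reshape(shape),
        protocol=protocol,
        system_name=system.name,
    )


def infer_sh_curve(grid: MapGrid, freq_floor: float | None = None) -> np.ndarray:
    """Locate the saddle-homoclinic boundary from the frequency map.

    For every ``mbar`` row that contains oscillatory cells, the edge of the
    oscillatory run that abuts a three-fixed-point (bistable) cell is the SH
    candidate: there a saddle exists for the cycle to collide with, and the
    measured frequency decays toward zero.  The boundary ``mu`` is placed by
    linearly interpolating the frequency between the last oscillatory cell
    and its silent neighbour down to ``freq_floor`` (default: twice the DFT
    bin width; the inference rests on the decaying trend, not on the exact
    cutoff).  Returns a polyline with columns ``(mbar, mu)`` sorted by
    ``mbar``; empty (with a warning) when no oscillatory cells exist.
    """
    if freq_floor is None:
        freq_floor = grid.protocol.freq_floor
    osc = grid.oscillatory()
    rows = []
    for j, mbar in enumerate(grid.mbar_values):
        col = osc[:, j]
        if not col.any():
            continue
        idx = np.flatnonzero(col)
        # contiguous run containing the majority of oscillatory cells
        for edge, neighbour in ((idx[0], idx[0] - 1), (idx[-1], idx[-1] + 1)):
            if neighbour < 0 or neighbour >= len(grid.mu_values):
                continue
            if osc[neighbour, j] or grid.diverged[neighbour, j]:
                continue
            if grid.region[neighbour, j].n_fp != 3:
                continue
            f1 = grid.frequency[edge, j]
            mu1 = grid.mu_values[edge]
            mu0 = grid.mu_values[neighbour]
            if f1 > freq_floor:
                frac = min(1.0, freq_floor / f1)
                mu_b = mu1 + (mu0 - mu1) * (1.0 - frac)
            else:
                mu_b = 0.5 * (mu0 + mu1)
            rows.append((float(mbar), float(mu_b)))
    if not rows:
        warnings.warn("no oscillatory cells in grid; SH polyline is empty")
        return np.empty((0, 2))
    rows.sort()
    return np.asarray(rows)


def classify_region(
    system,
    p1: float,
    p2: float,
    protocol: MapProtocol | None = None,
) -> RegionConfig:
    """Full attractor census at one map point.

    Combines the analytic fixed-point census with limit-cycle detection from
    two starts: beside the non-resting fixed point (the protocol start) and
    beside the resting one.  ``has_stable_lc`` is ``None`` when integration
    fails from both starts.
    """
    if isinstance(system, FastParams):
        system = EpileptorFastSystem(system)
    protocol = protocol or MapProtocol()
    xs = sorted(system.fixed_xs(p1, p2))
    starts = {xs[-1], xs[0]} if len(xs) > 1 else {xs[0]}
    has_lc: bool | None = None
    for xstart in starts:
        sub = _SingleStart(system, np.array([xstart]))
        X = _integrate_grid(sub, np.array([p1]), np.array([p2]), protocol)
        if not np.isfinite(X).all():
            continue
        ntail = max(2, X.shape[0] // 5)
        amp_tail = float(X[-ntail:].max() - X[-ntail:].min())
        osc = amp_tail >= protocol.amp_threshold
        has_lc = bool(osc) if has_lc is None else (has_lc or bool(osc))
    cfg = system.census(p1, p2)
    cfg.has_stable_lc = has_lc
    return cfg


class _SingleStart:
    """Wrap a system to force a specific starting x (internal helper)."""

    def __init__(self, system, x0):
        self._system = system
        self._x0 = x0
        self.name = system.name
        self.rest_branch = system.rest_branch

    def rhs_grid(self, x, y, p1, p2):
        return self._system.rhs_grid(x, y, p1, p2)

    def y_star(self, x):
        return self._system.y_star(x)

    def fixed_xs(self, p1, p2):
        return [float(self._x0[0])]

    def census(self, p1, p2):
        return self._system.census(p1, p2)


def region_census(grid: MapGrid) -> Counter:
    """Count the distinct (n_stable_fp, n_fp, has_stable_lc) configurations."""
    return Counter(
        grid.region[i, j].as_tuple()
        for i in range(len(grid.mu_values))
        for j in range(len(grid.mbar_values))
        if not grid.diverged[i, j]
    )
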