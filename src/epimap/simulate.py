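"""Deterministic integration engine shared by all three systems.

Integration uses :func:`scipy.integrate.solve_ivp` with the stiffness-capable
LSODA method and a hard cap of 0.1 on the step size, mirroring the simulation
protocol used throughout the analysis; output is sampled on a fixed grid
(default ``dt = 0.1``) so that downstream spectra and event detection are
grid-stable, and every fast oscillation (period of a few time units) contains
at least 20 samples.  All simulations are noise-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import models
from .bifurcations import cubic_real_roots
from .models import (
    DTB_COLUMNS,
    EPILEPTOR_COLUMNS,
    DTBParams,
    EpileptorParams,
    FastParams,
    Trajectory,
)

__all__ = [
    "SolveOptions",
    "IntegrationError",
    "integrate",
    "rest_initial_state",
    "run_preset",
]


class IntegrationError(RuntimeError):
    """Raised when the solver fails; carries the last valid time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time {last_time:g})")
        self.last_time = last_time


@dataclass
class SolveOptions:
    """Solver options for :func:`integrate`.

    ``max_step`` defaults to the protocol cap 0.1; ``sample_dt`` is the fixed
    output grid spacing.
    """

    t_span: tuple[float, float] = (0.0, 1000.0)
    initial_state: tuple[float, ...] | None = None
    max_step: float = 0.1
    rtol: float = 1e-8
    atol: float = 1e-10
    sample_dt: float = 0.1
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")
        if not self.t_span[1] > self.t_span[0]:
            raise ValueError("t_span must be increasing")

    def replace(self, **kw) -> "SolveOptions":
        from dataclasses import fields as _fields

        d = {f.name: getattr(self, f.name) for f in _fields(self)}
        d.update(kw)
        return SolveOptions(**d)


_MODEL_TABLE = {
    "epileptor": (models.epileptor_rhs, EPILEPTOR_COLUMNS),
    "fast": (models.fast_rhs, ("x", "y")),
    "dtb": (models.dtb_rhs, DTB_COLUMNS),
}


def integrate(model: str, params, opts: SolveOptions) -> Trajectory:
    """Integrate one of the registered models and return a sampled trajectory.

    ``model`` is one of ``"epileptor"``, ``"fast"`` or ``"dtb"``; ``params``
    the matching parameter dataclass.  Raises :class:`IntegrationError` on
    step-size collapse or a non-finite state, reporting the last valid time.
    """
    if model not in _MODEL_TABLE:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(_MODEL_TABLE)}")
    rhs, columns = _MODEL_TABLE[model]
    if opts.initial_state is None:
        raise ValueError("SolveOptions.initial_state must be set")
    y0 = np.asarray(opts.initial_state, dtype=float)
    rhs(opts.t_span[0], y0, params)  # precondition: rhs finite at start
    t_eval = np.arange(opts.t_span[0], opts.t_span[1] + 0.5 * opts.sample_dt, opts.sample_dt)
    sol = solve_ivp(
        rhs,
        opts.t_span,
        y0,
        args=(params,),
        method=opts.method,
        max_step=opts.max_step,
        rtol=opts.rtol,
        atol=opts.atol,
        t_eval=t_eval,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else opts.t_span[0]
        raise IntegrationError(f"solver failed: {sol.message}", last)
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        bad = int(np.argmax(~np.isfinite(states).all(axis=1)))
        raise IntegrationError("non-finite state in solution", float(sol.t[max(bad - 1, 0)]))
    return Trajectory(times=sol.t, states=states, model=model, columns=columns)


def rest_initial_state(params: EpileptorParams, z0: float = 3.0) -> tuple[float, ...]:
    """Full-Epileptor start on the interictal branch.

    Presets start from the resting (most negative) root of the fast cubic at
    ``mu = Irest1 - z0`` with the
    matching ``y1`` nullcline value, ``z = z0`` and the intermediate/filter
    states at zero; the first burst is treated as transient by downstream
    analyses.  This removes any dependence on arbitrary starting points.
    """
    mu = params.Irest1 - z0
    roots = [x for x in cubic_real_roots(-1.0, -2.0, 0.0, mu + 1.0) if x < 0.0]
    x1 = min(roots)
    y1 = params.y0 - 5.0 * x1 ** 2
    return (x1, y1, z0, 0.0, 0.0, 0.0)


def run_preset(name: str, *, tolerance_factor: float = 1.0, t_span=None):
    """Run a registered scenario and return ``(trajectory, report)``.

    ``tolerance_factor`` scales ``rtol``/``atol`` (used by the robustness
    checks that halve solver tolerances); ``t_span`` optionally overrides the
    preset's span.  The report carries everything needed to re-run the
    simulation bit-identically.
    """
    from .presets import get_preset  # local import to avoid cycle

    preset = get_preset(name)
    params = preset.make_params()
    opts = preset.make_options()
    if t_span is not None:
        opts = opts.replace(t_span=tuple(t_span))
    if tolerance_factor != 1.0:
        opts = opts.replace(rtol=opts.rtol * tolerance_factor, atol=opts.atol * tolerance_factor)
    traj = integrate(preset.model, params, opts)
    report = {
        "preset": preset.name,
        "model": preset.model,
        "note": preset.note,
        "params": params.__dict__.copy(),
        "options": {
            "t_span": list(opts.t_span),
            "initial_state": list(opts.initial_state),
            "max_step": opts.max_step,
            "rtol": opts.rtol,
            "atol": opts.atol,
            "sample_dt": opts.sample_dt,
            "method": opts.method,
        },
        "n_samples": len(traj),
    }
    return traj, report
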