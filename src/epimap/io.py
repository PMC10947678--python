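"""Config loading and plain-text writers (CSV/JSON) for every artefact.

All CSV output uses comma separation, '.' decimals, a header row, no index
column and LF line endings, so files are bit-identical across platforms.
Trajectories use the fixed column orders ``t,x1,y1,z,x2,y2,u`` (Epileptor)
and ``t,x,y,z`` (DTB).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import fields as dataclass_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .bifurcations import BifurcationSet, FixedPoint
from .mapgrid import MapGrid
from .models import (
    DTB_COLUMNS,
    EPILEPTOR_COLUMNS,
    DTBParams,
    EpileptorParams,
    FastParams,
    Trajectory,
)
from .simulate import SolveOptions

__all__ = [
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "write_bifurcation_set",
    "write_fixed_points",
    "write_map_grid",
    "write_outputs",
]

_PARAM_CLASSES = {"epileptor": EpileptorParams, "fast": FastParams, "dtb": DTBParams}


def load_config(path) -> dict:
    """Load a flat key/value config with one optional ``solver`` nesting.

    Top-level keys are ``model`` (default ``"epileptor"``) plus any parameter
    field of that model; ``solver`` holds :class:`SolveOptions` fields.
    Defaults are the standard parameter values, overlaid with the file's
    entries.  Unknown keys are rejected with the list of valid ones.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    model = raw.pop("model", "epileptor")
    if model not in _PARAM_CLASSES:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(_PARAM_CLASSES)}")
    cls = _PARAM_CLASSES[model]
    valid = {f.name for f in dataclass_fields(cls)}
    solver_raw = raw.pop("solver", {}) or {}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; valid keys: "
            f"{sorted(valid)} plus 'model' and 'solver'"
        )
    for k, v in raw.items():
        if not isinstance(v, (int, float)):
            raise ValueError(f"config key {k!r} must be numeric, got {type(v).__name__}")
    params = cls(**{k: float(v) for k, v in raw.items()})
    valid_solver = {f.name for f in dataclass_fields(SolveOptions)}
    unknown = set(solver_raw) - valid_solver
    if unknown:
        raise ValueError(
            f"unknown solver key(s) {sorted(unknown)}; valid: {sorted(valid_solver)}"
        )
    if "t_span" in solver_raw:
        solver_raw["t_span"] = tuple(solver_raw["t_span"])
    if "initial_state" in solver_raw:
        solver_raw["initial_state"] = tuple(solver_raw["initial_state"])
    options = SolveOptions(**solver_raw) if solver_raw else None
    return {"model": model, "params": params, "options": options}


def _to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def write_trajectory(traj: Trajectory, path) -> Path:
    path = Path(path)
    _to_csv(traj.to_frame(), path)
    return path


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = tuple(df.columns[1:])
    if cols == EPILEPTOR_COLUMNS:
        model = "epileptor"
    elif cols == DTB_COLUMNS:
        model = "dtb"
    elif cols == ("x", "y"):
        model = "fast"
    else:
        raise ValueError(f"unrecognised trajectory columns {cols}")
    return Trajectory(
        times=df["t"].to_numpy(), states=df.iloc[:, 1:].to_numpy(), model=model, columns=cols
    )


def write_fixed_points(points: list[FixedPoint], mu: float, mbar: float, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {"mu": mu, "mbar": mbar, "x": p.x, "y": p.y, "branch": p.branch,
             "stability": p.stability}
            for p in points
        ]
    )
    _to_csv(df, path)
    return path


def write_bifurcation_set(
    bset: BifurcationSet, out_dir, mbar_range=(-3.0, 2.0), n: int = 201
) -> list[Path]:
    """Write each analytic curve as a ``mbar,mu,curve_label`` polyline CSV
    plus a JSON file with the TB point."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    mbar = np.linspace(*mbar_range, n)
    curves = {
        "sn_minus": pd.DataFrame(
            {"mbar": mbar, "mu": np.full(n, bset.sn.sn_minus), "curve_label": "SN-"}
        ),
        "sn_plus": pd.DataFrame(
            {
                "mbar": mbar[mbar >= 0],
                "mu": bset.sn.sn_plus(mbar[mbar >= 0]),
                "curve_label": "SN+",
            }
        ),
        "sn_zero": pd.DataFrame(
            {
                "mbar": mbar[mbar <= 0],
                "mu": np.full((mbar <= 0).sum(), bset.sn.sn_zero),
                "curve_label": "SN0",
            }
        ),
        "hopf": pd.DataFrame(
            {
                "mbar": np.full(n, bset.hopf.mbar),
                "mu": np.linspace(bset.hopf.mu_min, bset.hopf.mu_min + 3.0, n),
                "curve_label": "Hopf",
            }
        ),
    }
    if bset.sh is not None and len(bset.sh):
        curves["sh"] = pd.DataFrame(
            {"mbar": bset.sh[:, 0], "mu": bset.sh[:, 1], "curve_label": "SH"}
        )
    for name, df in curves.items():
        p = out_dir / f"curve_{name}.csv"
        _to_csv(df, p)
        written.append(p)
    tbp = out_dir / "tb_point.json"
    tbp.write_text(
        json.dumps({"mu": bset.tb.mu, "mbar": bset.tb.mbar, "x": bset.tb.x}, indent=2)
        + "\n"
    )
    written.append(tbp)
    return written


def write_map_grid(grid: MapGrid, out_dir) -> list[Path]:
    """Persist a MapGrid as three matrix CSVs plus an axes CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    axes = pd.DataFrame(
        {
            "axis": ["mu"] * len(grid.mu_values) + ["mbar"] * len(grid.mbar_values),
            "value": np.concatenate([grid.mu_values, grid.mbar_values]),
        }
    )
    for name, mat in (
        ("amplitude", grid.amplitude),
        ("frequency", grid.frequency),
        ("converged", grid.converged_to_fp.astype(int)),
    ):
        p = out_dir / f"map_{name}.csv"
        _to_csv(pd.DataFrame(mat), p)
        written.append(p)
    p = out_dir / "map_axes.csv"
    _to_csv(axes, p)
    written.append(p)
    return written


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(objects: dict, out_dir) -> list[dict]:
    """Write a mapping of name -> object; returns a manifest with checksums.

    Supported objects: :class:`Trajectory`, :class:`MapGrid`,
    :class:`BifurcationSet`, plain dicts (JSON) and DataFrames (CSV).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for name, obj in objects.items():
        if isinstance(obj, Trajectory):
            paths = [write_trajectory(obj, out_dir / f"{name}.csv")]
        elif isinstance(obj, MapGrid):
            paths = write_map_grid(obj, out_dir / name)
        elif isinstance(obj, BifurcationSet):
            paths = write_bifurcation_set(obj, out_dir / name)
        elif isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            _to_csv(obj, p)
            paths = [p]
        elif isinstance(obj, dict):
            p = out_dir / f"{name}.json"
            p.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
            paths = [p]
        else:
            raise TypeError(f"cannot serialise object {name!r} of type {type(obj)}")
        manifest.extend({"file": str(p), "sha256": _sha256(p)} for p in paths)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
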