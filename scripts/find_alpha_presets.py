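"""Search for m values giving the Hopf-onset classes at alpha = -1.

With the path slope flipped (``alpha = -1``) the burster can enter the
oscillatory region through the supercritical Hopf line instead of the fold.
No published ``m`` values exist for these two scenarios, so this script
scans ``m`` over a grid, simulates each candidate, classifies the resulting
burster, and prints the ``m`` ranges that yield the SupH/SH and SupH/SupH
classes.  The representative values frozen in ``epimap.presets`` were chosen
as the midpoints of the ranges this search reports.

Run from the repository root:

    python scripts/find_alpha_presets.py [--fine] [--irest2 V]
"""

from __future__ import annotations

import argparse

import numpy as np

from epimap.bifurcations import bifurcation_set
from epimap.models import EpileptorParams, FastParams
from epimap.paths import classify_burster, detect_transitions
from epimap.simulate import SolveOptions, integrate, rest_initial_state


def classify_m(m: float, irest2: float, t_span=(0.0, 12000.0)) -> str:
    params = EpileptorParams(m=m, Irest2=irest2, x0=-2.0, alpha=-1.0)
    opts = SolveOptions(t_span=t_span, initial_state=rest_initial_state(params))
    try:
        traj = integrate("epileptor", params, opts)
    except Exception as exc:  # diverged candidates are reported, not fatal
        return f"error: {exc}"
    events = detect_transitions(traj, params=params)
    result = classify_burster(traj, bifurcation_set(FastParams()), events, params)
    return result.label


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fine", action="store_true", help="0.05 steps instead of 0.1")
    ap.add_argument("--irest2", type=float, default=0.0)
    ap.add_argument("--m-range", nargs=2, type=float, default=[0.2, 2.4])
    args = ap.parse_args()
    step = 0.05 if args.fine else 0.1
    ms = np.arange(args.m_range[0], args.m_range[1] + step / 2, step)
    by_label: dict[str, list[float]] = {}
    for m in ms:
        label = classify_m(float(m), args.irest2)
        by_label.setdefault(label, []).append(float(m))
        print(f"m={m:+.2f} Irest2={args.irest2}: {label}")
    print("\nSummary (label: m range):")
    for label, vals in sorted(by_label.items()):
        print(f"  {label:12s} m in [{min(vals):.2f}, {max(vals):.2f}] (n={len(vals)})")


if __name__ == "__main__":
    main()
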