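"""Paths on the map, seizure onset/offset detection and dynamotype labels.

During a burst the full Epileptor drags its fast subsystem through parameter
space along the algebraic path

    mu(z)        = Irest1 - z
    mbar(z, x2)  = 0.6*alpha*(z - 4)^2 + m - x2

so a simulated trajectory can be projected, sample by sample, onto the
``(mu, mbar)`` bifurcation map.  Crossings of the analytic curves along this
path are what start and stop the seizure, and the onset/offset bifurcation
pair is the burster's class (dynamotype): SN/SupH, SN/SH, SN/SN, SupH/SH or
SupH/SupH on this map.

Onsets and offsets of fast oscillations are detected from a sliding-window
amplitude envelope of the *detrended* ``x1`` (detrending removes the DC
baseline jumps of the SN transitions, which would otherwise register as
spurious amplitude).  An episode must outlast twice the envelope window to
count as an oscillation; shorter excursions are jump transients.  When no
oscillation episode exists at all, events are the branch alternations of the
depolarization-block (SN/SN) regime, detected as level crossings of the
smoothed ``x1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bifurcations import BifurcationSet, bifurcation_set
from .models import EpileptorParams, DTBParams, FastParams, Trajectory, mbar_of

__all__ = [
    "ProjectedPath",
    "BurstEvent",
    "BursterClassification",
    "project_path",
    "detect_transitions",
    "classify_burster",
    "x0_sweep",
    "dtb_path",
]

#: envelope window (time units): well above the fast period, well below burst length
ENVELOPE_WINDOW = 50.0
AMP_ON = 0.5
AMP_OFF = 0.2
#: x1 level separating the two fixed-point branches for SN/SN detection;
#: the unstable middle branch lies in (-4/3, 0) for the default coefficients
BRANCH_LEVEL = -0.7


@dataclass
class ProjectedPath:
    t: np.ndarray
    mu: np.ndarray
    mbar: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "mu": self.mu, "mbar": self.mbar})


@dataclass
class BurstEvent:
    kind: str  # "onset" | "offset"
    t: float
    mu: float
    mbar: float
    nearest_curve: str | None = None
    distance: float | None = None
    oscillatory: bool = True  # False for branch-switch (SN/SN) events


@dataclass
class BursterClassification:
    onset_type: str  # "SN" | "SupH" | "SH" | "none" | "ambiguous"
    offset_type: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.onset_type}/{self.offset_type}"


def project_path(traj: Trajectory, params: EpileptorParams) -> ProjectedPath:
    """Project a full-Epileptor trajectory onto the (mu, mbar) map.

    Pointwise algebraic map; no smoothing.  The raw ``x2`` enters ``mbar``.
    """
    if traj.model != "epileptor":
        raise ValueError("project_path expects a full-Epileptor trajectory")
    z = traj["z"]
    x2 = traj["x2"]
    return ProjectedPath(
        t=traj.times.copy(),
        mu=params.Irest1 - z,
        mbar=mbar_of(z, x2, params),
    )


def _moving_mean(x: np.ndarray, n: int) -> np.ndarray:
    c = np.cumsum(np.insert(x, 0, 0.0))
    out = (c[n:] - c[:-n]) / n
    pad_l = n // 2
    pad_r = x.size - out.size - pad_l
    return np.concatenate([np.full(pad_l, out[0]), out, np.full(pad_r, out[-1])])


def _sliding_ptp(x: np.ndarray, n: int) -> np.ndarray:
    from numpy.lib.stride_tricks import sliding_window_view

    pad = n // 2
    xp = np.pad(x, pad, mode="edge")
    w = sliding_window_view(xp, n)[: x.size]
    return w.max(axis=1) - w.min(axis=1)


def _oscillation_episodes(t, env, amp_on, amp_off, min_duration):
    """Hysteresis threshold crossings of the envelope, filtered by duration."""
    episodes = []
    active = False
    t_on = None
    for i in range(1, len(env)):
        if not active and env[i] >= amp_on and env[i - 1] < amp_on:
            active, t_on = True, t[i]
        elif active and env[i] <= amp_off and env[i - 1] > amp_off:
            active = False
            episodes.append((t_on, t[i]))
    return [(a, b) for a, b in episodes if b - a >= min_duration]


def _refine_onset(t, det, i_on, half_window, amp_on):
    """Move the onset mark to the first raw exceedance near the envelope crossing.

    The centred envelope leads a sharp jump by half a window; pinning the
    event to the first detrended excursion above threshold removes that bias
    so SN onsets land on the fold to within the slow drift per sample.
    """
    lo = np.searchsorted(t, t[i_on] - half_window)
    hi = min(len(t), np.searchsorted(t, t[i_on] + 2 * half_window))
    seg = np.abs(det[lo:hi])
    idx = np.flatnonzero(seg >= amp_on)
    return lo + idx[0] if idx.size else i_on


def _anchor_sustained_onset(env, i_on, i_off, n, amp_on):
    """Skip a leading jump transient: onset = first *persistent* exceedance.

    A fold transition rings for a few fast periods and fades, but its
    sliding-window envelope stays elevated for about one window length; a
    true oscillation onset stays above threshold indefinitely.  The onset is
    therefore moved to the first upward crossing of ``amp_on`` whose
    exceedance persists for 1.5 envelope windows (or to the episode end).
    When the initial crossing already persists -- the usual SN-onset case --
    it is kept unchanged.
    """
    hold = max(2, (3 * n) // 2)
    i = i_on
    while i < i_off:
        j = min(i + hold, i_off)
        if env[i:j].min() >= amp_on:
            return i
        # advance to the next upward crossing of amp_on
        below = np.flatnonzero(env[i:i_off] < amp_on)
        if not below.size:
            return i
        k = i + below[0]
        up = np.flatnonzero(env[k:i_off] >= amp_on)
        if not up.size:
            return i_on
        i = k + up[0]
    return i_on


def detect_transitions(
    traj: Trajectory,
    envelope_window: float = ENVELOPE_WINDOW,
    amp_on: float = AMP_ON,
    amp_off: float = AMP_OFF,
    params: EpileptorParams | None = None,
) -> list[BurstEvent]:
    """Detect seizure onsets and offsets in a full-Epileptor trajectory.

    Returns alternating onset/offset events.  Oscillation episodes come from
    a hysteresis (``amp_on > amp_off``) threshold on the sliding-window
    amplitude envelope of detrended ``x1``; an episode shorter than twice the
    window is discarded as a jump transient.  If no oscillation episode
    exists, branch alternations (SN/SN regime) are detected instead as
    crossings of smoothed ``x1`` through the inter-branch level, and flagged
    ``oscillatory=False``.
    """
    if amp_on <= amp_off:
        raise ValueError("hysteresis requires amp_on > amp_off")
    x1 = traj["x1"]
    t = traj.times
    n = max(3, int(round(envelope_window / traj.dt)))
    baseline = _moving_mean(x1, n)
    det = x1 - baseline
    env = _sliding_ptp(det, n)
    episodes = _oscillation_episodes(t, env, amp_on, amp_off, 2.0 * envelope_window)

    path = project_path(traj, params) if params is not None else None

    def _event(kind, i, oscillatory=True):
        return BurstEvent(
            kind=kind,
            t=float(t[i]),
            mu=float(path.mu[i]) if path else np.nan,
            mbar=float(path.mbar[i]) if path else np.nan,
            oscillatory=oscillatory,
        )

    events: list[BurstEvent] = []
    if episodes:
        for t_on, t_off in episodes:
            i_on = int(np.searchsorted(t, t_on))
            i_off = int(np.searchsorted(t, t_off))
            i_on = _anchor_sustained_onset(env, i_on, i_off, n, amp_on)
            i_on = _refine_onset(t, det, i_on, envelope_window / 2.0, amp_on)
            events.append(_event("onset", i_on))
            events.append(_event("offset", i_off))
        return events

    # no sustained oscillation: branch alternation (depolarization block)
    lv = baseline > BRANCH_LEVEL
    sw = np.diff(lv.astype(int))
    for i in np.flatnonzero(sw != 0):
        kind = "onset" if sw[i] > 0 else "offset"
        events.append(_event(kind, i + 1, oscillatory=False))
    # enforce onset-first alternation
    while events and events[0].kind == "offset":
        events.pop(0)
    return events


def _isi_trend(t, det, t_on, t_off, min_height=0.15):
    """Peak times within an episode; returns (median ISI, last ISI)."""
    from scipy.signal import find_peaks

    lo, hi = np.searchsorted(t, (t_on, t_off))
    seg = det[lo:hi]
    pk, _ = find_peaks(seg, height=min_height)
    if pk.size < 4:
        return np.nan, np.nan
    isi = np.diff(t[lo + pk])
    return float(np.median(isi)), float(isi[-1])


def classify_burster(
    traj: Trajectory,
    curves: BifurcationSet | None,
    events: list[BurstEvent] | None = None,
    params: EpileptorParams | None = None,
) -> BursterClassification:
    """Assign onset/offset bifurcation types to a bursting trajectory.

    Requires at least one complete burst.  The *last* complete oscillation
    episode is classified (earlier ones include the start-up transient):

    * onset type: nearest analytic curve at the onset path point -- the
      ``SN-`` fold line in ``mu`` versus the Hopf line in ``mbar`` --
      cross-checked by the amplitude at onset (a finite jump for SN, growth
      from zero for SupH);
    * offset type: the side of the Hopf line at the offset point (above:
      the cycle dies on the saddle-homoclinic; below: it shrank to zero at
      the supercritical Hopf), cross-checked by the inter-peak-interval
      trend (a diverging ISI marks SH).  Disagreement yields "ambiguous"
      with both candidates in the diagnostics;
    * no oscillation episodes but branch alternations: the SN/SN
      (depolarization-block) class;
    * no events at all: "none/none" (whole system at a fixed point).
    """
    if params is None:
        params = EpileptorParams()
    if curves is None:
        curves = bifurcation_set(FastParams())
    if events is None:
        events = detect_transitions(traj, params=params)
    diagnostics: dict = {"n_events": len(events)}
    if not events:
        return BursterClassification("none", "none", diagnostics)

    osc_events = [e for e in events if e.oscillatory]
    if not osc_events:
        diagnostics["mechanism"] = "branch alternation without oscillation"
        return BursterClassification("SN", "SN", diagnostics)

    onsets = [e for e in osc_events if e.kind == "onset"]
    offsets = [e for e in osc_events if e.kind == "offset"]
    pairs = [
        (on, off)
        for on, off in zip(onsets, offsets)
        if off.t > on.t
    ]
    if not pairs:
        return BursterClassification("none", "none", diagnostics)
    onset, offset = pairs[-1]

    sn_minus = curves.sn.sn_minus
    hopf_mbar = curves.hopf.mbar

    d_sn = abs(onset.mu - sn_minus)
    d_hopf = abs(onset.mbar - hopf_mbar)
    onset_type = "SN" if d_sn <= d_hopf else "SupH"
    diagnostics["onset"] = {
        "t": onset.t,
        "mu": onset.mu,
        "mbar": onset.mbar,
        "dist_sn_minus": d_sn,
        "dist_hopf": d_hopf,
    }
    onset.nearest_curve = "SN-" if onset_type == "SN" else "Hopf"
    onset.distance = min(d_sn, d_hopf)

    x1 = traj["x1"]
    t = traj.times
    n = max(3, int(round(ENVELOPE_WINDOW / traj.dt)))
    det = x1 - _moving_mean(x1, n)
    isi_med, isi_last = _isi_trend(t, det, onset.t, offset.t)
    isi_ratio = isi_last / isi_med if np.isfinite(isi_med) and isi_med > 0 else np.nan
    offset_above_hopf = offset.mbar > hopf_mbar
    curve_vote = "SH" if offset_above_hopf else "SupH"
    isi_vote = "SH" if (np.isfinite(isi_ratio) and isi_ratio > 1.8) else "SupH"
    offset_type = curve_vote if curve_vote == isi_vote else "ambiguous"
    diagnostics["offset"] = {
        "t": offset.t,
        "mu": offset.mu,
        "mbar": offset.mbar,
        "isi_median": isi_med,
        "isi_last": isi_last,
        "isi_ratio": isi_ratio,
        "curve_vote": curve_vote,
        "isi_vote": isi_vote,
    }
    offset.nearest_curve = "SH" if curve_vote == "SH" else "Hopf"

    # DC shift: baseline level change between pre-onset and ictal segments
    i_on = int(np.searchsorted(t, onset.t))
    i_off = int(np.searchsorted(t, offset.t))
    pre = slice(max(0, i_on - 5 * n), max(1, i_on - n))
    ictal = slice(i_on, max(i_on + 1, i_off))
    dc = float(np.median(x1[ictal]) - np.median(x1[pre]))
    diagnostics["dc_shift"] = dc
    diagnostics["has_dc_shift"] = bool(abs(dc) > 0.5)

    return BursterClassification(onset_type, offset_type, diagnostics)


def _burst_durations(events: list[BurstEvent]) -> tuple[list[float], list[float]]:
    """(interictal, ictal) durations from alternating events, skipping the
    first burst (start-up transient)."""
    ev = sorted(events, key=lambda e: e.t)
    ictal, interictal = [], []
    for a, b in zip(ev, ev[1:]):
        if a.kind == "onset" and b.kind == "offset":
            ictal.append(b.t - a.t)
        elif a.kind == "offset" and b.kind == "onset":
            interictal.append(b.t - a.t)
    return interictal[1:] if len(interictal) > 1 else interictal, (
        ictal[1:] if len(ictal) > 1 else ictal
    )


def _resample_by_arclength(mu: np.ndarray, mbar: np.ndarray, n: int = 400):
    d = np.hypot(np.diff(mu), np.diff(mbar))
    s = np.concatenate([[0.0], np.cumsum(d)])
    if s[-1] == 0:
        return np.full(n, mu[0]), np.full(n, mbar[0])
    u = np.linspace(0.0, s[-1], n)
    return np.interp(u, s, mu), np.interp(u, s, mbar)


def x0_sweep(
    base_params: EpileptorParams,
    x0_values,
    t_span=(0.0, 8000.0),
    z0: float = 3.0,
) -> dict[float, dict]:
    """Rerun the burster for several epileptogenicity values.

    For each ``x0``: the projected path over the last complete burst cycle
    (arc-length resampled), the interictal and ictal durations, and the
    per-burst count of intermediate spikes (local maxima of ``x2`` above its
    resting level).  An ``x0`` for which the whole system settles to a fixed
    point is flagged ``no_bursting``.
    """
    from .simulate import SolveOptions, integrate, rest_initial_state

    out: dict[float, dict] = {}
    for x0 in x0_values:
        p = base_params.replace(x0=float(x0))
        opts = SolveOptions(t_span=tuple(t_span), initial_state=rest_initial_state(p, z0))
        traj = integrate("epileptor", p, opts)
        events = detect_transitions(traj, params=p)
        entry: dict = {"x0": float(x0), "n_events": len(events)}
        onsets = [e for e in events if e.kind == "onset"]
        if len(onsets) < 2:
            entry["no_bursting"] = True
            out[float(x0)] = entry
            continue
        entry["no_bursting"] = False
        interictal, ictal = _burst_durations(events)
        entry["interictal_duration"] = float(np.median(interictal)) if interictal else np.nan
        entry["ictal_duration"] = float(np.median(ictal)) if ictal else np.nan
        # one full cycle: last onset-to-onset interval
        path = project_path(traj, p)
        i0 = int(np.searchsorted(traj.times, onsets[-2].t))
        i1 = int(np.searchsorted(traj.times, onsets[-1].t))
        mu_r, mbar_r = _resample_by_arclength(path.mu[i0:i1], path.mbar[i0:i1])
        entry["path"] = np.column_stack([mu_r, mbar_r])
        # intermediate spikes per burst: x2 peaks above rest during the cycle
        from scipy.signal import find_peaks

        x2 = traj["x2"][i0:i1]
        pk, _ = find_peaks(x2, height=0.0, prominence=0.5)
        entry["spikes_per_burst"] = int(pk.size)
        out[float(x0)] = entry
    return out


def path_overlap(path_a: np.ndarray, path_b: np.ndarray) -> float:
    """Mismatch between two cycle polylines, as a fraction of path extent.

    Symmetric Hausdorff distance between the two point sets divided by the
    arc length of the first polyline.  0 means the paths coincide.
    """
    d2 = ((path_a[:, None, :] - path_b[None, :, :]) ** 2).sum(-1)
    h = max(np.sqrt(d2.min(1)).max(), np.sqrt(d2.min(0)).max())
    arclen = np.hypot(*np.diff(path_a, axis=0).T).sum()
    return float(h / arclen) if arclen > 0 else float("inf")


def dtb_path(params: DTBParams, traj: Trajectory) -> np.ndarray:
    """Project a DTB trajectory onto its (mu1, nu) plane (affine in z).

    Returns an array with columns ``(mu1, nu)``; the points lie exactly on
    the straight path line by construction.
    """
    if traj.model != "dtb":
        raise ValueError("dtb_path expects a DTB trajectory")
    z = traj["z"]
    return np.column_stack([params.mu1_0 + params.d_mu1 * z, params.nu_0 + params.d_nu * z])
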