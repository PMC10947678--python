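"""Path projection, event detection and dynamotype classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from epimap.models import DTBParams, EpileptorParams, Trajectory, mbar_of
from epimap.paths import (
    classify_burster,
    detect_transitions,
    dtb_path,
    path_overlap,
    project_path,
)
from epimap.presets import get_preset


class TestProjectPath:
    def test_algebraic_identity(self, sn_sh_run):
        """The projection satisfies its defining formulas at every sample."""
        traj, _ = sn_sh_run
        p = get_preset("sn_sh").make_params()
        path = project_path(traj, p)
        np.testing.assert_array_equal(path.mu, p.Irest1 - traj["z"])
        np.testing.assert_allclose(
            path.mbar,
            0.6 * p.alpha * (traj["z"] - 4.0) ** 2 + p.m - traj["x2"],
            rtol=0,
            atol=1e-12,
        )

    @given(z=st.floats(-2.0, 6.0), x2=st.floats(-3.0, 3.0))
    def test_mu_zero_when_z_equals_drive(self, z, x2):
        p = EpileptorParams()
        tr = Trajectory(np.array([0.0]), np.array([[0.0, 0.0, z, x2, 0.0, 0.0]]))
        path = project_path(tr, p)
        assert path.mu[0] == pytest.approx(p.Irest1 - z)
        assert path.mbar[0] == pytest.approx(mbar_of(z, x2, p))

    def test_spikes_in_path_only_with_intermediate_bursting(
        self, original_run, sn_sh_run
    ):
        """Irest2 = 0.45 puts fast mbar excursions in the ictal path;
        Irest2 = 0 gives a smooth path."""

        def ictal_mbar_wiggle(run, name):
            traj, _ = run
            p = get_preset(name).make_params()
            path = project_path(traj, p)
            events = detect_transitions(traj, params=p)
            on = [e for e in events if e.kind == "onset"][-1]
            off = [e for e in events if e.kind == "offset"][-1]
            sl = slice(
                np.searchsorted(traj.times, on.t), np.searchsorted(traj.times, off.t)
            )
            mbar = path.mbar[sl]
            # detrended high-frequency content of the path
            k = 101
            kernel = np.ones(k) / k
            smooth = np.convolve(mbar, kernel, mode="same")
            return np.abs(mbar - smooth)[k:-k].max()

        assert ictal_mbar_wiggle(original_run, "original") > 0.5
        assert ictal_mbar_wiggle(sn_sh_run, "sn_sh") < 0.2

    def test_rejects_wrong_model(self, dtb_run):
        traj, _ = dtb_run
        with pytest.raises(ValueError):
            project_path(traj, EpileptorParams())


class TestDetectTransitions:
    def test_constant_trajectory_has_no_events(self):
        t = np.arange(0.0, 500.0, 0.1)
        states = np.tile([0.3, -1.0, 3.0, 0.0, 0.0, 0.0], (len(t), 1))
        tr = Trajectory(t, states)
        assert detect_transitions(tr, params=EpileptorParams()) == []

    def test_alternating_equal_counts(self, sn_sh_run):
        traj, _ = sn_sh_run
        events = detect_transitions(traj, params=get_preset("sn_sh").make_params())
        kinds = [e.kind for e in events]
        assert kinds == ["onset", "offset"] * (len(kinds) // 2)

    def test_sn_onset_lands_on_fold(self, sn_sh_run, default_curves):
        """Detected onset mu is within 5% of the analytic SN- value."""
        traj, _ = sn_sh_run
        events = detect_transitions(traj, params=get_preset("sn_sh").make_params())
        onset = [e for e in events if e.kind == "onset"][-1]
        sn_minus = default_curves.sn.sn_minus
        assert abs(onset.mu - sn_minus) <= 0.05 * abs(sn_minus)

    def test_suph_onset_near_hopf_line(self, suph_sh_run, default_curves):
        """A Hopf onset is detected near mbar = -N.

        Deterministic slow passage delays the detectable oscillation, so the
        match is loose (25%) compared to the fold case.
        """
        traj, _ = suph_sh_run
        events = detect_transitions(traj, params=get_preset("suph_sh").make_params())
        onset = [e for e in events if e.kind == "onset"][-1]
        assert abs(onset.mbar - default_curves.hopf.mbar) <= 0.25
        # and it is unambiguously not a fold onset
        assert abs(onset.mu - default_curves.sn.sn_minus) > 0.3

    def test_hysteresis_validation(self, sn_sh_run):
        traj, _ = sn_sh_run
        with pytest.raises(ValueError, match="amp_on > amp_off"):
            detect_transitions(traj, amp_on=0.1, amp_off=0.2)


class TestClassifyBurster:
    @pytest.mark.parametrize(
        "fixture_name, expected",
        [
            ("original_run", "SN/SupH"),
            ("sn_sh_run", "SN/SH"),
            ("depol_block_run", "SN/SN"),
            ("suph_sh_run", "SupH/SH"),
            ("suph_suph_run", "SupH/SupH"),
        ],
    )
    def test_preset_labels(self, fixture_name, expected, request, default_curves):
        traj, _ = request.getfixturevalue(fixture_name)
        preset = {
            "original_run": "original",
            "sn_sh_run": "sn_sh",
            "depol_block_run": "depol_block",
            "suph_sh_run": "suph_sh",
            "suph_suph_run": "suph_suph",
        }[fixture_name]
        p = get_preset(preset).make_params()
        events = detect_transitions(traj, params=p)
        result = classify_burster(traj, default_curves, events, p)
        assert result.label == expected

    def test_sn_classes_show_dc_shift(self, sn_sh_run, default_curves):
        traj, _ = sn_sh_run
        p = get_preset("sn_sh").make_params()
        result = classify_burster(traj, default_curves, params=p)
        assert result.diagnostics["has_dc_shift"]

    def test_hysteresis_loop_has_area(self, sn_sh_run, original_run, default_curves):
        """Onset and offset map locations are distinct for hysteresis bursters."""
        for run, name in ((sn_sh_run, "sn_sh"), (original_run, "original")):
            traj, _ = run
            p = get_preset(name).make_params()
            result = classify_burster(traj, default_curves, params=p)
            on, off = result.diagnostics["onset"], result.diagnostics["offset"]
            gap = np.hypot(on["mu"] - off["mu"], on["mbar"] - off["mbar"])
            assert gap > 0.1

    def test_label_concatenation(self, sn_sh_run, default_curves):
        traj, _ = sn_sh_run
        p = get_preset("sn_sh").make_params()
        res = classify_burster(traj, default_curves, params=p)
        assert res.label == f"{res.onset_type}/{res.offset_type}"


class TestDTBPath:
    def test_path_exactly_on_line(self, dtb_run):
        traj, _ = dtb_run
        params = get_preset("dtb_sn_sh").make_params()
        pts = dtb_path(params, traj)
        # every point satisfies the affine relation in z exactly
        z = traj["z"]
        np.testing.assert_array_equal(pts[:, 0], params.mu1_0 + params.d_mu1 * z)
        np.testing.assert_array_equal(pts[:, 1], params.nu_0 + params.d_nu * z)

    def test_hysteresis_sequence(self, dtb_run):
        """Rest -> fold -> cycle -> homoclinic -> rest, i.e. the slow
        variable alternates direction and x alternates rest/oscillation."""
        traj, _ = dtb_run
        x = traj["x"]
        blk = 2000  # 1000-time-unit blocks
        amps = np.array(
            [np.ptp(x[i : i + blk]) for i in range(0, len(x) - blk, blk)]
        )
        assert amps.max() > 0.5  # oscillatory phases
        assert amps.min() < 0.1  # resting phases
        # multiple alternations
        ictal = amps > 0.3
        assert np.abs(np.diff(ictal.astype(int))).sum() >= 3

    def test_degenerate_z_maps_to_point(self):
        params = DTBParams()
        t = np.arange(0.0, 1.0, 0.1)
        states = np.tile([0.2, 0.0, 1.5], (len(t), 1))
        tr = Trajectory(t, states, model="dtb", columns=("x", "y", "z"))
        pts = dtb_path(params, tr)
        assert np.ptp(pts[:, 0]) == 0.0
        assert np.ptp(pts[:, 1]) == 0.0


class TestPathOverlap:
    def test_identical_paths(self):
        a = np.column_stack([np.linspace(0, 1, 50), np.sin(np.linspace(0, 3, 50))])
        assert path_overlap(a, a) == 0.0

    def test_shifted_path_measures_offset(self):
        a = np.column_stack([np.linspace(0, 1, 50), np.zeros(50)])
        b = a + [0.0, 0.05]
        assert path_overlap(a, b) == pytest.approx(0.05, rel=1e-6)
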