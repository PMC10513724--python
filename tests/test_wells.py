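"""Well panels: quantification, limit of detection, saturation flags,
depth response and signal-to-background ratio."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fgscheck as f
from fgscheck.errors import GeometryError, LayoutError, PanelError
from fgscheck.io_config import Image2D, RoiSpec, WellSpec
from fgscheck.wells import WellMeasurement, WellPanelResult


def make_panel(entries, floor_mean=0.0, floor_sd=2.0, bit_depth=16):
    """Hand-built panel: entries are (concentration_nm, mean, sd)."""
    ms = [
        WellMeasurement(
            label=f"{c:g} nM",
            role="sample",
            concentration_nm=c,
            depth_mm=None,
            mean=m,
            sd=s,
            mean_norm=0.0,
            sd_norm=0.0,
        )
        for (c, m, s) in entries
    ]
    ctrl = WellMeasurement(
        label="control",
        role="control",
        concentration_nm=0.0,
        depth_mm=None,
        mean=floor_mean,
        sd=floor_sd,
        mean_norm=0.0,
        sd_norm=0.0,
    )
    return WellPanelResult(
        wells=tuple(ms) + (ctrl,),
        qd800=None,
        noise_floor_mean=floor_mean,
        noise_floor_sd=floor_sd,
        bit_depth=bit_depth,
    )


class TestQuantifyWells:
    def test_noiseless_means_match_forward_model(self, conc_panel):
        img, gt = conc_panel
        panel = f.quantify_wells(img, gt.layout.wells)
        floor, g = gt.params["floor"], gt.params["gain_per_nm"]
        sat = gt.params["saturation_level"]
        for w in panel.wells:
            if w.role == "sample":
                assert w.mean == pytest.approx(
                    min(floor + g * w.concentration_nm, sat)
                )
        assert max(w.mean_norm for w in panel.wells) == pytest.approx(1.0)

    def test_qd800_reported_separately(self):
        img, gt = f.render_wells("conc", qd800_leak=70000.0)
        panel = f.quantify_wells(img, gt.layout.wells)
        assert panel.qd800 is not None
        assert all(w.role != "qd800" for w in panel.wells)
        # QD800 pegged at full scale must not rescale the ICG series
        top = max(w.mean for w in panel.wells)
        assert panel.well("1000 nM").mean_norm == pytest.approx(
            panel.well("1000 nM").mean / top
        )

    def test_missing_control_rejected(self, conc_panel):
        img, gt = conc_panel
        wells = [w for w in gt.layout.wells if w.role != "control"]
        with pytest.raises(PanelError):
            f.quantify_wells(img, wells)

    def test_overlapping_wells_rejected(self, conc_panel):
        img, _ = conc_panel
        a = WellSpec(RoiSpec("a", "circle", circle=(60, 60, 18)), concentration_nm=10)
        b = WellSpec(RoiSpec("b", "circle", circle=(60, 80, 18)), concentration_nm=3)
        ctrl = WellSpec(RoiSpec("c", "circle", circle=(120, 60, 18)), role="control")
        with pytest.raises(LayoutError):
            f.quantify_wells(img, [a, b, ctrl])

    def test_all_wells_equal_control(self):
        img = Image2D(pixels=np.full((240, 240), 500.0), bit_depth=16)
        wells = [
            WellSpec(RoiSpec("a", "circle", circle=(60, 60, 18)), concentration_nm=10),
            WellSpec(RoiSpec("b", "circle", circle=(60, 120, 18)), concentration_nm=3),
            WellSpec(RoiSpec("c", "circle", circle=(120, 60, 18)), role="control"),
        ]
        panel = f.quantify_wells(img, wells)
        assert len({w.mean_norm for w in panel.wells}) == 1
        panel = f.detect_floor_and_saturation(panel)
        assert panel.lod_concentration_nm is None
        assert panel.lod_undefined


class TestFloorAndSaturation:
    def test_lod_three_sigma_rule_by_hand(self):
        """Control (0, sd 2): criterion is 6; a 1 nM well at 1 fails it and
        a 3 nM well at 10 passes, so LoD = 3 nM."""
        panel = make_panel([(1.0, 1.0, 0.5), (3.0, 10.0, 0.5)])
        out = f.detect_floor_and_saturation(panel, k_sigma=3)
        assert out.lod_concentration_nm == 3.0

    def test_no_saturation_when_strictly_increasing_below_full_scale(self):
        panel = make_panel([(1, 100, 1), (10, 1000, 1), (100, 10000, 1), (1000, 40000, 1)])
        out = f.detect_floor_and_saturation(panel)
        assert out.saturated_labels == ()

    def test_wells_at_full_scale_flagged(self):
        panel = make_panel(
            [(100, 20000, 1), (300, 65535, 1), (1000, 65535, 1)], floor_sd=1.0
        )
        out = f.detect_floor_and_saturation(panel)
        assert out.saturated_labels == ("1000 nM", "300 nM")
        assert out.well("300 nM").saturated and not out.well("100 nM").saturated

    def test_display_ceiling_below_full_scale_flagged_by_plateau(self):
        img, gt = f.render_wells("conc", saturation_level=50000.0)
        panel = f.detect_floor_and_saturation(f.quantify_wells(img, gt.layout.wells))
        assert panel.saturated_labels == ("1000 nM", "300 nM")

    def test_floor_plateau_not_flagged_as_saturation(self, conc_panel):
        """Wells indistinguishable down at the noise floor (1 vs 3 nM on a
        16-bit scale) are not saturation."""
        img, gt = conc_panel
        panel = f.detect_floor_and_saturation(f.quantify_wells(img, gt.layout.wells))
        assert panel.saturated_labels == ("1000 nM", "300 nM")


class TestDepthResponse:
    def test_attenuation_fit_recovers_truth_noiseless(self, depth_panel):
        img, gt = depth_panel
        panel = f.quantify_wells(img, gt.layout.wells)
        summary = f.depth_response(panel)
        assert summary.d_att_mm == pytest.approx(gt.params["d_att_mm"], rel=0.05)
        assert summary.fit_r2 > 0.999

    def test_means_strictly_decreasing_in_depth(self, depth_panel):
        img, gt = depth_panel
        panel = f.quantify_wells(img, gt.layout.wells)
        means = [
            w.mean
            for w in sorted(
                (w for w in panel.wells if w.role == "sample"),
                key=lambda w: w.depth_mm,
            )
        ]
        assert all(a > b for a, b in zip(means[:-1], means[1:]))

    def test_designed_boundary_at_4mm(self):
        """Panel engineered so wells at 4 mm and shallower clear the 3-sigma
        criterion while 5 and 6 mm sink into the control band."""
        cam = f.CameraModel(read_noise_sd=30.0)
        img, gt = f.render_wells(
            "depth", camera=cam, i0=40000.0, d_att_mm=0.8, floor=100.0, seed=5
        )
        panel = f.quantify_wells(img, gt.layout.wells)
        summary = f.depth_response(panel)
        assert summary.max_reliable_depth_mm == 4.0

    def test_all_below_criterion_undefined(self):
        img = Image2D(pixels=np.full((240, 240), 500.0), bit_depth=16)
        wells = [
            WellSpec(RoiSpec("a", "circle", circle=(60, 60, 18)), depth_mm=1.0),
            WellSpec(RoiSpec("b", "circle", circle=(60, 120, 18)), depth_mm=2.0),
            WellSpec(RoiSpec("c", "circle", circle=(120, 60, 18)), role="control"),
        ]
        summary = f.depth_response(f.quantify_wells(img, wells))
        assert summary.max_reliable_depth_mm is None
        assert summary.fit_skipped_reason is not None


def disk_wells(values, background, shape=(200, 200), radius=15.0):
    """Constant image with constant-valued disks; returns (image, wells)."""
    pixels = np.full(shape, float(background))
    wells = []
    for i, v in enumerate(values):
        center = (60.0 + 80.0 * (i // 2), 60.0 + 80.0 * (i % 2))
        roi = RoiSpec(f"w{i}", "circle", circle=(*center, radius))
        wells.append(WellSpec(roi=roi, depth_mm=float(i + 2)))
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        pixels[(rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2] = v
    return Image2D(pixels=pixels, bit_depth=16), wells


class TestSbr:
    def test_equal_signal_and_background_is_0db(self):
        img, wells = disk_wells([700.0], background=700.0)
        res = f.compute_sbr(img, wells)
        assert res.panel_sbr_db == pytest.approx(0.0, abs=1e-12)

    def test_tenfold_amplitude_is_20db(self):
        img, wells = disk_wells([5000.0], background=500.0)
        res = f.compute_sbr(img, wells)
        assert res.panel_sbr_db == pytest.approx(20.0, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 60.0))
    def test_invariant_to_global_scaling(self, scale):
        img, wells = disk_wells([800.0], background=100.0)
        scaled = Image2D(pixels=img.pixels * scale, bit_depth=32)
        a = f.compute_sbr(img, wells)
        b = f.compute_sbr(scaled, wells)
        assert b.panel_sbr_db == pytest.approx(a.panel_sbr_db, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(offset=st.floats(10.0, 5000.0))
    def test_background_lift_strictly_decreases_sbr(self, offset):
        img, wells = disk_wells([8000.0], background=100.0)
        lifted_px = img.pixels.copy()
        mask = wells[0].roi.mask(img.shape)
        lifted_px[~mask] += offset
        lifted = Image2D(pixels=lifted_px, bit_depth=32)
        assert (
            f.compute_sbr(lifted, wells).panel_sbr_db
            < f.compute_sbr(img, wells).panel_sbr_db
        )

    def test_panel_value_is_mean_over_designated_wells(self, depth_panel):
        img, gt = depth_panel
        chosen = f.sbr_wells_from_layout(gt.layout.wells)
        assert sorted(w.depth_mm for w in chosen) == [2.0, 3.0, 4.0]
        res = f.compute_sbr(img, chosen)
        assert res.panel_sbr_db == pytest.approx(
            np.mean([w.sbr_db for w in res.wells])
        )

    def test_annulus_collision_rejected(self, depth_panel):
        img, gt = depth_panel
        chosen = f.sbr_wells_from_layout(gt.layout.wells)
        with pytest.raises(GeometryError):
            f.compute_sbr(img, chosen, annulus_factor=2.5)
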