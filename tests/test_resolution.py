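"""USAF arithmetic, CTF percentile formula (with an independent
brute-force oracle), sharpness ladders and depth-of-field curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fgscheck as f
from fgscheck.errors import DomainError, FgsCheckError
from fgscheck.io_config import Image2D, RoiSpec
from fgscheck.resolution import SHARPNESS_ELEMENTS


def brute_force_ctf(values):
    """Direct evaluation of the contrast formula on a pixel set, written
    independently of the library path: plain Python sort, top/bottom 20%
    (counts rounded up), CTF = 100 (max - min) / (max + min)."""
    v = sorted(float(x) for x in values)
    k = max(1, math.ceil(0.2 * len(v)))
    mx = sum(v[-k:]) / k
    mn = sum(v[:k]) / k
    return 100.0 * (mx - mn) / (mx + mn)


class TestUsafArithmetic:
    @pytest.mark.parametrize(
        "group, element, lp, width_um",
        [
            (0, 1, 1.0, 500.0),  # coarsest standard element
            (7, 6, 228.1, 2.19),  # finest, at display rounding
            (2, 5, 6.35, 78.75),
        ],
    )
    def test_lp_per_mm_table(self, group, element, lp, width_um):
        el = f.usaf_lp_per_mm(group, element)
        assert round(el.lp_per_mm, 2 if lp < 100 else 1) == lp
        assert round(el.line_width_um, 2) == width_um
        # exact relation, not just display values
        assert el.lp_per_mm == pytest.approx(2 ** (group + (element - 1) / 6), rel=1e-12)
        assert el.line_width_um == pytest.approx(1000 / (2 * el.lp_per_mm), rel=1e-12)

    def test_element_out_of_range(self):
        with pytest.raises(DomainError):
            f.usaf_lp_per_mm(0, 7)


class TestComputeCtf:
    def test_ideal_bars_give_100(self, usaf_image):
        img, gt = usaf_image
        roi = gt.layout.roi("g0e1_h")
        res = f.compute_ctf(img, roi)
        assert res.ctf_percent == pytest.approx(100.0)

    def test_constant_region_gives_0(self):
        img = Image2D(pixels=np.full((32, 32), 500.0), bit_depth=16)
        res = f.compute_ctf(img, RoiSpec("r", "rect", rect=(4, 4, 16, 16)))
        assert res.ctf_percent == pytest.approx(0.0)
        assert not res.degenerate

    def test_hand_constructed_extrema(self):
        """ROI engineered so the top-20% mean is 75 and bottom-20% mean is
        25: CTF must be exactly 50."""
        vals = np.concatenate(
            [np.full(20, 25.0), np.full(60, 50.0), np.full(20, 75.0)]
        )
        rng = np.random.default_rng(0)
        pixels = np.full((32, 32), 50.0)
        pixels[10, :20] = 25.0
        block = rng.permutation(vals).reshape(10, 10)
        pixels[:10, :10] = block
        img = Image2D(pixels=pixels, bit_depth=8 if pixels.max() < 255 else 16)
        res = f.compute_ctf(img, RoiSpec("r", "rect", rect=(0, 0, 10, 10)))
        assert res.max_r == pytest.approx(75.0)
        assert res.min_r == pytest.approx(25.0)
        assert res.ctf_percent == pytest.approx(50.0)

    def test_all_dark_roi_degenerate(self, usaf_image):
        img, _ = usaf_image
        res = f.compute_ctf(img, RoiSpec("dark", "rect", rect=(0, 0, 8, 8)))
        assert res.degenerate
        assert math.isnan(res.ctf_percent)

    def test_threshold_domain(self, usaf_image):
        img, gt = usaf_image
        roi = gt.layout.roi("g0e1_h")
        with pytest.raises(DomainError):
            f.compute_ctf(img, roi, background_threshold=0.05)
        res = f.compute_ctf(img, roi, background_threshold=0.4)
        assert res.threshold_used == 0.4

    def test_mild_blur_keeps_ctf_above_95(self):
        """In focus with blur well below the bar width (sigma = 0.1 bar
        widths), the coarsest element stays above 95% contrast."""
        cam = f.CameraModel(sigma0_px=0.5)  # bar width is 5 px at 10 px/mm
        img, gt = f.render_usaf([(0, 1)], 10.0, cam)
        rois = f.element_rois_from_layout(gt.layout)[0]
        assert f.element_ctf(img, rois).ctf_percent >= 95.0

    def test_oracle_equivalence_on_rendered_bars(self, sharpness_render):
        """compute_ctf agrees with a brute-force evaluation of the contrast
        formula over the same pixel set to 1e-9 relative."""
        img, gt = sharpness_render
        for roi in gt.layout.rois:
            res = f.compute_ctf(img, roi)
            expected = brute_force_ctf(roi.extract(img))
            assert res.ctf_percent == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.01, 100.0),
    )
    def test_bounds_and_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        pixels = rng.uniform(0, 1000, size=(24, 24))
        img1 = Image2D(pixels=pixels, bit_depth=16)
        img2 = Image2D(pixels=np.clip(pixels * scale, 0, 65535), bit_depth=16)
        roi = RoiSpec("r", "rect", rect=(2, 2, 20, 20))
        r1, r2 = f.compute_ctf(img1, roi), f.compute_ctf(img2, roi)
        assert 0.0 <= r1.ctf_percent <= 100.0
        if pixels.max() * scale <= 65535:  # no clipping occurred
            assert r2.ctf_percent == pytest.approx(r1.ctf_percent, rel=1e-9)


def oracle_bar_ctf(bar_width_px: float, sigma: float) -> float:
    """Independent 1-D oracle: convolve an ideal three-bar profile with a
    Gaussian kernel and apply the percentile contrast formula."""
    from scipy.ndimage import gaussian_filter1d

    n = int(round(5 * bar_width_px))
    coords = np.arange(n) + 0.5
    phase = np.floor(coords / bar_width_px).astype(int)
    profile = np.where((phase % 2 == 0) & (phase < 5), 1.0, 0.0)
    if sigma > 0:
        profile = gaussian_filter1d(profile, sigma, mode="nearest")
    return brute_force_ctf(profile)


class TestSharpnessCurve:
    def test_no_blur_all_elements_100(self, sharpness_render):
        img, gt = sharpness_render
        res = f.sharpness_curve(img, f.element_rois_from_layout(gt.layout))
        assert len(res.results) == 9
        for r in res.results:
            assert r.ctf_percent == pytest.approx(100.0)
        assert res.resolving_limit_lp_mm == pytest.approx(6.3496, abs=1e-3)

    def test_blur_makes_ctf_decrease_with_lp(self):
        """With blur of one bar-width of the 4 lp/mm element, CTF drops
        strictly with spatial frequency while elements stay resolved (bar
        width >= 2 sigma), and unresolved elements sit below all resolved
        ones; the 1-D convolution oracle shows the same strict decrease."""
        px_per_mm = 40.0
        sigma = px_per_mm / (2 * 4.0)  # one bar width of the 4.0 lp/mm element
        cam = f.CameraModel(sigma0_px=sigma)
        img, gt = f.render_usaf(SHARPNESS_ELEMENTS, px_per_mm, cam)
        res = f.sharpness_curve(img, f.element_rois_from_layout(gt.layout))
        widths = [px_per_mm / (2 * r.element.lp_per_mm) for r in res.results]
        resolved = [
            r.ctf_percent for r, w in zip(res.results, widths) if w >= 2 * sigma
        ]
        unresolved = [
            r.ctf_percent for r, w in zip(res.results, widths) if w < 2 * sigma
        ]
        assert len(resolved) >= 3
        assert all(a > b for a, b in zip(resolved[:-1], resolved[1:]))
        assert all(u < min(resolved) for u in unresolved)
        oracle = [oracle_bar_ctf(w, sigma) for w in widths if w >= 2 * sigma]
        assert all(a > b for a, b in zip(oracle[:-1], oracle[1:]))

    def test_heavy_blur_lowers_resolving_limit(self):
        px_per_mm = 40.0
        cam = f.CameraModel(sigma0_px=px_per_mm)  # blur of a full millimeter
        img, gt = f.render_usaf(SHARPNESS_ELEMENTS, px_per_mm, cam)
        res = f.sharpness_curve(img, f.element_rois_from_layout(gt.layout))
        assert res.resolving_limit_lp_mm is None or res.resolving_limit_lp_mm < 1.26


def make_stack(cam, zs, px_per_mm=10.0):
    stack = []
    rois = None
    for z in zs:
        img, gt = f.render_usaf([(0, 1)], px_per_mm, cam, z_cm=z)
        if rois is None:
            rois = f.element_rois_from_layout(gt.layout)[0]
        stack.append((float(z), img))
    return stack, rois


class TestDofCurve:
    def test_blur_free_stack_constant_full_range(self):
        stack, rois = make_stack(f.CameraModel(), range(-7, 8))
        d = f.dof_curve(stack, rois)
        assert all(c == pytest.approx(100.0) for c in d.ctf_percent)
        assert d.in_focus_range_cm == (-7.0, 7.0)

    def test_defocus_peaks_at_focus_and_decays_outward(self):
        # Slope keeps sigma(7 cm) below ~0.8 bar widths, where percentile
        # CTF is still informative (beyond that it floors at the macro
        # contrast of the blurred block and stops decreasing).
        cam = f.CameraModel(sigma0_px=0.3, defocus_slope_px_per_cm=0.5)
        stack, rois = make_stack(cam, range(-7, 8))
        d = f.dof_curve(stack, rois)
        ctf = np.array(d.ctf_percent)
        i0 = d.z_cm.index(0.0)
        assert np.argmax(ctf) == i0
        assert np.all(np.diff(ctf[: i0 + 1]) >= -1e-9)
        assert np.all(np.diff(ctf[i0:]) <= 1e-9)

    def test_asymmetric_stack_uses_available_span(self):
        """A stack from -6 to +7 (a proximity interlock trimming the near
        side) is scored over exactly that span."""
        stack, rois = make_stack(f.CameraModel(), range(-6, 8))
        d = f.dof_curve(stack, rois)
        assert d.z_cm[0] == -6.0 and d.z_cm[-1] == 7.0
        assert d.in_focus_range_cm == (-6.0, 7.0)

    def test_never_reaching_threshold_yields_empty_range(self):
        cam = f.CameraModel(sigma0_px=12.0)
        stack, rois = make_stack(cam, range(-2, 3))
        d = f.dof_curve(stack, rois)
        assert d.in_focus_range_cm is None  # signalled, not raised

    def test_symmetric_blur_gives_symmetric_range(self):
        cam = f.CameraModel(sigma0_px=0.5, defocus_slope_px_per_cm=0.6)
        stack, rois = make_stack(cam, range(-7, 8))
        d = f.dof_curve(stack, rois)
        lo, hi = d.in_focus_range_cm
        assert abs(abs(lo) - abs(hi)) <= 1.0  # within one z step

    def test_stack_validation(self):
        stack, rois = make_stack(f.CameraModel(), [1, 2, 3])
        with pytest.raises(FgsCheckError):
            f.dof_curve(stack, rois)  # no z = 0
        dup = stack + [stack[0]]
        with pytest.raises(FgsCheckError):
            f.dof_curve(dup, rois)
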