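"""Synthetic phantom generator with recorded ground truth.

Every characterization metric in this package can be exercised without
instrument access by rendering the corresponding phantom scene — USAF-1951
bar targets, a homogeneous fluorescent slab, an equidistant dot grid,
concentration and depth well plates, and near-Gaussian excitation spectra —
through a simple forward camera model.  The generating parameters are
returned as a :class:`SynthGroundTruth` sidecar so recovery tests can
compare estimates against truth, and every render is a pure function of
``(parameters, seed)``.

Forward model order (fixed): scene -> defocus blur -> vignette x gain ->
noise -> LUT -> quantization.

* Defocus blur is Gaussian with sigma(z) = sigma0 + slope * |z_cm|: the
  package makes no optical prescription beyond monotone blur growth away
  from the plane of focus, which is the only property the depth-of-field
  test needs.
* Vignetting is radial-quadratic, V(r) = 1 - v * (r / r_max)^2 with r_max
  the half-diagonal, so a single strength parameter v is what the
  uniformity test must recover.
* Noise is Poisson(scale * latent) / scale plus Gaussian read noise; both
  terms can be zeroed for exact tests.
* Geometric distortion follows the Brown radial model about the image
  center, r_d = r_u * (1 + k1 * r_u^2 + k2 * r_u^4), with radii normalized
  by the half-diagonal.
* Quantization clips to [0, 2^bit_depth - 1] and rounds.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, GeometryError, LayoutError, ResolutionError, SamplingError
from .io_config import (
    Image2D,
    Layout,
    RoiSpec,
    SpectralTrace,
    WellSpec,
    save_image,
    save_layout,
    save_spectrum,
)

__all__ = [
    "CameraModel",
    "SynthGroundTruth",
    "render_usaf",
    "render_uniform_field",
    "render_dot_grid",
    "render_wells",
    "render_spectrum",
    "render_from_ground_truth",
    "save_fixture",
    "GAUSSIAN_FWHM_FACTOR",
]

#: FWHM of a Gaussian of standard deviation sigma is this factor times sigma.
GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class CameraModel:
    """Parameters of the forward imaging model.

    ``lut``, when set, is a monotone piecewise-linear transfer curve given
    as breakpoints ``[(in0, out0), (in1, out1), ...]`` on the sensor scale;
    it emulates vendor display mapping (perceived floor / saturation) and
    is applied after noise, before quantization.
    """

    sigma0_px: float = 0.0
    defocus_slope_px_per_cm: float = 0.0
    vignette_strength: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    gain: float = 1.0
    read_noise_sd: float = 0.0
    poisson_scale: float = 0.0
    bit_depth: int = 16
    lut: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.sigma0_px < 0 or self.defocus_slope_px_per_cm < 0:
            raise ConfigError("blur parameters must be non-negative")
        if not 0 <= self.vignette_strength < 1:
            raise ConfigError("vignette_strength must lie in [0, 1)")
        if self.gain <= 0:
            raise ConfigError("gain must be positive")
        if self.read_noise_sd < 0 or self.poisson_scale < 0:
            raise ConfigError("noise parameters must be non-negative")
        if self.lut is not None:
            pts = np.asarray(self.lut, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
                raise ConfigError("lut must be a sequence of (in, out) pairs")
            if np.any(np.diff(pts[:, 0]) <= 0) or np.any(np.diff(pts[:, 1]) < 0):
                raise ConfigError("lut must be monotone")

    @property
    def full_scale(self) -> float:
        return float(2**self.bit_depth - 1)

    def blur_sigma(self, z_cm: float) -> float:
        return self.sigma0_px + self.defocus_slope_px_per_cm * abs(z_cm)

    def vignette_map(self, shape: tuple[int, int]) -> np.ndarray:
        H, W = shape
        yc, xc = (H - 1) / 2.0, (W - 1) / 2.0
        rows = np.arange(H)[:, None] - yc
        cols = np.arange(W)[None, :] - xc
        r2 = rows**2 + cols**2
        r2max = yc**2 + xc**2
        return 1.0 - self.vignette_strength * (r2 / r2max)


def _apply_camera(
    scene: np.ndarray, camera: CameraModel, z_cm: float, rng: np.random.Generator
) -> np.ndarray:
    """Run the forward model on a noiseless latent scene."""
    out = np.asarray(scene, dtype=np.float64)
    sigma = camera.blur_sigma(z_cm)
    if sigma > 0:
        out = gaussian_filter(out, sigma=sigma, mode="nearest")
    out = out * camera.vignette_map(out.shape) * camera.gain
    if camera.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * camera.poisson_scale) / camera.poisson_scale
    if camera.read_noise_sd > 0:
        out = out + rng.normal(0.0, camera.read_noise_sd, size=out.shape)
    if camera.lut is not None:
        pts = np.asarray(camera.lut, dtype=float)
        out = np.interp(out, pts[:, 0], pts[:, 1])
    return np.clip(np.round(out), 0.0, camera.full_scale)


def _brown_distort(
    points: np.ndarray, center: tuple[float, float], r_norm: float, k1: float, k2: float
) -> np.ndarray:
    """Apply the Brown radial model to (row, col) points about ``center``,
    radii normalized by ``r_norm``."""
    vec = points - np.asarray(center)
    r_u = np.linalg.norm(vec, axis=1) / r_norm
    factor = 1.0 + k1 * r_u**2 + k2 * r_u**4
    return np.asarray(center) + vec * factor[:, None]


@dataclass
class SynthGroundTruth:
    """Generating parameters of a synthetic fixture.

    ``params`` holds the scene description for the given ``kind``
    (bar geometry and per-element ROIs, lattice centers, well intensities,
    spectral parameters, ...).  Together with ``camera`` and ``rng_seed``
    it is sufficient to re-render the fixture bit-identically via
    :func:`render_from_ground_truth`.
    """

    kind: Literal["usaf", "uniform", "dots", "conc_wells", "depth_wells", "spectrum"]
    camera: CameraModel | None
    params: dict
    rng_seed: int
    layout: Layout | None = None

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v

        out = {
            "kind": self.kind,
            "camera": None if self.camera is None else _clean(asdict(self.camera)),
            "params": _clean(self.params),
            "rng_seed": int(self.rng_seed),
        }
        return out

    @classmethod
    def from_dict(cls, doc: dict, layout: Layout | None = None) -> "SynthGroundTruth":
        cam = doc.get("camera")
        camera = None
        if cam is not None:
            lut = cam.get("lut")
            cam = {**cam, "lut": None if lut is None else tuple(tuple(p) for p in lut)}
            camera = CameraModel(**cam)
        return cls(
            kind=doc["kind"],
            camera=camera,
            params=dict(doc["params"]),
            rng_seed=int(doc["rng_seed"]),
            layout=layout,
        )


# ---------------------------------------------------------------------------
# USAF-1951 bar target


def _usaf_lp_per_mm(group: int, element: int) -> float:
    return float(2.0 ** (group + (element - 1) / 6.0))


def _render_bar_block(
    block: np.ndarray, width_px: float, horizontal: bool, high: float
) -> None:
    """Paint three bars (on/off period = 2 * width) into ``block`` in place.

    Bars run across the block; pixel centers sample the continuous pattern.
    """
    n = block.shape[0] if horizontal else block.shape[1]
    coords = np.arange(n) + 0.5
    phase = np.floor(coords / width_px).astype(int)
    on = (phase % 2 == 0) & (phase < 5)  # bars at phases 0, 2, 4
    if horizontal:
        block[on, :] = high
    else:
        block[:, on] = high


def render_usaf(
    elements: Sequence[tuple[int, int]] = ((0, 1),),
    px_per_mm: float = 10.0,
    camera: CameraModel | None = None,
    z_cm: float = 0.0,
    seed: int = 0,
    high: float = 3000.0,
    low: float = 0.0,
) -> tuple[Image2D, SynthGroundTruth]:
    """Render USAF-1951 elements as horizontal + vertical three-bar blocks.

    Each element resolves ``2^(group + (element-1)/6)`` line pairs per mm;
    bar width is ``px_per_mm / (2 * lp_per_mm)`` pixels and bar length is
    five bar widths, per the USAF-1951 element geometry.  The ground truth
    records one rectangular ROI per orientation per element (named
    ``g{G}e{E}_h`` / ``g{G}e{E}_v``).
    """
    camera = camera or CameraModel()
    margin = 16
    tiles: list[tuple[tuple[int, int], int, int]] = []  # (elem, block_px, row0)
    row = margin
    max_block = 0
    for g, e in elements:
        lp = _usaf_lp_per_mm(g, e)
        w = px_per_mm / (2.0 * lp)
        if w < 1.0:
            raise ResolutionError(
                f"group {g} element {e}: bar width {w:.3f} px < 1 px at {px_per_mm} px/mm"
            )
        block = int(round(5 * w))
        tiles.append(((g, e), block, row))
        row += block + margin
        max_block = max(max_block, block)
    H = max(row, 2 * margin + 16)
    W = max(2 * max_block + 3 * margin, 48)
    scene = np.full((H, W), low, dtype=np.float64)
    rois: list[RoiSpec] = []
    meta: dict = {"elements": []}
    for (g, e), block, r0 in tiles:
        lp = _usaf_lp_per_mm(g, e)
        w = px_per_mm / (2.0 * lp)
        c_h = margin
        c_v = 2 * margin + max_block
        _render_bar_block(scene[r0 : r0 + block, c_h : c_h + block], w, True, high)
        _render_bar_block(scene[r0 : r0 + block, c_v : c_v + block], w, False, high)
        rois.append(RoiSpec(f"g{g}e{e}_h", "rect", rect=(r0, c_h, block, block)))
        rois.append(RoiSpec(f"g{g}e{e}_v", "rect", rect=(r0, c_v, block, block)))
        meta["elements"].append(
            {"group": g, "element": e, "lp_per_mm": lp, "bar_width_px": w, "block_px": block}
        )

    rng = np.random.default_rng(seed)
    pixels = _apply_camera(scene, camera, z_cm, rng)
    layout = Layout(image_shape=(H, W), rois=rois, metadata={"kind": "usaf"})
    gt = SynthGroundTruth(
        kind="usaf",
        camera=camera,
        params={
            **meta,
            "px_per_mm": px_per_mm,
            "z_cm": z_cm,
            "high": high,
            "low": low,
            "element_list": [list(el) for el in elements],
        },
        rng_seed=seed,
        layout=layout,
    )
    img = Image2D(
        pixels=pixels,
        bit_depth=camera.bit_depth,
        source=f"synth:usaf(seed={seed},z={z_cm})",
        pixel_pitch_mm=1.0 / px_per_mm,
    )
    return img, gt


# ---------------------------------------------------------------------------
# Homogeneous slab (FOV uniformity)


def render_uniform_field(
    size_px: tuple[int, int] = (480, 640),
    camera: CameraModel | None = None,
    seed: int = 0,
    level: float = 30000.0,
) -> tuple[Image2D, SynthGroundTruth]:
    """Render the homogeneous fluorescent slab: a constant latent scene
    observed through vignetting and noise.  Emulates a flat phantom larger
    than the field of view, so the image edge is still on the slab."""
    camera = camera or CameraModel()
    scene = np.full(size_px, level, dtype=np.float64)
    rng = np.random.default_rng(seed)
    pixels = _apply_camera(scene, camera, 0.0, rng)
    gt = SynthGroundTruth(
        kind="uniform",
        camera=camera,
        params={"size_px": list(size_px), "level": level},
        rng_seed=seed,
        layout=Layout(image_shape=size_px, metadata={"kind": "uniform"}),
    )
    img = Image2D(
        pixels=pixels, bit_depth=camera.bit_depth, source=f"synth:uniform(seed={seed})"
    )
    return img, gt


# ---------------------------------------------------------------------------
# Equidistant dot grid (distortion)


def render_dot_grid(
    spacing_px: float = 40.0,
    rows: int = 2,
    cols: int = 9,
    camera: CameraModel | None = None,
    seed: int = 0,
    dot_sigma_px: float = 1.5,
    amplitude: float = 20000.0,
    margin_px: float | None = None,
) -> tuple[Image2D, SynthGroundTruth]:
    """Render a fluorescent dot lattice, displaced by the Brown radial
    model about the image center.

    Dots are Gaussian blobs (sd ``dot_sigma_px``) so peak positions are
    well defined at subpixel scale.  Ground truth records both undistorted
    and distorted centers.
    """
    camera = camera or CameraModel()
    if dot_sigma_px < 0.5:
        raise ConfigError("dot_sigma_px must be >= 0.5 px")
    margin = float(margin_px if margin_px is not None else spacing_px)
    H = int(round((rows - 1) * spacing_px + 2 * margin))
    W = int(round((cols - 1) * spacing_px + 2 * margin))
    H, W = max(H, 16), max(W, 16)
    yc, xc = (H - 1) / 2.0, (W - 1) / 2.0
    r_norm = np.hypot(yc, xc)

    r_idx, c_idx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    centers = np.column_stack(
        [
            yc + (r_idx.ravel() - (rows - 1) / 2.0) * spacing_px,
            xc + (c_idx.ravel() - (cols - 1) / 2.0) * spacing_px,
        ]
    )
    distorted = _brown_distort(centers, (yc, xc), r_norm, camera.k1, camera.k2)
    pad = 3 * dot_sigma_px
    if (
        distorted[:, 0].min() < pad
        or distorted[:, 0].max() > H - 1 - pad
        or distorted[:, 1].min() < pad
        or distorted[:, 1].max() > W - 1 - pad
    ):
        raise GeometryError("distorted dot leaves the frame; increase margin_px")

    scene = np.zeros((H, W), dtype=np.float64)
    rr = np.arange(H)[:, None]
    cc = np.arange(W)[None, :]
    for (dr, dc) in distorted:
        r0, r1 = int(max(0, dr - 5 * dot_sigma_px)), int(min(H, dr + 5 * dot_sigma_px + 1))
        c0, c1 = int(max(0, dc - 5 * dot_sigma_px)), int(min(W, dc + 5 * dot_sigma_px + 1))
        sub_r = rr[r0:r1]
        sub_c = cc[:, c0:c1]
        scene[r0:r1, c0:c1] += amplitude * np.exp(
            -((sub_r - dr) ** 2 + (sub_c - dc) ** 2) / (2 * dot_sigma_px**2)
        )

    rng = np.random.default_rng(seed)
    pixels = _apply_camera(scene, camera, 0.0, rng)
    gt = SynthGroundTruth(
        kind="dots",
        camera=camera,
        params={
            "spacing_px": spacing_px,
            "rows": rows,
            "cols": cols,
            "dot_sigma_px": dot_sigma_px,
            "amplitude": amplitude,
            "margin_px": margin,
            "undistorted_centers": centers,
            "distorted_centers": distorted,
        },
        rng_seed=seed,
        layout=Layout(image_shape=(H, W), metadata={"kind": "dots"}),
    )
    img = Image2D(
        pixels=pixels, bit_depth=camera.bit_depth, source=f"synth:dots(seed={seed})"
    )
    return img, gt


# ---------------------------------------------------------------------------
# Well plates (concentration / depth)

#: ICG-equivalent dilution series of the nine-well concentration plate, nM.
CONC_SERIES_NM = (1000.0, 300.0, 100.0, 30.0, 10.0, 3.0, 1.0)
#: Overburden depths of the nine-well depth plate, mm (eight sample wells
#: spanning 0.5–6 mm plus a 6 mm blank control).
DEPTH_SERIES_MM = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0)


def _well_grid_layout(
    n_wells: int, radius_px: float, pitch_px: float
) -> tuple[tuple[int, int], list[tuple[float, float]]]:
    """3-column grid of well centers, image sized to fit."""
    n_cols = 3
    n_rows = int(np.ceil(n_wells / n_cols))
    H = int(round(n_rows * pitch_px + pitch_px))
    W = int(round(n_cols * pitch_px + pitch_px))
    centers = []
    for i in range(n_wells):
        r, c = divmod(i, n_cols)
        centers.append((pitch_px * (r + 1), pitch_px * (c + 1)))
    return (H, W), centers


def render_wells(
    kind: Literal["conc", "depth"],
    camera: CameraModel | None = None,
    seed: int = 0,
    floor: float = 100.0,
    gain_per_nm: float = 250.0,
    saturation_level: float | None = None,
    concentrations_nm: Sequence[float] = CONC_SERIES_NM,
    qd800_leak: float = 0.0,
    i0: float = 40000.0,
    d_att_mm: float = 2.0,
    depths_mm: Sequence[float] = DEPTH_SERIES_MM,
    radius_px: float = 18.0,
    pitch_px: float = 60.0,
) -> tuple[Image2D, SynthGroundTruth]:
    """Render a nine-well plate phantom.

    ``kind='conc'``: seven ICG-equivalent dilutions (default 1000 down to
    1 nM), a 0 nM control and a QD800 well; well intensity is ``floor +
    gain_per_nm * C`` clipped at ``saturation_level`` (default: the sensor
    full scale) — the default gain saturates the 1000 and 300 nM wells on
    a 16-bit sensor, as real systems do.  The QD800 well renders above
    floor only when ``qd800_leak > 0`` (visible room-light leakage; it is
    a control channel, not an ICG signal).

    ``kind='depth'``: eight wells of 1000 nM-equivalent signal under
    0.5–6 mm of tissue-mimicking overburden plus a 6 mm blank control;
    well intensity decays as ``floor + i0 * exp(-depth / d_att_mm)``.
    """
    camera = camera or CameraModel()
    sat = camera.full_scale if saturation_level is None else float(saturation_level)

    wells: list[WellSpec] = []
    latents: list[float] = []
    if kind == "conc":
        labels = list(concentrations_nm)
        n = len(labels) + 2
        (H, W), centers = _well_grid_layout(n, radius_px, pitch_px)
        for i, c_nm in enumerate(labels):
            roi = RoiSpec(f"w{i}_c{c_nm:g}", "circle", circle=(*centers[i], radius_px))
            wells.append(WellSpec(roi=roi, concentration_nm=float(c_nm)))
            latents.append(min(floor + gain_per_nm * c_nm, sat))
        roi = RoiSpec("control", "circle", circle=(*centers[len(labels)], radius_px))
        wells.append(WellSpec(roi=roi, role="control", concentration_nm=0.0))
        latents.append(floor)
        roi = RoiSpec("qd800", "circle", circle=(*centers[len(labels) + 1], radius_px))
        wells.append(WellSpec(roi=roi, role="qd800"))
        latents.append(min(floor + qd800_leak, sat))
        params = {
            "floor": floor,
            "gain_per_nm": gain_per_nm,
            "saturation_level": sat,
            "concentrations_nm": list(labels),
            "qd800_leak": qd800_leak,
            "radius_px": radius_px,
            "pitch_px": pitch_px,
        }
    elif kind == "depth":
        labels = list(depths_mm)
        n = len(labels) + 1
        (H, W), centers = _well_grid_layout(n, radius_px, pitch_px)
        for i, d in enumerate(labels):
            roi = RoiSpec(f"w{i}_d{d:g}", "circle", circle=(*centers[i], radius_px))
            wells.append(WellSpec(roi=roi, depth_mm=float(d)))
            latents.append(min(floor + i0 * np.exp(-d / d_att_mm), sat))
        roi = RoiSpec("control", "circle", circle=(*centers[len(labels)], radius_px))
        wells.append(WellSpec(roi=roi, role="control", depth_mm=6.0))
        latents.append(floor)
        params = {
            "floor": floor,
            "i0": i0,
            "d_att_mm": d_att_mm,
            "saturation_level": sat,
            "depths_mm": list(labels),
            "radius_px": radius_px,
            "pitch_px": pitch_px,
        }
    else:
        raise ConfigError(f"unknown well plate kind {kind!r}")

    # Disjointness check: wells on the grid must not touch.
    for i in range(len(wells)):
        for j in range(i + 1, len(wells)):
            (r1, c1, rad1) = wells[i].roi.circle  # type: ignore[misc]
            (r2, c2, rad2) = wells[j].roi.circle  # type: ignore[misc]
            if np.hypot(r1 - r2, c1 - c2) <= rad1 + rad2:
                raise LayoutError(f"wells {wells[i].roi.name} and {wells[j].roi.name} overlap")

    scene = np.full((H, W), floor, dtype=np.float64)
    for well, latent in zip(wells, latents):
        scene[well.roi.mask((H, W))] = latent

    rng = np.random.default_rng(seed)
    pixels = _apply_camera(scene, camera, 0.0, rng)
    layout = Layout(image_shape=(H, W), wells=wells, metadata={"kind": f"{kind}_wells"})
    gt = SynthGroundTruth(
        kind="conc_wells" if kind == "conc" else "depth_wells",
        camera=camera,
        params={**params, "latents": latents, "kind": kind},
        rng_seed=seed,
        layout=layout,
    )
    img = Image2D(
        pixels=pixels, bit_depth=camera.bit_depth, source=f"synth:{kind}_wells(seed={seed})"
    )
    return img, gt


# ---------------------------------------------------------------------------
# Excitation spectrum


def render_spectrum(
    center_nm: float = 780.0,
    sigma_nm: float = 1.24,
    amplitude: float = 1.0,
    baseline: float = 0.02,
    noise_sd: float = 0.0,
    n_samples: int = 601,
    seed: int = 0,
    span_nm: float = 15.0,
) -> tuple[SpectralTrace, SynthGroundTruth]:
    """Render a near-Gaussian excitation band on a uniform wavelength grid.

    The default sigma of 1.24 nm gives a true FWHM of 2.92 nm, in the
    middle of the narrow diode-laser bands real systems show.  The true
    FWHM ``2 * sqrt(2 ln 2) * sigma`` is recorded in the ground truth.
    """
    wl = np.linspace(center_nm - span_nm, center_nm + span_nm, int(n_samples))
    step = wl[1] - wl[0]
    if step > sigma_nm / 3.0:
        raise SamplingError(
            f"grid step {step:.4f} nm too coarse for sigma {sigma_nm} nm (need <= sigma/3)"
        )
    profile = baseline + amplitude * np.exp(-((wl - center_nm) ** 2) / (2 * sigma_nm**2))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        profile = profile + rng.normal(0.0, noise_sd, size=profile.shape)
    profile = np.clip(profile, 0.0, None)
    degenerate = amplitude <= 0
    gt = SynthGroundTruth(
        kind="spectrum",
        camera=None,
        params={
            "center_nm": center_nm,
            "sigma_nm": sigma_nm,
            "amplitude": amplitude,
            "baseline": baseline,
            "noise_sd": noise_sd,
            "n_samples": int(n_samples),
            "span_nm": span_nm,
            "true_fwhm_nm": GAUSSIAN_FWHM_FACTOR * sigma_nm,
            "degenerate": bool(degenerate),
        },
        rng_seed=seed,
    )
    return SpectralTrace(wavelength_nm=wl, intensity=profile), gt


# ---------------------------------------------------------------------------
# Reproducibility plumbing


def render_from_ground_truth(gt: SynthGroundTruth):
    """Re-render a fixture from its ground-truth sidecar (bit-identical to
    the original render)."""
    p = gt.params
    if gt.kind == "usaf":
        return render_usaf(
            elements=[tuple(el) for el in p["element_list"]],
            px_per_mm=p["px_per_mm"],
            camera=gt.camera,
            z_cm=p["z_cm"],
            seed=gt.rng_seed,
            high=p["high"],
            low=p["low"],
        )
    if gt.kind == "uniform":
        return render_uniform_field(
            size_px=tuple(p["size_px"]), camera=gt.camera, seed=gt.rng_seed, level=p["level"]
        )
    if gt.kind == "dots":
        return render_dot_grid(
            spacing_px=p["spacing_px"],
            rows=p["rows"],
            cols=p["cols"],
            camera=gt.camera,
            seed=gt.rng_seed,
            dot_sigma_px=p["dot_sigma_px"],
            amplitude=p["amplitude"],
            margin_px=p["margin_px"],
        )
    if gt.kind in ("conc_wells", "depth_wells"):
        common = dict(
            camera=gt.camera,
            seed=gt.rng_seed,
            floor=p["floor"],
            saturation_level=p["saturation_level"],
            radius_px=p["radius_px"],
            pitch_px=p["pitch_px"],
        )
        if gt.kind == "conc_wells":
            return render_wells(
                "conc",
                gain_per_nm=p["gain_per_nm"],
                concentrations_nm=p["concentrations_nm"],
                qd800_leak=p["qd800_leak"],
                **common,
            )
        return render_wells(
            "depth", i0=p["i0"], d_att_mm=p["d_att_mm"], depths_mm=p["depths_mm"], **common
        )
    if gt.kind == "spectrum":
        return render_spectrum(
            center_nm=p["center_nm"],
            sigma_nm=p["sigma_nm"],
            amplitude=p["amplitude"],
            baseline=p["baseline"],
            noise_sd=p["noise_sd"],
            n_samples=p["n_samples"],
            seed=gt.rng_seed,
            span_nm=p["span_nm"],
        )
    raise ConfigError(f"unknown fixture kind {gt.kind!r}")


def save_fixture(
    result: tuple, gt: SynthGroundTruth, out_dir: str | os.PathLike, stem: str | None = None
) -> dict[str, str]:
    """Write a rendered fixture to disk: 16-bit TIFF (or CSV for spectra),
    a ground-truth JSON sidecar and, when present, a layout YAML consumable
    by :func:`fgscheck.io_config.load_layout`.  Returns the written paths."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    stem = stem or gt.kind
    data = result[0] if isinstance(result, tuple) else result
    paths: dict[str, str] = {}
    if isinstance(data, Image2D):
        img_path = os.path.join(out_dir, f"{stem}.tif")
        save_image(data, img_path)
        paths["image"] = img_path
    elif isinstance(data, SpectralTrace):
        csv_path = os.path.join(out_dir, f"{stem}.csv")
        save_spectrum(data, csv_path)
        paths["spectrum"] = csv_path
    else:
        raise ConfigError(f"cannot save fixture payload of type {type(data)}")
    gt_path = os.path.join(out_dir, f"{stem}.groundtruth.json")
    with open(gt_path, "w") as fh:
        json.dump(gt.to_dict(), fh, indent=2, sort_keys=True)
    paths["ground_truth"] = gt_path
    if gt.layout is not None:
        layout_path = os.path.join(out_dir, f"{stem}.layout.yaml")
        save_layout(gt.layout, layout_path)
        paths["layout"] = layout_path
    return paths
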