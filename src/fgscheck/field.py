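"""Field-of-view metrics: illumination uniformity and radial distortion.

Uniformity is measured on an image of a homogeneous fluorescent slab
larger than the field of view: a horizontal band (default +/- 50 rows
about mid-height) is averaged per column and the resulting profile,
normalized to its maximum, exposes vignetting and illumination fall-off.

Distortion is measured on an image of an equidistant fluorescent dot
grid: dot peaks are located along row bands near mid-height, successive
peak distances are normalized by the largest spacing (an undistorted grid
reads exactly 1 everywhere), and the worst deviation is summarized as a
distortion index together with which side of the field it occurs on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .errors import DetectionError, GeometryError, InsufficientDataError
from .io_config import Image2D, RoiSpec

__all__ = [
    "UniformityProfile",
    "DotGridResult",
    "uniformity_profile",
    "masked_region_zeroing",
    "estimate_vignette_strength",
    "dot_distances",
]


@dataclass(frozen=True)
class UniformityProfile:
    """Normalized column-mean profile of the central band.

    ``x_norm`` spans [0, 1] across the image width; ``profile`` is in
    [0, 1] with max exactly 1.  Summary statistics: fraction of columns at
    or above 0.9, the minimum value, and the center-to-edge ratio (edge =
    mean of the two outermost columns).
    """

    x_norm: np.ndarray
    profile: np.ndarray
    band_half_width_px: int
    band_rows: tuple[int, int]  # half-open row bounds of the band
    frac_above_090: float
    min_profile: float
    center_edge_ratio: float


def _column_means_masked(
    band: np.ndarray, band_mask: np.ndarray | None
) -> np.ndarray:
    """Per-column means of a band, ignoring masked pixels; fully masked
    columns are interpolated from their valid neighbors."""
    if band_mask is None:
        return band.mean(axis=0)
    valid = ~band_mask
    counts = valid.sum(axis=0)
    sums = np.where(valid, band, 0.0).sum(axis=0)
    means = np.divide(sums, counts, out=np.zeros(band.shape[1]), where=counts > 0)
    missing = counts == 0
    if missing.any():
        cols = np.arange(band.shape[1])
        if not (~missing).any():
            raise GeometryError("every column of the band is fully masked")
        means[missing] = np.interp(cols[missing], cols[~missing], means[~missing])
    return means


def uniformity_profile(
    image: Image2D,
    band_half_width_px: int = 50,
    masks: Sequence[RoiSpec] | None = None,
    smooth_window: int | None = None,
) -> UniformityProfile:
    """Column-mean intensity profile over the central horizontal band.

    ``masks`` (e.g. vendor logo overlays) are excluded from the column
    statistics; a column whose band pixels are all masked is interpolated
    from its neighbors.  ``smooth_window`` applies an optional moving
    median (hot-pixel guard) before normalization.
    """
    H, W = image.shape
    if H <= 2 * band_half_width_px:
        raise GeometryError(
            f"band of half-width {band_half_width_px} px does not fit image height {H}"
        )
    mid = H // 2
    r0, r1 = mid - band_half_width_px, mid + band_half_width_px + 1
    band = image.pixels[r0:r1, :]

    band_mask = None
    if masks:
        full = np.zeros(image.shape, dtype=bool)
        for m in masks:
            full |= m.mask(image.shape)
        band_mask = full[r0:r1, :]

    profile = _column_means_masked(band, band_mask)
    if smooth_window is not None:
        profile = median_filter(profile, size=int(smooth_window), mode="nearest")
    peak = profile.max()
    if peak <= 0:
        raise GeometryError("band has no positive intensity")
    profile = profile / peak
    edge = 0.5 * (profile[0] + profile[-1])
    center = profile[W // 2]
    return UniformityProfile(
        x_norm=np.linspace(0.0, 1.0, W),
        profile=profile,
        band_half_width_px=band_half_width_px,
        band_rows=(r0, r1),
        frac_above_090=float((profile >= 0.9).mean()),
        min_profile=float(profile.min()),
        center_edge_ratio=float(center / edge) if edge > 0 else float("inf"),
    )


def masked_region_zeroing(image: Image2D, masks: Sequence[RoiSpec]) -> Image2D:
    """Return a copy of the image with the masked regions set to 0 (the
    display convention for vendor logos).  For statistics, pass the masks
    to :func:`uniformity_profile` instead so they are excluded, not zeroed.
    """
    out = image.pixels.copy()
    for m in masks:
        out[m.mask(image.shape)] = 0.0
    return Image2D(
        pixels=out,
        bit_depth=image.bit_depth,
        source=image.source + "+masked",
        pixel_pitch_mm=image.pixel_pitch_mm,
        channel_policy=image.channel_policy,
        lossy=image.lossy,
    )


def estimate_vignette_strength(
    prof: UniformityProfile, image_shape: tuple[int, int]
) -> float:
    """Invert the radial-quadratic vignette model from a uniformity profile.

    For V(r) = 1 - v (r/r_max)^2 the band's column means are analytic in v;
    solving the min/max profile ratio for v gives the estimate.  Exact on
    noise-free synthetic slabs.
    """
    H, W = image_shape
    yc, xc = (H - 1) / 2.0, (W - 1) / 2.0
    r2max = yc**2 + xc**2
    r0, r1 = prof.band_rows
    my2 = float(np.mean((np.arange(r0, r1) - yc) ** 2))

    i_min = int(np.argmin(prof.profile))
    i_max = int(np.argmax(prof.profile))
    x_min = i_min - xc
    x_max = i_max - xc
    a = (x_min**2 + my2) / r2max
    b = (x_max**2 + my2) / r2max
    p = prof.min_profile  # profile is max-normalized, so value at i_max is 1
    denom = a - p * b
    if denom <= 0:
        return 0.0
    return float((1.0 - p) / denom)


@dataclass(frozen=True)
class DotGridResult:
    """Peak positions and spacing statistics of a dot-grid image.

    ``spacings_norm`` divides by the maximum spacing so an undistorted
    grid reads exactly 1 everywhere and any deviation reads below 1;
    ``distortion_index = 1 - min(spacings_norm)``.  ``side_flag`` names
    the side of the field (left/right) where spacings deviate most, or
    'none' when the grid is uniform within tolerance.
    """

    band_rows: tuple[int, ...]
    peak_positions_px: tuple[np.ndarray, ...]  # per analyzed band
    spacings_px: np.ndarray
    spacings_norm: np.ndarray
    distortion_index: float
    side_flag: str


def _refine_parabolic(profile: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """3-point parabolic subpixel refinement of peak indices."""
    out = idx.astype(np.float64)
    for n, i in enumerate(idx):
        if 0 < i < profile.size - 1:
            y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                out[n] = i + 0.5 * (y0 - y2) / denom
    return out


def _band_peaks(
    profile: np.ndarray, min_prominence_frac: float
) -> np.ndarray:
    rng = profile.max() - profile.min()
    if rng <= 0:
        raise DetectionError("flat profile: no dots found")
    prominence = min_prominence_frac * rng
    idx, _ = find_peaks(profile, prominence=prominence)
    if idx.size >= 2:
        # Re-detect with a minimum separation of half the median spacing to
        # suppress noise peaks riding on dot flanks.
        med = np.median(np.diff(idx))
        idx, _ = find_peaks(profile, prominence=prominence, distance=max(1, med / 2))
    if idx.size < 4:
        raise InsufficientDataError(f"only {idx.size} dot peaks found; need >= 4")
    pos = _refine_parabolic(profile, idx)
    if np.any(np.diff(pos) <= 0):
        raise DetectionError("non-monotone peak positions after refinement")
    return pos


def _auto_row_bands(image: Image2D, n_bands: int = 2) -> list[int]:
    """Rows of the dot rows nearest mid-height, from the row-mean profile."""
    row_profile = image.pixels.mean(axis=1)
    rng = row_profile.max() - row_profile.min()
    if rng <= 0:
        raise DetectionError("flat image: no dot rows found")
    idx, _ = find_peaks(row_profile, prominence=0.2 * rng)
    if idx.size == 0:
        raise DetectionError("no dot rows detected")
    mid = image.shape[0] / 2.0
    chosen = sorted(idx, key=lambda i: abs(i - mid))[: min(n_bands, idx.size)]
    return sorted(int(i) for i in chosen)


def dot_distances(
    image: Image2D,
    row_bands: Sequence[int] | None = None,
    min_prominence_frac: float = 0.2,
    band_half_width_px: int = 3,
) -> DotGridResult:
    """Spacing analysis of the dot rows nearest mid-height.

    For each band (a row +/- ``band_half_width_px``), dots appear as peaks
    of the column-mean profile; peaks are located with a prominence
    criterion and refined to subpixel positions by parabolic
    interpolation.  When two bands yield the same dot count their spacing
    series are averaged; otherwise the band nearest mid-height is used.
    """
    if row_bands is None:
        row_bands = _auto_row_bands(image)
    H, W = image.shape
    positions: list[np.ndarray] = []
    used_rows: list[int] = []
    for row in row_bands:
        r0 = max(0, int(row) - band_half_width_px)
        r1 = min(H, int(row) + band_half_width_px + 1)
        profile = image.pixels[r0:r1, :].mean(axis=0)
        positions.append(_band_peaks(profile, min_prominence_frac))
        used_rows.append(int(row))

    spacing_series = [np.diff(p) for p in positions]
    lengths = {len(s) for s in spacing_series}
    if len(lengths) == 1 and len(spacing_series) > 1:
        spacings = np.mean(spacing_series, axis=0)
    else:
        spacings = spacing_series[0]
    if np.any(spacings <= 0):
        raise DetectionError("non-positive dot spacing")

    norm = spacings / spacings.max()
    distortion_index = float(1.0 - norm.min())
    tol = 1e-9
    if distortion_index <= tol:
        side = "none"
    else:
        n = norm.size
        left_dev = 1.0 - norm[: n // 2].min()
        right_dev = 1.0 - norm[(n + 1) // 2 :].min() if n > 1 else 0.0
        side = "left" if left_dev >= right_dev else "right"
    return DotGridResult(
        band_rows=tuple(used_rows),
        peak_positions_px=tuple(positions),
        spacings_px=spacings,
        spacings_norm=norm,
        distortion_index=distortion_index,
        side_flag=side,
    )
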