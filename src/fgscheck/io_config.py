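"""Input handling: images, video frames, spectra and phantom layouts.

All downstream metrics consume the small data model defined here —
:class:`Image2D` (a 2-D intensity array with bit-depth and provenance
metadata), :class:`SpectralTrace` (a wavelength/intensity pair of vectors),
:class:`RoiSpec` (a named rectangle or circle in pixel coordinates) and
:class:`WellSpec` (an ROI annotated with a concentration or a depth).

Conventions
-----------
Pixel coordinates are 0-based and row-major with the origin at the
top-left; rectangles are half-open ``[row0, row0+height) x [col0,
col0+width)`` so they slice numpy arrays directly.  Color inputs are
reduced to a scalar channel according to a ``channel_policy``: ``as_is``
rejects color, ``luminance`` takes the unweighted mean of the channels
(vendor display renders carry no defensible RGB weighting), and
``named_channel`` selects one channel by index.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import (
    BoundsError,
    ConfigError,
    FormatError,
    InsufficientDataError,
    LayoutError,
    NoFrameError,
    ParseError,
)

__all__ = [
    "Image2D",
    "SpectralTrace",
    "RoiSpec",
    "WellSpec",
    "Layout",
    "SystemProfile",
    "load_image",
    "save_image",
    "load_spectrum",
    "save_spectrum",
    "load_layout",
    "save_layout",
]

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}
_VIDEO_SUFFIXES = {".mp4"}


@dataclass
class Image2D:
    """A two-dimensional intensity image plus acquisition metadata.

    Parameters
    ----------
    pixels
        2-D float array of finite, non-negative intensities, each at most
        ``2**bit_depth - 1``.
    bit_depth
        Bit depth of the originating container (8, 12, 16, ...).
    source
        Provenance string, typically ``"path[#frame]"``; synthetic images
        record their generator.
    pixel_pitch_mm
        Optional physical size of one pixel at the working distance.
    channel_policy
        How a color input was reduced to this scalar image.
    lossy
        True when the source container used lossy compression (JPEG);
        reports must disclose this.
    """

    pixels: np.ndarray
    bit_depth: int
    source: str = ""
    pixel_pitch_mm: float | None = None
    channel_policy: str = "as_is"
    lossy: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise FormatError(f"expected a 2-D image, got shape {px.shape}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise FormatError(f"image too small: {px.shape} (both dims must be >= 16)")
        if not np.all(np.isfinite(px)):
            raise FormatError("image contains non-finite pixels")
        if px.min() < 0:
            raise FormatError("image contains negative pixels")
        full_scale = float(2**self.bit_depth - 1)
        if px.max() > full_scale:
            raise FormatError(
                f"pixel value {px.max()} exceeds full scale {full_scale} "
                f"for bit depth {self.bit_depth}"
            )
        if self.pixel_pitch_mm is not None and self.pixel_pitch_mm <= 0:
            raise ConfigError("pixel_pitch_mm must be positive")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def full_scale(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass
class SpectralTrace:
    """A sampled spectrum: strictly increasing wavelengths (nm) and
    non-negative intensities in arbitrary units."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=np.float64)
        it = np.asarray(self.intensity, dtype=np.float64)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise ParseError("wavelength and intensity must be 1-D vectors of equal length")
        if wl.size < 8:
            raise InsufficientDataError(f"spectrum has {wl.size} samples; need >= 8")
        if np.any(np.diff(wl) <= 0):
            raise ParseError("wavelengths must be strictly increasing")
        if wl.min() <= 0:
            raise ParseError("wavelengths must be positive")
        if np.any(it < 0) or not np.all(np.isfinite(it)):
            raise ParseError("intensities must be finite and non-negative")
        if not np.any(it > 0):
            raise ParseError("spectrum has no positive intensity")
        self.wavelength_nm = wl
        self.intensity = it

    def __len__(self) -> int:
        return int(self.wavelength_nm.size)


@dataclass(frozen=True)
class RoiSpec:
    """A named rectangular or circular region in pixel coordinates.

    ``rect`` is ``(row0, col0, height, width)`` with half-open bounds;
    ``circle`` is ``(center_row, center_col, radius_px)``.  A pixel belongs
    to a circle when its center lies within ``radius_px`` of the circle
    center.
    """

    name: str
    shape: Literal["rect", "circle"]
    rect: tuple[int, int, int, int] | None = None
    circle: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.shape == "rect":
            if self.rect is None:
                raise ConfigError(f"ROI {self.name!r}: rect bounds missing")
            r0, c0, h, w = self.rect
            if h <= 0 or w <= 0:
                raise ConfigError(f"ROI {self.name!r}: height and width must be > 0")
        elif self.shape == "circle":
            if self.circle is None:
                raise ConfigError(f"ROI {self.name!r}: circle parameters missing")
            _, _, r = self.circle
            if r <= 0:
                raise ConfigError(f"ROI {self.name!r}: radius must be > 0")
        else:
            raise ConfigError(f"ROI {self.name!r}: unknown shape {self.shape!r}")

    def validate_in(self, image_shape: tuple[int, int]) -> None:
        """Raise :class:`BoundsError` unless the ROI lies fully inside an
        image of the given (height, width)."""
        H, W = image_shape
        if self.shape == "rect":
            r0, c0, h, w = self.rect  # type: ignore[misc]
            if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
                raise BoundsError(
                    f"ROI {self.name!r} rect {self.rect} outside image {image_shape}"
                )
        else:
            cr, cc, r = self.circle  # type: ignore[misc]
            if cr - r < 0 or cc - r < 0 or cr + r > H - 1 or cc + r > W - 1:
                raise BoundsError(
                    f"ROI {self.name!r} circle {self.circle} outside image {image_shape}"
                )

    def mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask of this ROI in an image of given shape."""
        self.validate_in(image_shape)
        H, W = image_shape
        out = np.zeros((H, W), dtype=bool)
        if self.shape == "rect":
            r0, c0, h, w = self.rect  # type: ignore[misc]
            out[r0 : r0 + h, c0 : c0 + w] = True
        else:
            cr, cc, r = self.circle  # type: ignore[misc]
            rows = np.arange(H)[:, None]
            cols = np.arange(W)[None, :]
            out = (rows - cr) ** 2 + (cols - cc) ** 2 <= r**2
        return out

    def extract(self, image: Image2D) -> np.ndarray:
        """Pixel values of the image under this ROI, as a flat vector."""
        if self.shape == "rect":
            self.validate_in(image.shape)
            r0, c0, h, w = self.rect  # type: ignore[misc]
            return image.pixels[r0 : r0 + h, c0 : c0 + w].ravel()
        return image.pixels[self.mask(image.shape)]


@dataclass(frozen=True)
class WellSpec:
    """A circular well ROI annotated with its nominal content.

    ``role`` is ``sample`` for the dilution/depth series, ``control`` for
    the blank well and ``qd800`` for the quantum-dot room-light control.
    Exactly one of ``concentration_nm`` (nanomolar) / ``depth_mm`` is set
    for sample wells.
    """

    roi: RoiSpec
    role: Literal["sample", "control", "qd800"] = "sample"
    concentration_nm: float | None = None
    depth_mm: float | None = None

    @property
    def label(self) -> str:
        if self.role == "control":
            return "control"
        if self.role == "qd800":
            return "qd800"
        if self.concentration_nm is not None:
            return f"{self.concentration_nm:g} nM"
        if self.depth_mm is not None:
            return f"{self.depth_mm:g} mm"
        return self.roi.name


@dataclass
class SystemProfile:
    """Vendor-reported system metadata, echoed verbatim into reports.

    Power density and peak wavelength are bookkeeping: this package never
    measures them (they come from a power meter / data sheet), it only
    records them next to computed metrics.
    """

    system_id: str
    reported_peak_nm: float | None = None
    working_distance_cm: float | None = None
    fov_cm: tuple[float, float] | None = None
    power_density_mw_cm2: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        for attr in ("reported_peak_nm", "working_distance_cm", "power_density_mw_cm2"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ConfigError(f"{attr} must be positive, got {v}")
        if self.fov_cm is not None and any(x <= 0 for x in self.fov_cm):
            raise ConfigError(f"fov_cm must be positive, got {self.fov_cm}")


@dataclass
class Layout:
    """A phantom layout: named ROIs plus (optionally) annotated wells,
    validated against the declared image size."""

    image_shape: tuple[int, int]  # (height, width)
    rois: list[RoiSpec] = field(default_factory=list)
    wells: list[WellSpec] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [r.name for r in self.rois] + [w.roi.name for w in self.wells]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"duplicate ROI names: {sorted(dupes)}")
        for roi in self.rois:
            roi.validate_in(self.image_shape)
        for well in self.wells:
            well.roi.validate_in(self.image_shape)

    def roi(self, name: str) -> RoiSpec:
        for r in self.rois:
            if r.name == name:
                return r
        for w in self.wells:
            if w.roi.name == name:
                return w.roi
        raise ConfigError(f"no ROI named {name!r} in layout")


# ---------------------------------------------------------------------------
# Images


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    if arr.dtype == np.uint32:
        return 32
    # Float containers: choose the smallest standard depth that holds the data.
    mx = float(np.nanmax(arr)) if arr.size else 0.0
    for depth in (8, 12, 16, 32):
        if mx <= 2**depth - 1:
            return depth
    raise FormatError(f"cannot infer bit depth for max value {mx}")


def _reduce_channels(
    arr: np.ndarray, channel_policy: str, channel_index: int | None
) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3:
        raise FormatError(f"unsupported image dimensionality {arr.ndim}")
    if channel_policy == "as_is":
        raise FormatError(
            "color image with channel_policy='as_is'; choose 'luminance' or 'named_channel'"
        )
    if channel_policy == "luminance":
        return arr.astype(np.float64).mean(axis=2)
    if channel_policy == "named_channel":
        if channel_index is None:
            raise ConfigError("channel_policy='named_channel' requires channel_index")
        if not 0 <= channel_index < arr.shape[2]:
            raise ConfigError(
                f"channel_index {channel_index} out of range for {arr.shape[2]} channels"
            )
        return arr[:, :, channel_index]
    raise ConfigError(f"unknown channel_policy {channel_policy!r}")


def _read_video_frame(path: str, index: int) -> np.ndarray:
    try:
        import imageio.v3 as iio

        frames = iio.imiter(path)
        for i, frame in enumerate(frames):
            if i == index:
                return np.asarray(frame)
        raise NoFrameError(f"{path}: video has no frame {index}")
    except NoFrameError:
        raise
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise FormatError(f"no video backend available for {path}: {exc}") from exc
    except Exception as exc:
        raise FormatError(f"cannot read video {path}: {exc}") from exc


def load_image(
    path: str | os.PathLike,
    frame_policy: Literal["first_frame", "index"] = "first_frame",
    channel_policy: Literal["as_is", "luminance", "named_channel"] = "as_is",
    frame_index: int = 0,
    channel_index: int | None = None,
    pixel_pitch_mm: float | None = None,
) -> Image2D:
    """Load a still image or a single video frame as :class:`Image2D`.

    Vendors export single frames as TIFF/PNG/JPG or whole clips as MP4; for
    clips the first frame is quantified by default (``frame_policy=
    'index'`` with ``frame_index`` is the escape hatch).  JPEG sources are
    flagged lossy in the result's provenance.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    suffix = os.path.splitext(path)[1].lower()
    index = 0 if frame_policy == "first_frame" else int(frame_index)
    if suffix in _VIDEO_SUFFIXES:
        arr = _read_video_frame(path, index)
        source = f"{path}#{index}"
    elif suffix in _IMAGE_SUFFIXES:
        try:
            if suffix in (".tif", ".tiff"):
                arr = tifffile.imread(path)
            else:
                import imageio.v3 as iio

                arr = iio.imread(path)
        except Exception as exc:
            raise FormatError(f"cannot read image {path}: {exc}") from exc
        source = path
    else:
        raise FormatError(f"unsupported image format {suffix!r} for {path}")

    bit_depth = _infer_bit_depth(np.asarray(arr))
    scalar = _reduce_channels(np.asarray(arr), channel_policy, channel_index)
    return Image2D(
        pixels=scalar.astype(np.float64),
        bit_depth=bit_depth,
        source=source,
        pixel_pitch_mm=pixel_pitch_mm,
        channel_policy=channel_policy,
        lossy=suffix in (".jpg", ".jpeg"),
    )


def save_image(image: Image2D, path: str | os.PathLike) -> None:
    """Write an :class:`Image2D` as an 8- or 16-bit TIFF (bit-exact for
    integer-valued pixels, which round-trips through :func:`load_image`)."""
    path = os.fspath(path)
    if not path.lower().endswith((".tif", ".tiff")):
        raise FormatError("save_image writes TIFF only")
    dtype = np.uint8 if image.bit_depth <= 8 else np.uint16
    tifffile.imwrite(path, np.round(image.pixels).astype(dtype))


# ---------------------------------------------------------------------------
# Spectra


def load_spectrum(path: str | os.PathLike) -> SpectralTrace:
    """Read a two-column (wavelength_nm, intensity) CSV; an optional header
    row is skipped, rows are sorted by wavelength and duplicate wavelengths
    are collapsed by their mean intensity."""
    path = os.fspath(path)
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:
        raise ParseError(f"cannot read spectrum CSV {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns, got {df.shape[1]}")
    df = df.iloc[:, :2]
    # Drop a header row if the first row is non-numeric.
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = int(numeric.isna().any(axis=1).sum())
        raise ParseError(f"{path}: {bad} non-numeric data row(s)")
    numeric.columns = ["wavelength_nm", "intensity"]
    collapsed = numeric.groupby("wavelength_nm", sort=True, as_index=False).mean()
    if len(collapsed) < 8:
        raise InsufficientDataError(
            f"{path}: {len(collapsed)} distinct wavelengths; need >= 8"
        )
    return SpectralTrace(
        wavelength_nm=collapsed["wavelength_nm"].to_numpy(),
        intensity=collapsed["intensity"].to_numpy(),
    )


def save_spectrum(trace: SpectralTrace, path: str | os.PathLike) -> None:
    """Write a trace as a two-column CSV with header."""
    pd.DataFrame(
        {"wavelength_nm": trace.wavelength_nm, "intensity": trace.intensity}
    ).to_csv(os.fspath(path), index=False)


# ---------------------------------------------------------------------------
# Layouts


def _roi_from_mapping(entry: Mapping) -> RoiSpec:
    name = entry.get("name")
    if not name:
        raise ConfigError(f"ROI entry missing name: {entry}")
    shape = entry.get("shape")
    if shape == "rect":
        return RoiSpec(name=name, shape="rect", rect=tuple(int(v) for v in entry["bounds"]))
    if shape == "circle":
        return RoiSpec(
            name=name, shape="circle", circle=tuple(float(v) for v in entry["circle"])
        )
    raise ConfigError(f"ROI {name!r}: unknown shape {shape!r}")


def _well_from_mapping(entry: Mapping) -> WellSpec:
    roi = _roi_from_mapping({**entry, "shape": entry.get("shape", "circle")})
    role = entry.get("role", "sample")
    conc = entry.get("concentration_nm")
    depth = entry.get("depth_mm")
    if role == "sample" and conc is None and depth is None:
        raise ConfigError(f"well {roi.name!r}: sample wells need concentration_nm or depth_mm")
    return WellSpec(
        roi=roi,
        role=role,
        concentration_nm=None if conc is None else float(conc),
        depth_mm=None if depth is None else float(depth),
    )


def load_layout(path: str | os.PathLike) -> Layout:
    """Read a phantom layout from YAML or JSON.

    The document must declare the image size it applies to::

        image: {height: 480, width: 640}
        rois:
          - {name: band, shape: rect, bounds: [190, 0, 100, 640]}
        wells:
          - {name: w1000, circle: [100, 100, 40], concentration_nm: 1000}
          - {name: ctrl, circle: [300, 100, 40], role: control}
    """
    path = os.fspath(path)
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except Exception as exc:
        raise ConfigError(f"cannot parse layout {path}: {exc}") from exc
    if not isinstance(doc, Mapping) or "image" not in doc:
        raise ConfigError(f"{path}: layout must be a mapping with an 'image' section")
    img = doc["image"]
    shape = (int(img["height"]), int(img["width"]))
    rois = [_roi_from_mapping(e) for e in doc.get("rois", [])]
    wells = [_well_from_mapping(e) for e in doc.get("wells", [])]
    meta = dict(doc.get("metadata", {}))
    return Layout(image_shape=shape, rois=rois, wells=wells, metadata=meta)


def save_layout(layout: Layout, path: str | os.PathLike) -> None:
    """Serialize a layout to YAML in the format :func:`load_layout` reads."""
    doc: dict = {
        "image": {"height": layout.image_shape[0], "width": layout.image_shape[1]},
    }
    if layout.rois:
        doc["rois"] = [
            {
                "name": r.name,
                "shape": r.shape,
                **({"bounds": list(r.rect)} if r.shape == "rect" else {"circle": list(r.circle)}),
            }
            for r in layout.rois
        ]
    if layout.wells:
        entries = []
        for w in layout.wells:
            e: dict = {"name": w.roi.name, "circle": list(w.roi.circle), "role": w.role}
            if w.concentration_nm is not None:
                e["concentration_nm"] = w.concentration_nm
            if w.depth_mm is not None:
                e["depth_mm"] = w.depth_mm
            entries.append(e)
        doc["wells"] = entries
    if layout.metadata:
        doc["metadata"] = layout.metadata
    with open(os.fspath(path), "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
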