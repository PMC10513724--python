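"""Well-plate metrics: concentration sensitivity, imaging depth and
signal-to-background ratio (SBR).

A sensitivity plate carries a dilution series of ICG-equivalent wells
(1000 down to 1 nM), a 0 nM control and a QD800 quantum-dot well that
responds to visible room light rather than the excitation source.  A
depth plate carries 1000 nM-equivalent wells under increasing thicknesses
of tissue-mimicking overburden plus a blank control.  Both are quantified
as per-well mean / standard deviation over the well disk, normalized to
the panel maximum for display.

Detectability uses the conventional limit-of-detection rule: a well is
detected when its mean exceeds the control mean by ``k_sigma`` (default 3)
control standard deviations.  Saturation is flagged when a well sits at
the sensor ceiling or when its mean is indistinguishable (within 1% of
full scale) from the next-higher concentration.

SBR compares area-normalized power (mean of squared pixel values) inside
a well disk against the surrounding annulus of outer radius 1.5x the well
radius, in dB: ``10 * log10(signal_power / background_power)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import GeometryError, LayoutError, PanelError
from .io_config import Image2D, WellSpec

__all__ = [
    "WellMeasurement",
    "WellPanelResult",
    "DepthSummary",
    "SbrResult",
    "quantify_wells",
    "detect_floor_and_saturation",
    "depth_response",
    "compute_sbr",
    "sbr_wells_from_layout",
]


@dataclass(frozen=True)
class WellMeasurement:
    """Mean / standard deviation of one well, raw and panel-normalized."""

    label: str
    role: str
    concentration_nm: float | None
    depth_mm: float | None
    mean: float
    sd: float
    mean_norm: float
    sd_norm: float
    saturated: bool = False


@dataclass(frozen=True)
class WellPanelResult:
    """Quantified well panel.

    ``wells`` holds the sample series plus the control (the QD800 well, a
    different probe, is reported separately in ``qd800``).  Floor /
    saturation / LoD fields are populated by
    :func:`detect_floor_and_saturation`; ``lod_concentration_nm`` is None
    until then or when undetectable.
    """

    wells: tuple[WellMeasurement, ...]
    qd800: WellMeasurement | None
    noise_floor_mean: float
    noise_floor_sd: float
    bit_depth: int
    lod_concentration_nm: float | None = None
    lod_undefined: bool = False
    saturated_labels: tuple[str, ...] = ()
    k_sigma: float | None = None
    sat_frac: float | None = None

    @property
    def full_scale(self) -> float:
        return float(2**self.bit_depth - 1)

    def well(self, label: str) -> WellMeasurement:
        for w in self.wells:
            if w.label == label:
                return w
        raise PanelError(f"no well labelled {label!r}")


def _check_disjoint(specs: Sequence[WellSpec]) -> None:
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            r1c = specs[i].roi.circle
            r2c = specs[j].roi.circle
            if np.hypot(r1c[0] - r2c[0], r1c[1] - r2c[1]) <= r1c[2] + r2c[2]:
                raise LayoutError(
                    f"wells {specs[i].roi.name!r} and {specs[j].roi.name!r} overlap"
                )


def quantify_wells(image: Image2D, wells: Sequence[WellSpec]) -> WellPanelResult:
    """Per-well mean and standard deviation over disk pixels, normalized
    to the maximum well mean of the panel (QD800 excluded from the
    normalization of the ICG series)."""
    for w in wells:
        if w.roi.shape != "circle":
            raise LayoutError(f"well {w.roi.name!r} must be circular")
        w.roi.validate_in(image.shape)
    _check_disjoint(wells)
    controls = [w for w in wells if w.role == "control"]
    if len(controls) != 1:
        raise PanelError(f"panel needs exactly one control well, found {len(controls)}")

    raw: list[tuple[WellSpec, float, float]] = []
    for w in wells:
        vals = w.roi.extract(image)
        raw.append((w, float(vals.mean()), float(vals.std())))

    series = [(w, m, s) for (w, m, s) in raw if w.role != "qd800"]
    max_mean = max(m for (_, m, _) in series)
    scale = max_mean if max_mean > 0 else 1.0

    def _measure(w: WellSpec, m: float, s: float) -> WellMeasurement:
        return WellMeasurement(
            label=w.label,
            role=w.role,
            concentration_nm=w.concentration_nm,
            depth_mm=w.depth_mm,
            mean=m,
            sd=s,
            mean_norm=m / scale,
            sd_norm=s / scale,
        )

    measurements = tuple(_measure(w, m, s) for (w, m, s) in series)
    qd = next(
        (_measure(w, m, s) for (w, m, s) in raw if w.role == "qd800"), None
    )
    ctrl = next(m for m in measurements if m.role == "control")
    return WellPanelResult(
        wells=measurements,
        qd800=qd,
        noise_floor_mean=ctrl.mean,
        noise_floor_sd=ctrl.sd,
        bit_depth=image.bit_depth,
    )


def detect_floor_and_saturation(
    panel: WellPanelResult, k_sigma: float = 3.0, sat_frac: float = 0.99
) -> WellPanelResult:
    """Annotate a concentration panel with its limit of detection and
    saturated wells.

    LoD: the lowest concentration whose mean exceeds ``control_mean +
    k_sigma * control_sd``.  Saturation: raw mean at or above ``sat_frac``
    of full scale, or a mean within 1% of full scale of the next-higher
    concentration's mean (a plateau flags both members of the pair).
    """
    conc = sorted(
        (w for w in panel.wells if w.role == "sample" and w.concentration_nm is not None),
        key=lambda w: w.concentration_nm,
    )
    if len(conc) < 2:
        raise PanelError("need at least two concentration wells")

    criterion = panel.noise_floor_mean + k_sigma * panel.noise_floor_sd
    lod = None
    undefined = False
    detectable = [w for w in conc if w.mean > criterion]
    if detectable:
        lod = min(w.concentration_nm for w in detectable)
    elif panel.noise_floor_sd == 0 and all(w.mean == panel.noise_floor_mean for w in conc):
        undefined = True

    full = panel.full_scale
    saturated: set[str] = set()
    for w in conc:
        if w.mean >= sat_frac * full:
            saturated.add(w.label)
    # Plateau rule: saturation is a ceiling phenomenon, so walk down from
    # the highest concentration and flag wells indistinguishable (within 1%
    # of full scale) from the well above them; stop at the first real step.
    # This catches display ceilings that sit below the sensor full scale
    # without flagging indistinguishable wells down at the noise floor.
    for higher, lower in zip(conc[::-1][:-1], conc[::-1][1:]):
        if abs(higher.mean - lower.mean) < 0.01 * full:
            saturated.add(higher.label)
            saturated.add(lower.label)
        else:
            break

    wells = tuple(
        replace(w, saturated=w.label in saturated) if w.role == "sample" else w
        for w in panel.wells
    )
    return replace(
        panel,
        wells=wells,
        lod_concentration_nm=lod,
        lod_undefined=undefined,
        saturated_labels=tuple(sorted(saturated)),
        k_sigma=k_sigma,
        sat_frac=sat_frac,
    )


@dataclass(frozen=True)
class DepthSummary:
    """Depth-panel summary: the deepest detectable well and, when enough
    wells qualify, a log-linear attenuation fit ``mean - floor =
    I0 * exp(-depth / d_att_mm)``."""

    max_reliable_depth_mm: float | None
    d_att_mm: float | None
    i0: float | None
    fit_r2: float | None
    fit_skipped_reason: str | None
    k_sigma: float


def depth_response(
    panel: WellPanelResult, k_sigma: float = 3.0, sat_frac: float = 0.99
) -> DepthSummary:
    """Summarize a depth panel: deepest well still detected above the
    control criterion, plus an optional attenuation-length fit restricted
    to detectable, non-saturated wells."""
    depth_wells = sorted(
        (w for w in panel.wells if w.role == "sample" and w.depth_mm is not None),
        key=lambda w: w.depth_mm,
    )
    if not depth_wells:
        raise PanelError("panel has no depth-labelled wells")

    criterion = panel.noise_floor_mean + k_sigma * panel.noise_floor_sd
    detectable = [w for w in depth_wells if w.mean > criterion]
    max_depth = max((w.depth_mm for w in detectable), default=None)

    floor = panel.noise_floor_mean
    full = panel.full_scale
    fit_wells = [
        w
        for w in detectable
        if w.mean < sat_frac * full and w.mean - floor > 0
    ]
    if len(fit_wells) < 3:
        return DepthSummary(
            max_reliable_depth_mm=max_depth,
            d_att_mm=None,
            i0=None,
            fit_r2=None,
            fit_skipped_reason=f"only {len(fit_wells)} usable wells (need >= 3)",
            k_sigma=k_sigma,
        )
    d = np.array([w.depth_mm for w in fit_wells])
    y = np.log(np.array([w.mean - floor for w in fit_wells]))
    fit = stats.linregress(d, y)
    if fit.slope >= 0:
        return DepthSummary(
            max_reliable_depth_mm=max_depth,
            d_att_mm=None,
            i0=None,
            fit_r2=float(fit.rvalue**2),
            fit_skipped_reason="non-decaying response",
            k_sigma=k_sigma,
        )
    return DepthSummary(
        max_reliable_depth_mm=max_depth,
        d_att_mm=float(-1.0 / fit.slope),
        i0=float(np.exp(fit.intercept)),
        fit_r2=float(fit.rvalue**2),
        fit_skipped_reason=None,
        k_sigma=k_sigma,
    )


@dataclass(frozen=True)
class SbrWell:
    """SBR of one well: area-normalized powers and their ratio in dB."""

    label: str
    signal_power: float
    background_power: float
    sbr_db: float


@dataclass(frozen=True)
class SbrResult:
    """Per-well SBR plus the panel value (mean over the designated wells).

    Powers are means of squared pixel values, so disk and annulus areas
    need not match; the annulus spans radii ``(r, annulus_factor * r]``.
    """

    wells: tuple[SbrWell, ...]
    panel_sbr_db: float
    annulus_factor: float


def sbr_wells_from_layout(
    wells: Sequence[WellSpec], depths_mm: Sequence[float] = (2.0, 3.0, 4.0)
) -> list[WellSpec]:
    """Select the depth wells designated for SBR (default 2, 3 and 4 mm)."""
    chosen = [w for w in wells if w.depth_mm in set(depths_mm) and w.role == "sample"]
    if len(chosen) != len(depths_mm):
        raise LayoutError(
            f"expected wells at depths {tuple(depths_mm)} mm, found {len(chosen)}"
        )
    return chosen


def compute_sbr(
    image: Image2D, wells: Sequence[WellSpec], annulus_factor: float = 1.5
) -> SbrResult:
    """SBR in dB for each well against its surrounding annulus.

    The annulus must stay clear of every other well disk and must contain
    at least a quarter as many pixels as the disk (guards against annuli
    clipped by the frame edge).
    """
    if annulus_factor <= 1.0:
        raise GeometryError("annulus_factor must exceed 1")
    for w in wells:
        if w.roi.shape != "circle":
            raise LayoutError(f"SBR well {w.roi.name!r} must be circular")
        w.roi.validate_in(image.shape)

    H, W = image.shape
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    results = []
    for w in wells:
        cr, cc, r = w.roi.circle  # type: ignore[misc]
        outer = annulus_factor * r
        if cr - outer < 0 or cc - outer < 0 or cr + outer > H - 1 or cc + outer > W - 1:
            raise GeometryError(
                f"annulus of well {w.roi.name!r} leaves the image; use a smaller factor"
            )
        for other in wells:
            if other is w:
                continue
            ocr, occ, orr = other.roi.circle  # type: ignore[misc]
            if np.hypot(cr - ocr, cc - occ) <= outer + orr:
                raise GeometryError(
                    f"annulus of well {w.roi.name!r} intersects well "
                    f"{other.roi.name!r}; use a smaller annulus_factor"
                )
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        disk = d2 <= r**2
        annulus = (d2 > r**2) & (d2 <= outer**2)
        if annulus.sum() < disk.sum() / 4:
            raise GeometryError(f"annulus of well {w.roi.name!r} has too few pixels")
        signal_power = float(np.mean(image.pixels[disk] ** 2))
        background_power = float(np.mean(image.pixels[annulus] ** 2))
        if background_power <= 0:
            raise GeometryError(f"zero background power around well {w.roi.name!r}")
        results.append(
            SbrWell(
                label=w.label,
                signal_power=signal_power,
                background_power=background_power,
                sbr_db=float(10.0 * np.log10(signal_power / background_power)),
            )
        )
    return SbrResult(
        wells=tuple(results),
        panel_sbr_db=float(np.mean([r.sbr_db for r in results])),
        annulus_factor=annulus_factor,
    )
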