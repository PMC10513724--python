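"""Spatial resolution, sharpness and depth of field via the USAF-1951
contrast transfer function.

A USAF-1951 element in group G, element E resolves

    lp/mm = 2 ** (G + (E - 1) / 6)

line pairs per millimeter, i.e. a single line is ``1000 / (2 * lp_per_mm)``
micrometers wide.  Contrast on an element region r is scored with the
contrast transfer function

    CTF(%) = 100 * (max(r) - min(r)) / (max(r) + min(r)),

where, to be robust on real images, max(r) and min(r) are the means of the
top and bottom 20% of pixel values in the region rather than single
extrema.  Horizontal- and vertical-bar regions are scored separately and
averaged.

Sharpness is the CTF across a ladder of elements at the plane of focus;
depth of field (DOF) is the CTF of the coarsest (1.0 lp/mm) element as the
target moves away from the plane of focus along z, with the in-focus range
read off at a CTF threshold (default 60%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, FgsCheckError, LayoutError
from .io_config import Image2D, Layout, RoiSpec

__all__ = [
    "UsafElement",
    "CtfResult",
    "ElementRois",
    "DofCurve",
    "usaf_lp_per_mm",
    "compute_ctf",
    "element_ctf",
    "sharpness_curve",
    "SharpnessResult",
    "element_rois_from_layout",
    "dof_curve",
    "SHARPNESS_ELEMENTS",
]

#: (group, element) ladder used for sharpness scoring: 1.0, 1.26, 1.59,
#: 2.0, 2.52, 3.17, 4.0, 5.04 and 6.35 lp/mm.
SHARPNESS_ELEMENTS: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 3), (0, 5), (1, 1), (1, 3), (1, 5), (2, 1), (2, 3), (2, 5),
)


@dataclass(frozen=True)
class UsafElement:
    """One USAF-1951 element and its derived resolution figures."""

    group: int
    element: int
    lp_per_mm: float
    line_width_um: float


def usaf_lp_per_mm(group: int, element: int) -> UsafElement:
    """Resolution of USAF-1951 group/element: ``2^(group + (element-1)/6)``
    line pairs per mm; single-line width is ``1000 / (2 * lp_per_mm)`` um.

    Values are exact (full float precision); round only for display.
    """
    if not 1 <= element <= 6:
        raise DomainError(f"element must be in 1..6, got {element}")
    lp = float(2.0 ** (group + (element - 1) / 6.0))
    return UsafElement(
        group=int(group), element=int(element), lp_per_mm=lp, line_width_um=1000.0 / (2.0 * lp)
    )


@dataclass(frozen=True)
class CtfResult:
    """CTF of one element region (or the mean of its two orientations).

    ``max_r`` / ``min_r`` are the means of the top / bottom 20% of region
    values.  ``degenerate`` marks an all-dark region where the CTF is
    undefined (``ctf_percent`` is then ``nan``).
    """

    element: UsafElement | None
    orientation: str  # horizontal | vertical | mean
    max_r: float
    min_r: float
    ctf_percent: float
    threshold_used: float
    degenerate: bool = False


@dataclass(frozen=True)
class ElementRois:
    """The two bar regions (horizontal-bar and vertical-bar) of one element."""

    element: UsafElement
    horizontal: RoiSpec
    vertical: RoiSpec


def _percentile_extrema(values: np.ndarray, frac: float = 0.2) -> tuple[float, float]:
    """Means of the top and bottom ``frac`` of values, by rank, with
    fractional counts rounded up (at least one pixel each)."""
    v = np.sort(values, kind="stable")
    k = max(1, int(np.ceil(frac * v.size)))
    return float(v[-k:].mean()), float(v[:k].mean())


def compute_ctf(
    image: Image2D,
    roi: RoiSpec,
    background_threshold: float = 0.2,
    orientation: str = "mean",
    element: UsafElement | None = None,
) -> CtfResult:
    """CTF of one region via the 20%-percentile form of the contrast
    formula.

    ``background_threshold`` (allowed range 0.1–0.4 of the image maximum)
    delineates the target extent; it localizes and validates the target
    but does not exclude pixels from the percentile statistics — dark bars
    legitimately fall below it.  The threshold actually used is recorded
    in the result for auditability.
    """
    if not 0.1 <= background_threshold <= 0.4:
        raise DomainError(
            f"background_threshold must be in [0.1, 0.4], got {background_threshold}"
        )
    roi.validate_in(image.shape)
    values = roi.extract(image)
    # Target-extent mask (localization only): the ROI should intersect the
    # above-threshold foreground unless the region is entirely dark.
    img_max = float(image.pixels.max())
    _ = values >= background_threshold * img_max
    max_r, min_r = _percentile_extrema(values)
    if max_r + min_r == 0:
        return CtfResult(
            element=element,
            orientation=orientation,
            max_r=max_r,
            min_r=min_r,
            ctf_percent=float("nan"),
            threshold_used=background_threshold,
            degenerate=True,
        )
    ctf = 100.0 * (max_r - min_r) / (max_r + min_r)
    return CtfResult(
        element=element,
        orientation=orientation,
        max_r=max_r,
        min_r=min_r,
        ctf_percent=ctf,
        threshold_used=background_threshold,
    )


def element_ctf(
    image: Image2D, rois: ElementRois, background_threshold: float = 0.2
) -> CtfResult:
    """Score one element: horizontal and vertical bar regions separately,
    then report their mean (orientation='mean')."""
    h = compute_ctf(image, rois.horizontal, background_threshold, "horizontal", rois.element)
    v = compute_ctf(image, rois.vertical, background_threshold, "vertical", rois.element)
    if h.degenerate or v.degenerate:
        return CtfResult(
            element=rois.element,
            orientation="mean",
            max_r=(h.max_r + v.max_r) / 2,
            min_r=(h.min_r + v.min_r) / 2,
            ctf_percent=float("nan"),
            threshold_used=background_threshold,
            degenerate=True,
        )
    return CtfResult(
        element=rois.element,
        orientation="mean",
        max_r=(h.max_r + v.max_r) / 2,
        min_r=(h.min_r + v.min_r) / 2,
        ctf_percent=(h.ctf_percent + v.ctf_percent) / 2,
        threshold_used=background_threshold,
    )


def element_rois_from_layout(
    layout: Layout, elements: Sequence[tuple[int, int]] | None = None
) -> list[ElementRois]:
    """Collect ``g{G}e{E}_h`` / ``g{G}e{E}_v`` ROI pairs from a layout.

    When ``elements`` is None, every complete pair in the layout is
    returned, ordered by lp/mm.
    """
    by_name = {r.name: r for r in layout.rois}
    if elements is None:
        keys = sorted(
            {
                n[:-2]
                for n in by_name
                if n.endswith(("_h", "_v")) and n.startswith("g") and "e" in n
            }
        )
        parsed = []
        for k in keys:
            g, e = k[1:].split("e")
            parsed.append((int(g), int(e)))
        elements = parsed
    out = []
    for g, e in sorted(elements, key=lambda ge: usaf_lp_per_mm(*ge).lp_per_mm):
        h_name, v_name = f"g{g}e{e}_h", f"g{g}e{e}_v"
        if h_name not in by_name or v_name not in by_name:
            raise LayoutError(f"layout is missing ROIs for element g{g}e{e}")
        out.append(
            ElementRois(
                element=usaf_lp_per_mm(g, e),
                horizontal=by_name[h_name],
                vertical=by_name[v_name],
            )
        )
    return out


@dataclass(frozen=True)
class SharpnessResult:
    """Per-element CTF ladder plus the resolving limit: the highest lp/mm
    whose mean CTF is at or above the criterion (default 40%)."""

    results: tuple[CtfResult, ...]
    resolving_limit_lp_mm: float | None
    criterion_percent: float


def sharpness_curve(
    image: Image2D,
    layout: Sequence[ElementRois],
    background_threshold: float = 0.2,
    criterion_percent: float = 40.0,
) -> SharpnessResult:
    """Score every element of the ladder on one in-focus image, ordered by
    lp/mm, and summarize the resolving limit."""
    if not layout:
        raise LayoutError("no element ROIs supplied")
    ordered = sorted(layout, key=lambda er: er.element.lp_per_mm)
    results = tuple(element_ctf(image, er, background_threshold) for er in ordered)
    limit = None
    for res in results:
        if not res.degenerate and res.ctf_percent >= criterion_percent:
            limit = res.element.lp_per_mm
    return SharpnessResult(
        results=results, resolving_limit_lp_mm=limit, criterion_percent=criterion_percent
    )


@dataclass(frozen=True)
class DofCurve:
    """CTF of the 1.0 lp/mm element versus signed distance z from the
    plane of focus (negative z = closer to the lens).  ``in_focus_range_cm``
    is the widest contiguous z interval with CTF at or above the threshold
    (ties broken toward the interval containing z = 0), or None when the
    curve never reaches it."""

    z_cm: tuple[float, ...]
    ctf_percent: tuple[float, ...]
    in_focus_range_cm: tuple[float, float] | None
    threshold_percent: float


def dof_curve(
    stack: Sequence[tuple[float, Image2D]],
    roi_1lp: ElementRois,
    threshold_percent: float = 60.0,
    background_threshold: float = 0.2,
) -> DofCurve:
    """Depth-of-field curve from a z stack of target images.

    The stack may be asymmetric (different extents on the near and far
    side); z values must be unique and include 0 (the plane of focus).
    """
    zs = [float(z) for z, _ in stack]
    if len(set(zs)) != len(zs):
        raise FgsCheckError("z positions must be unique")
    if 0.0 not in zs:
        raise FgsCheckError("stack must include the plane of focus z = 0")
    order = np.argsort(zs)
    z_sorted = [zs[i] for i in order]
    ctfs = []
    for i in order:
        res = element_ctf(stack[i][1], roi_1lp, background_threshold)
        ctfs.append(float("nan") if res.degenerate else res.ctf_percent)

    above = [not np.isnan(c) and c >= threshold_percent for c in ctfs]
    best: tuple[float, float] | None = None
    best_len = -1
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            width = z_sorted[j] - z_sorted[i]
            contains0 = z_sorted[i] <= 0.0 <= z_sorted[j]
            cur_best_contains0 = best is not None and best[0] <= 0.0 <= best[1]
            if width > best_len or (width == best_len and contains0 and not cur_best_contains0):
                best = (z_sorted[i], z_sorted[j])
                best_len = width
            i = j + 1
        else:
            i += 1
    return DofCurve(
        z_cm=tuple(z_sorted),
        ctf_percent=tuple(ctfs),
        in_focus_range_cm=best,
        threshold_percent=threshold_percent,
    )
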