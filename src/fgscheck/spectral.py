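"""Excitation-band analysis: peak wavelength and FWHM.

The excitation source of a fluorescence-guided-surgery system is
characterized by the full width at half maximum (FWHM) of its spectral
band, in nanometers.  A narrow band means high wavelength specificity and
little off-target excitation of tissue autofluorophores.

The estimator is deliberately plain: a robust baseline (median of the
lowest decile of intensities) is subtracted, the peak is the sample
maximum (wavelength-centroid of the maximal plateau on ties), and the two
half-maximum crossings are located by linear interpolation between the
bracketing samples.  No smoothing is applied by default because smoothing
biases the width; a 3-point moving median is available for spiky traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .errors import UnresolvedBandError
from .io_config import SpectralTrace

__all__ = ["SpectralResult", "compute_fwhm"]


@dataclass(frozen=True)
class SpectralResult:
    """Peak and width of a single spectral band.

    ``left_half_nm`` / ``right_half_nm`` are the interpolated wavelengths
    where the baseline-subtracted intensity crosses half its maximum;
    ``fwhm_nm = right_half_nm - left_half_nm``.
    """

    peak_nm: float
    fwhm_nm: float
    left_half_nm: float
    right_half_nm: float
    baseline_level: float
    normalized: bool

    def __post_init__(self) -> None:
        if not self.left_half_nm < self.peak_nm < self.right_half_nm:
            raise UnresolvedBandError(
                f"half crossings {self.left_half_nm}, {self.right_half_nm} do not "
                f"bracket peak {self.peak_nm}"
            )


def _interp_crossing(
    wl: np.ndarray, y: np.ndarray, i_lo: int, i_hi: int, half: float
) -> float:
    """Wavelength where y crosses ``half`` between samples i_lo and i_hi."""
    y0, y1 = y[i_lo], y[i_hi]
    if y1 == y0:
        return float(wl[i_lo])
    t = (half - y0) / (y1 - y0)
    return float(wl[i_lo] + t * (wl[i_hi] - wl[i_lo]))


def compute_fwhm(trace: SpectralTrace, smooth: bool = False) -> SpectralResult:
    """Measure peak wavelength and FWHM of a single-band trace.

    Raises :class:`UnresolvedBandError` when the peak sits at either end of
    the trace or when a half-maximum crossing is missing on one side (the
    band is not fully contained in the sampled window).
    """
    wl = trace.wavelength_nm
    y = trace.intensity.astype(np.float64)
    if smooth:
        y = median_filter(y, size=3, mode="nearest")

    n_low = max(1, int(np.ceil(0.1 * y.size)))
    baseline = float(np.median(np.sort(y)[:n_low]))
    ys = y - baseline

    ymax = ys.max()
    if ymax <= 0:
        raise UnresolvedBandError("trace has no signal above baseline")
    # Normalization is recorded but never affects the result (the estimator
    # is scale invariant); traces whose raw max is 1 are treated as already
    # normalized display exports.
    normalized = bool(np.isclose(y.max(), 1.0, rtol=1e-6))

    at_max = np.flatnonzero(ys == ymax)
    # Maximal plateau: contiguous run of equal maxima -> wavelength centroid.
    runs = np.split(at_max, np.flatnonzero(np.diff(at_max) > 1) + 1)
    run = max(runs, key=len)
    peak_nm = float(wl[run].mean())
    i_peak_l, i_peak_r = int(run[0]), int(run[-1])
    if i_peak_l == 0 or i_peak_r == y.size - 1:
        raise UnresolvedBandError("peak lies at the boundary of the sampled window")

    half = ymax / 2.0
    below_left = np.flatnonzero(ys[:i_peak_l] < half)
    if below_left.size == 0:
        raise UnresolvedBandError("no half-maximum crossing on the short-wavelength side")
    i = int(below_left[-1])
    left = _interp_crossing(wl, ys, i, i + 1, half)

    below_right = np.flatnonzero(ys[i_peak_r + 1 :] < half)
    if below_right.size == 0:
        raise UnresolvedBandError("no half-maximum crossing on the long-wavelength side")
    j = int(below_right[0]) + i_peak_r + 1
    right = _interp_crossing(wl, ys, j - 1, j, half)

    return SpectralResult(
        peak_nm=peak_nm,
        fwhm_nm=right - left,
        left_half_nm=left,
        right_half_nm=right,
        baseline_level=baseline,
        normalized=normalized,
    )
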