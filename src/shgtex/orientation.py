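"""Orientation index (OI) of a ROI from its thresholded Fourier spectrum.

The anisotropy of the fiber network in a ROI is summarized by

    OI = 1 - short_axis / long_axis

where the axes are those of the equivalent ellipse of the binary mask
obtained by thresholding the max-normalized FFT magnitude at 0.38.
OI = 0 marks an isotropic structure (circular spectrum), OI = 1 perfectly
oriented fibers (the spectrum collapses onto a line).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

DEFAULT_THRESHOLD = 0.38


@dataclass
class SpectrumMask:
    """Binary FFT-magnitude mask (shifted, DC at center) with provenance."""

    mask: np.ndarray
    threshold: float
    window_applied: bool
    degenerate: bool = False


@dataclass
class AxisEstimate:
    """Equivalent-ellipse axes of a spectrum mask and the derived OI."""

    short_axis_px: float
    long_axis_px: float
    oi: float
    degenerate: bool = False


def fft_magnitude(roi_pixels: np.ndarray, window: bool = True) -> np.ndarray:
    """Max-normalized, DC-suppressed, center-shifted FFT magnitude.

    The mean is subtracted before the transform (removes the DC peak) and a
    separable Hann taper is applied by default to suppress the edge-induced
    axis-aligned cross. A constant input yields an all-zero magnitude.
    """
    x = np.asarray(roi_pixels, dtype=float)
    if x.ndim != 2:
        raise ValueError("roi_pixels must be 2D")
    if not np.all(np.isfinite(x)):
        raise ValueError("roi_pixels contain non-finite values")
    x = x - x.mean()
    if window:
        x = x * np.outer(hann(x.shape[0]), hann(x.shape[1]))
    mag = np.abs(np.fft.fftshift(np.fft.fft2(x)))
    peak = mag.max()
    if peak == 0.0:
        return np.zeros_like(mag)
    return mag / peak


def binarize_spectrum(
    magnitude: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    window_applied: bool = True,
) -> SpectrumMask:
    """Threshold the normalized magnitude; pixels >= threshold are kept."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    mag = np.asarray(magnitude, dtype=float)
    if mag.min() < 0.0 or mag.max() > 1.0 + 1e-12:
        raise ValueError("magnitude must be max-normalized to [0, 1]")
    mask = mag >= threshold
    return SpectrumMask(
        mask=mask,
        threshold=float(threshold),
        window_applied=window_applied,
        degenerate=not mask.any(),
    )


def estimate_axes(spectrum_mask: SpectrumMask) -> AxisEstimate:
    """Short/long axes of the mask's equivalent ellipse and the OI.

    Central second moments of the true-pixel point set give a 2x2 moment
    matrix with eigenvalues lam1 >= lam2; the equivalent-ellipse convention
    sets long = 4*sqrt(lam1), short = 4*sqrt(lam2). A collinear mask
    (lam2 = 0) yields OI = 1; a single-pixel mask (both zero) is reported
    as the isotropic limit OI = 0 with the degenerate flag set.
    """
    if spectrum_mask.degenerate or not spectrum_mask.mask.any():
        raise ValueError("degenerate spectrum: empty mask")
    pts = np.argwhere(spectrum_mask.mask).astype(float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    lam2, lam1 = np.sort(np.linalg.eigvalsh(cov))
    lam2 = max(lam2, 0.0)
    if lam1 <= 0.0:  # single pixel
        return AxisEstimate(0.0, 0.0, 0.0, degenerate=True)
    long_axis = 4.0 * np.sqrt(lam1)
    short_axis = 4.0 * np.sqrt(lam2)
    oi = 1.0 - short_axis / long_axis
    return AxisEstimate(float(short_axis), float(long_axis), float(oi))


def orientation_index(
    roi_pixels: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    window: bool = True,
) -> AxisEstimate:
    """OI of a ROI: FFT magnitude -> 0.38 binarization -> axis ratio.

    A constant (degenerate) ROI yields ``oi = nan`` with the flag set.
    """
    mag = fft_magnitude(roi_pixels, window=window)
    if not np.any(mag > 0.0):
        return AxisEstimate(np.nan, np.nan, np.nan, degenerate=True)
    mask = binarize_spectrum(mag, threshold=threshold, window_applied=window)
    if mask.degenerate:
        return AxisEstimate(np.nan, np.nan, np.nan, degenerate=True)
    return estimate_axes(mask)
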