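"""First- and second-order texture statistics of a ROI.

First-order statistics (FOS) are the population moments of the intensity
histogram: mean, standard deviation, skewness and (non-excess) kurtosis,
each normalized by the pixel count n^2.

Second-order statistics (SOS) derive from the gray-level co-occurrence
matrix (GLCM) P_ij — the probability of observing the intensity-level pair
(i, j) at a fixed pixel offset: energy, inertia (contrast), correlation,
inverse difference moment (homogeneity) and entropy (natural log).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_N_LEVELS = 64
DEFAULT_DIRECTIONS = (0.0, 45.0, 90.0, 135.0)


@dataclass
class FOSFeatures:
    mean: float
    std: float
    skewness: float  # nan when std == 0
    kurtosis: float  # non-excess; nan when std == 0
    n_pixels: int


@dataclass
class GLCM:
    """Normalized co-occurrence probability matrix with its parameters."""

    p: np.ndarray
    n_levels: int
    offsets: list
    symmetric: bool

    @property
    def marginal_i(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def marginal_j(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @property
    def mu_i(self) -> float:
        return float(np.arange(self.n_levels) @ self.marginal_i)

    @property
    def mu_j(self) -> float:
        return float(np.arange(self.n_levels) @ self.marginal_j)

    @property
    def sigma_i(self) -> float:
        i = np.arange(self.n_levels)
        return float(np.sqrt((i - self.mu_i) ** 2 @ self.marginal_i))

    @property
    def sigma_j(self) -> float:
        j = np.arange(self.n_levels)
        return float(np.sqrt((j - self.mu_j) ** 2 @ self.marginal_j))


@dataclass
class SOSFeatures:
    energy: float
    inertia: float
    correlation: float
    idm: float
    entropy: float


def fos_features(roi_pixels: np.ndarray) -> FOSFeatures:
    """Population mean, std, skewness and non-excess kurtosis of a ROI.

    All moments are normalized by the pixel count (divide-by-n^2, not
    n^2 - 1). For a constant ROI (std = 0) skewness and kurtosis are
    undefined and reported as nan.
    """
    x = np.asarray(roi_pixels, dtype=float)
    if x.size == 0:
        raise ValueError("empty ROI")
    if not np.all(np.isfinite(x)):
        raise ValueError("roi_pixels contain non-finite values")
    n = x.size
    mu = x.mean()
    dev = x - mu
    var = np.mean(dev**2)
    std = np.sqrt(var)
    if std == 0.0:
        skew = kurt = np.nan
    else:
        skew = np.mean(dev**3) / std**3
        kurt = np.mean(dev**4) / var**2
    return FOSFeatures(
        mean=float(mu), std=float(std), skewness=float(skew),
        kurtosis=float(kurt), n_pixels=int(n),
    )


def _direction_offset(angle_deg: float, distance_px: int) -> tuple:
    """Offset (drow, dcol) for a co-occurrence direction.

    0 deg is the +col direction; angles rotate counter-clockwise in the
    usual image convention (row axis points down), so 45 deg is up-right.
    """
    lookup = {
        0.0: (0, distance_px),
        45.0: (-distance_px, distance_px),
        90.0: (-distance_px, 0),
        135.0: (-distance_px, -distance_px),
    }
    a = float(angle_deg) % 180.0
    if a not in lookup:
        raise ValueError(f"unsupported GLCM direction {angle_deg} deg")
    return lookup[a]


def quantize(roi_pixels: np.ndarray, n_levels: int) -> np.ndarray:
    """Linear rebin of intensities to n_levels over the ROI's [min, max].

    A constant image maps every pixel to level 0.
    """
    x = np.asarray(roi_pixels, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.shape, dtype=np.intp)
    levels = ((x - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.minimum(levels, n_levels - 1)


def compute_glcm(
    roi_pixels: np.ndarray,
    n_levels: int = DEFAULT_N_LEVELS,
    distance_px: int = 1,
    directions=DEFAULT_DIRECTIONS,
    symmetric: bool = True,
) -> GLCM:
    """Gray-level co-occurrence matrix of a ROI.

    Intensities are rebinned to ``n_levels`` over the ROI's own [min, max]
    range; co-occurrences are accumulated over all ``directions`` at the
    stated pixel ``distance_px``, symmetrized by adding the transpose when
    ``symmetric``, then normalized to sum to 1.
    """
    x = np.asarray(roi_pixels, dtype=float)
    if x.ndim != 2:
        raise ValueError("roi_pixels must be 2D")
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    levels = quantize(x, n_levels)
    h, w = levels.shape
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    offsets = [_direction_offset(a, distance_px) for a in directions]
    n_pairs = 0
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = levels[r0:r1, c0:c1].ravel()
        b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        counts += np.bincount(
            a * n_levels + b, minlength=n_levels * n_levels
        ).reshape(n_levels, n_levels)
        n_pairs += a.size
    if n_pairs == 0:
        raise ValueError("image smaller than the co-occurrence offset in all directions")
    if symmetric:
        counts = counts + counts.T
    return GLCM(
        p=counts / counts.sum(),
        n_levels=int(n_levels),
        offsets=offsets,
        symmetric=bool(symmetric),
    )


def sos_features(glcm: GLCM) -> SOSFeatures:
    """Energy, inertia, correlation, IDM and entropy of a GLCM.

    Entropy uses the natural log with the 0*ln(0) := 0 convention. The
    correlation of a zero-variance GLCM (all mass on one level, as for a
    uniform image) is defined as 0.
    """
    p = glcm.p
    n = glcm.n_levels
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    energy = float(np.sum(p**2))
    inertia = float(np.sum((i - j) ** 2 * p))
    idm = float(np.sum(p / (1.0 + (i - j) ** 2)))
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log(p[nz])))
    si, sj = glcm.sigma_i, glcm.sigma_j
    if si == 0.0 or sj == 0.0:
        correlation = 0.0
    else:
        correlation = float(
            np.sum((i - glcm.mu_i) * (j - glcm.mu_j) * p) / (si * sj)
        )
    return SOSFeatures(
        energy=energy, inertia=inertia, correlation=correlation,
        idm=idm, entropy=entropy,
    )
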