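"""Square ROI selection near vessel walls.

Analysis regions are 150 x 150 um^2 squares placed no further than 500 um
from the blood vessel wall, non-overlapping, 50-80 per experimental group.
Placement is a seeded greedy procedure over a candidate grid so that runs
are reproducible; the manual selection it replaces offers no such guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import ImagePatch


@dataclass(frozen=True)
class ROI:
    """An axis-aligned square region within a source image.

    ``origin`` is the (row, col) of the top-left pixel, 0-based inclusive.
    """

    origin: tuple
    side_px: int
    side_um: float
    vessel_distance_um: float | None
    id: str

    @property
    def slices(self) -> tuple:
        r, c = self.origin
        return (slice(r, r + self.side_px), slice(c, c + self.side_px))

    def overlaps(self, other: "ROI") -> bool:
        r1, c1 = self.origin
        r2, c2 = other.origin
        return (
            abs(r1 - r2) < min(self.side_px, other.side_px)
            and abs(c1 - c2) < min(self.side_px, other.side_px)
        )


@dataclass
class ROISet:
    rois: list
    source_image_id: str
    seed: int
    warnings: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def to_dict(self) -> dict:
        return {
            "source_image_id": self.source_image_id,
            "seed": self.seed,
            "count": len(self.rois),
            "warnings": list(self.warnings),
            "rois": [
                {
                    "id": r.id,
                    "origin": list(r.origin),
                    "side_px": r.side_px,
                    "side_um": r.side_um,
                    "vessel_distance_um": r.vessel_distance_um,
                }
                for r in self.rois
            ],
        }


def vessel_distance_map(vessel_mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Euclidean distance (um) from each pixel to the nearest vessel pixel.

    Vessel-interior pixels hold 0. Raises if the mask is empty.
    """
    mask = np.asarray(vessel_mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("vessel_mask must be 2D")
    if not mask.any():
        raise ValueError("vessel_mask is empty: no vessel present")
    return ndimage.distance_transform_edt(~mask) * float(pixel_size_um)


def extract_roi(image: ImagePatch, roi: ROI) -> ImagePatch:
    """Crop an ROI out of its source image, keeping pixel size and channel."""
    return ImagePatch(
        image.pixels[roi.slices], image.pixel_size_um, image.channel
    )


def _window_contains(mask: np.ndarray, side: int) -> np.ndarray:
    """For every valid origin, whether the side x side window hits the mask."""
    integ = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    integ[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1)
    h, w = mask.shape
    nr, nc = h - side + 1, w - side + 1
    s = (
        integ[side : side + nr, side : side + nc]
        - integ[0:nr, side : side + nc]
        - integ[side : side + nr, 0:nc]
        + integ[0:nr, 0:nc]
    )
    return s > 0


def feasible_origins(
    image_shape: tuple,
    side_px: int,
    vessel_mask: np.ndarray | None,
    distance_map_um: np.ndarray | None,
    max_distance_um: float,
    stride: int,
) -> list:
    """Candidate ROI origins satisfying the distance and lumen rules.

    With a vessel mask, an origin is feasible when the ROI center lies at
    most ``max_distance_um`` from the vessel wall and no ROI pixel falls
    inside the lumen. Without one, all grid origins are feasible
    (whole-image tiling).
    """
    h, w = image_shape
    origins = []
    if vessel_mask is not None:
        hits = _window_contains(np.asarray(vessel_mask).astype(bool), side_px)
    half = side_px // 2
    for r in range(0, h - side_px + 1, stride):
        for c in range(0, w - side_px + 1, stride):
            if vessel_mask is None:
                origins.append((r, c))
                continue
            if hits[r, c]:
                continue  # ROI would intersect the lumen
            if distance_map_um[r + half, c + half] > max_distance_um:
                continue
            origins.append((r, c))
    return origins


def select_rois(
    image: ImagePatch,
    vessel_mask: np.ndarray | None = None,
    side_um: float = 150.0,
    max_distance_um: float = 500.0,
    min_count: int = 50,
    max_count: int = 80,
    seed: int = 0,
    source_image_id: str = "image",
    tile_without_vessel: bool = True,
) -> ROISet:
    """Select non-overlapping square ROIs near the vessel wall.

    ROIs are squares of side ``round(side_um / pixel_size_um)`` px. With a
    vessel mask, candidates lie on a half-side-stride grid and must satisfy
    the center-distance (<= ``max_distance_um``) and lumen-exclusion rules;
    without one (and ``tile_without_vessel``) the image is tiled on a
    full-side-stride grid. A seeded random ordering is accepted greedily
    under the pairwise non-overlap constraint, up to ``max_count``; a
    warning is recorded when fewer than ``min_count`` fit.
    """
    if side_um <= 0:
        raise ValueError(f"side_um must be > 0, got {side_um}")
    side_px = int(round(side_um / image.pixel_size_um))
    h, w = image.pixels.shape[:2]
    if side_px > min(h, w):
        raise ValueError(
            f"ROI side {side_px} px ({side_um} um at {image.pixel_size_um} um/px) "
            f"exceeds image of shape {(h, w)}"
        )
    if side_px < 1:
        raise ValueError("ROI side rounds to zero pixels")

    warnings_list = []
    if vessel_mask is None:
        if not tile_without_vessel:
            raise ValueError(
                "no vessel mask given and whole-image tiling is disabled"
            )
        dist_map = None
        stride = side_px
        warnings_list.append("no vessel mask: whole-image tiling fallback used")
    else:
        dist_map = vessel_distance_map(vessel_mask, image.pixel_size_um)
        stride = max(side_px // 2, 1)

    candidates = feasible_origins(
        (h, w), side_px, vessel_mask, dist_map, max_distance_um, stride
    )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    accepted = []
    half = side_px // 2
    for idx in order:
        if len(accepted) >= max_count:
            break
        r, c = candidates[idx]
        if any(abs(r - ar) < side_px and abs(c - ac) < side_px for ar, ac in accepted):
            continue
        accepted.append((r, c))

    accepted.sort()
    rois = []
    for k, (r, c) in enumerate(accepted):
        dist = None if dist_map is None else float(dist_map[r + half, c + half])
        rois.append(
            ROI(
                origin=(r, c),
                side_px=side_px,
                side_um=side_px * image.pixel_size_um,
                vessel_distance_um=dist,
                id=f"{source_image_id}_roi{k:03d}",
            )
        )
    if len(rois) < min_count:
        warnings_list.append(
            f"only {len(rois)} ROIs fit (minimum requested {min_count})"
        )
    return ROISet(
        rois=rois, source_image_id=source_image_id, seed=int(seed),
        warnings=warnings_list,
    )


def validate_roi_set(
    roi_set: ROISet,
    image: ImagePatch,
    vessel_mask: np.ndarray | None = None,
    max_distance_um: float = 500.0,
) -> None:
    """Independently re-check every ROI constraint; raises on violation."""
    h, w = image.pixels.shape[:2]
    for roi in roi_set:
        r, c = roi.origin
        if r < 0 or c < 0 or r + roi.side_px > h or c + roi.side_px > w:
            raise AssertionError(f"ROI {roi.id} outside image bounds")
        if abs(roi.side_um - roi.side_px * image.pixel_size_um) > image.pixel_size_um:
            raise AssertionError(f"ROI {roi.id} physical side inconsistent")
        if vessel_mask is not None:
            if np.asarray(vessel_mask, dtype=bool)[roi.slices].any():
                raise AssertionError(f"ROI {roi.id} intersects the vessel lumen")
            dmap = vessel_distance_map(vessel_mask, image.pixel_size_um)
            half = roi.side_px // 2
            if dmap[r + half, c + half] > max_distance_um:
                raise AssertionError(f"ROI {roi.id} center too far from vessel")
    for i, a in enumerate(roi_set.rois):
        for b in roi_set.rois[i + 1 :]:
            if a.overlaps(b):
                raise AssertionError(f"ROIs {a.id} and {b.id} overlap")
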