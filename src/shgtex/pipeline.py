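"""End-to-end orchestration: images -> ROIs -> features -> group statistics.

The pipeline mirrors the standard SHG workflow: load (or simulate) the
micrographs of each experimental group, tile square ROIs near vessel
walls, compute the orientation index plus first- and second-order texture
features per ROI, and compare every feature between groups. Outputs are a
per-ROI feature table (CSV), a comparison table (CSV) and a JSON run log;
a fixed seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .image import ImagePatch
from .io import read_image, write_log, write_table
from .orientation import orientation_index
from .roi import extract_roi, select_rois, validate_roi_set
from .stats import FEATURE_COLUMNS, FeatureRecord, compare_groups
from .synthetic import generate_fiber_image, generate_vessel_scene
from .texture import compute_glcm, fos_features, sos_features


@dataclass
class RunConfig:
    """Complete, hashable description of one pipeline run."""

    seed: int = 0
    pixel_size_um: float = 0.15
    # either a simulation spec ...
    simulate: dict | None = None
    # ... or an input manifest: list of {path, group, vessel_mask, pixel_size_um}
    images: list = field(default_factory=list)
    roi: dict = field(default_factory=lambda: {
        "side_um": 150.0,
        "max_distance_um": 500.0,
        "min_count": 50,
        "max_count": 80,
        "tile_without_vessel": True,
    })
    fft: dict = field(default_factory=lambda: {"threshold": 0.38, "window": True})
    glcm: dict = field(default_factory=lambda: {
        "n_levels": 64,
        "distance_px": 1,
        "directions": [0.0, 45.0, 90.0, 135.0],
        "symmetric": True,
    })
    stars_mode: str = "vs-control"  # or "all-pairs"
    control_label: str = "control"
    out_dir: str | None = None
    qc: bool = False  # export ROI overlays and spectrum masks as PNG

    def __post_init__(self) -> None:
        defaults = RunConfig.__dataclass_fields__
        for name in ("roi", "fft", "glcm"):
            merged = defaults[name].default_factory()
            merged.update(getattr(self, name) or {})
            setattr(self, name, merged)
        if self.stars_mode not in ("vs-control", "all-pairs"):
            raise ValueError(f"unknown stars_mode {self.stars_mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant parameters (out_dir excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_roi_overlay(patch, roi_set, path) -> None:
    """QC PNG: the image with 1-px ROI rectangle outlines burned in."""
    import imageio.v3 as iio

    img = np.asarray(patch.pixels, float)
    lo, hi = img.min(), img.max()
    canvas = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo) * 255.0
    for roi in roi_set:
        r, c = roi.origin
        s = roi.side_px
        canvas[r, c : c + s] = 255.0
        canvas[r + s - 1, c : c + s] = 255.0
        canvas[r : r + s, c] = 255.0
        canvas[r : r + s, c + s - 1] = 255.0
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, canvas.astype(np.uint8))


def _write_spectrum_mask(pixels, config, path) -> None:
    """QC PNG: the binarized FFT-magnitude mask of one ROI."""
    import imageio.v3 as iio

    from .orientation import binarize_spectrum, fft_magnitude

    mag = fft_magnitude(pixels, window=config.fft["window"])
    if not np.any(mag > 0):
        return  # degenerate ROI: nothing to show
    mask = binarize_spectrum(mag, threshold=config.fft["threshold"])
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (mask.mask * np.uint8(255)))


def simulate_inputs(config: RunConfig):
    """Generate the per-group images described by ``config.simulate``.

    Yields (image_id, group_label, ImagePatch, vessel_mask_or_None, truth).
    Per-image seeds derive deterministically from the run seed.
    """
    sim = config.simulate
    if not sim:
        raise ValueError("config has no simulation spec")
    shape_px = tuple(sim.get("shape_px", (256, 256)))
    vessel = sim.get("vessel")
    groups = sim["groups"]
    ss = np.random.SeedSequence(config.seed)
    child_seeds = iter(ss.generate_state(sum(g.get("n_images", 1) for g in groups.values())))
    for label, gparams in groups.items():
        n_images = int(gparams.get("n_images", 1))
        fiber_params = {
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in gparams.items()
            if k != "n_images"
        }
        for i in range(n_images):
            img_seed = int(next(child_seeds))
            image_id = f"{label}_img{i:02d}"
            if vessel:
                patch, truth = generate_vessel_scene(
                    shape_px=shape_px,
                    vessel_radius_px=vessel.get("radius_px", 60.0),
                    wall_thickness_px=vessel.get("wall_thickness_px", 15.0),
                    collagen_params=fiber_params,
                    pixel_size_um=config.pixel_size_um,
                    seed=img_seed,
                )
                yield image_id, label, patch, truth.vessel_mask, truth
            else:
                patch, truth = generate_fiber_image(
                    shape_px=shape_px,
                    pixel_size_um=config.pixel_size_um,
                    seed=img_seed,
                    **fiber_params,
                )
                yield image_id, label, patch, None, truth


def load_inputs(config: RunConfig):
    """Read the images listed in the manifest, with per-entry vessel masks."""
    if not config.images:
        raise ValueError("config lists no input images")
    group_px: dict = {}
    entries = []
    for entry in config.images:
        px = entry.get("pixel_size_um", config.pixel_size_um)
        patch = read_image(entry["path"], pixel_size_um=px)
        group = entry["group"]
        if group in group_px and group_px[group] != patch.pixel_size_um:
            raise ValueError(
                f"inconsistent pixel sizes within group {group!r}"
            )
        group_px[group] = patch.pixel_size_um
        mask = None
        if entry.get("vessel_mask"):
            mask = read_image(
                entry["vessel_mask"], pixel_size_um=patch.pixel_size_um
            ).pixels.astype(bool)
        entries.append((Path(entry["path"]).stem, group, patch, mask, None))
    return entries


def analyze_roi(pixels: np.ndarray, config: RunConfig):
    """OI + FOS + SOS of one ROI; degenerate ROIs get nan OI."""
    axes = orientation_index(
        pixels,
        threshold=config.fft["threshold"],
        window=config.fft["window"],
    )
    fos = fos_features(pixels)
    glcm = compute_glcm(
        pixels,
        n_levels=config.glcm["n_levels"],
        distance_px=config.glcm["distance_px"],
        directions=tuple(config.glcm["directions"]),
        symmetric=config.glcm["symmetric"],
    )
    sos = sos_features(glcm)
    return axes, fos, sos


def run_pipeline(config: RunConfig):
    """Execute the full analysis; returns (features_df, comparisons_df, log).

    When ``config.out_dir`` is set, writes features.csv, comparisons.csv
    and run_log.json there, each carrying the config hash.
    """
    inputs = (
        list(simulate_inputs(config)) if config.simulate else load_inputs(config)
    )
    records = []
    warnings_log = []
    n_degenerate = 0
    roi_counts = {}
    for image_id, group, patch, vessel_mask, _truth in inputs:
        if patch.channel not in ("SHG", "2PEF"):
            raise ValueError(
                f"{image_id}: channel {patch.channel!r} cannot enter the "
                "SHG texture stage (expected SHG or 2PEF)"
            )
        roi_set = select_rois(
            patch,
            vessel_mask=vessel_mask,
            side_um=config.roi["side_um"],
            max_distance_um=config.roi["max_distance_um"],
            min_count=config.roi["min_count"],
            max_count=config.roi["max_count"],
            seed=config.seed,
            source_image_id=image_id,
            tile_without_vessel=config.roi["tile_without_vessel"],
        )
        validate_roi_set(
            roi_set, patch, vessel_mask, config.roi["max_distance_um"]
        )
        for msg in roi_set.warnings:
            warnings_log.append(f"{image_id}: {msg}")
        roi_counts[image_id] = len(roi_set)
        qc_dir = None
        if config.qc and config.out_dir:
            qc_dir = Path(config.out_dir) / "qc"
            _write_roi_overlay(patch, roi_set, qc_dir / f"{image_id}_rois.png")
        for roi in roi_set:
            sub = extract_roi(patch, roi)
            if qc_dir is not None:
                _write_spectrum_mask(
                    np.asarray(sub.pixels, float), config,
                    qc_dir / f"{roi.id}_spectrum.png",
                )
            axes, fos, sos = analyze_roi(np.asarray(sub.pixels, float), config)
            if axes.degenerate:
                n_degenerate += 1
                warnings_log.append(f"{roi.id}: degenerate ROI (constant intensity)")
            records.append(
                FeatureRecord(
                    roi_id=roi.id, group_label=group,
                    oi=axes.oi, fos=fos, sos=sos,
                )
            )

    features_df = pd.DataFrame([r.to_row() for r in records])

    groups = list(dict.fromkeys(r.group_label for r in records))
    if config.stars_mode == "vs-control":
        if config.control_label not in groups:
            raise ValueError(
                f"control group {config.control_label!r} absent from data"
            )
        pairs = [
            (config.control_label, g) for g in groups if g != config.control_label
        ]
    else:
        pairs = list(itertools.combinations(groups, 2))

    comparison_rows = []
    for feature in FEATURE_COLUMNS:
        for ga, gb in pairs:
            cmp_res = compare_groups(records, feature, ga, gb)
            comparison_rows.append(dataclasses.asdict(cmp_res))
    comparisons_df = pd.DataFrame(comparison_rows)

    log = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_images": len(inputs),
        "roi_counts": roi_counts,
        "n_rois": len(records),
        "n_degenerate_rois": n_degenerate,
        "warnings": warnings_log,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        write_table(features_df, out / "features.csv", log["config_hash"], __version__)
        write_table(
            comparisons_df, out / "comparisons.csv", log["config_hash"], __version__
        )
        write_log(log, out / "run_log.json")
    return features_df, comparisons_df, log
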