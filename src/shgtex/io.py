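"""Image and table I/O: TIFF/PNG in, TIFF/CSV/JSON out.

Pixel size is read from TIFF resolution tags when present, otherwise taken
from the caller's override; images without either are rejected. Gray 8/16
bit images map to the SHG channel (or 2PEF on request), 8-bit RGB to
IHC_RGB. CSV tables carry a comment header with the package version and
the run's config hash so every output is traceable to its configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .image import ImagePatch
from .synthetic import SceneGroundTruth


def _pixel_size_from_tiff(path: Path) -> float | None:
    """Micrometres per pixel from TIFF XResolution/ResolutionUnit, if set."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        tags = page.tags
        if "XResolution" not in tags:
            return None
        num, den = tags["XResolution"].value
        if num == 0 or den == 0:
            return None
        px_per_unit = num / den
        unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
        unit = getattr(unit, "value", unit)
        um_per_unit = {2: 25400.0, 3: 10000.0}.get(int(unit))  # inch, cm
        if um_per_unit is None:
            return None
        return um_per_unit / px_per_unit


def read_image(
    path,
    pixel_size_um: float | None = None,
    channel: str | None = None,
) -> ImagePatch:
    """Read a TIFF/PNG micrograph into an :class:`ImagePatch`.

    ``pixel_size_um`` overrides (and is required in the absence of) TIFF
    resolution metadata.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        tag_px = _pixel_size_from_tiff(path)
    elif suffix == ".png":
        arr = iio.imread(path)
        tag_px = None
    else:
        raise ValueError(f"unsupported image format {suffix!r} for {path}")
    px = pixel_size_um if pixel_size_um is not None else tag_px
    if px is None:
        raise ValueError(
            f"{path}: no pixel size in metadata and none supplied in config"
        )
    if arr.ndim == 3 and arr.shape[2] == 3:
        if arr.dtype != np.uint8:
            raise ValueError(f"{path}: RGB images must be 8-bit, got {arr.dtype}")
        return ImagePatch(arr, pixel_size_um=px, channel=channel or "IHC_RGB")
    if arr.ndim == 2:
        if arr.dtype not in (np.uint8, np.uint16):
            raise ValueError(
                f"{path}: grayscale images must be 8- or 16-bit unsigned, "
                f"got {arr.dtype}"
            )
        return ImagePatch(arr, pixel_size_um=px, channel=channel or "SHG")
    raise ValueError(f"{path}: unsupported image layout with shape {arr.shape}")


def write_image(patch: ImagePatch, path) -> None:
    """Write a patch as TIFF (16-bit gray for SHG/2PEF, 8-bit RGB for IHC).

    Pixel size is stored in the TIFF resolution tags (px/cm).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    px_per_cm = 10000.0 / patch.pixel_size_um
    if patch.channel == "IHC_RGB":
        data = np.asarray(patch.pixels)
        if data.dtype != np.uint8:
            data = np.clip(np.round(data), 0, 255).astype(np.uint8)
        photometric = "rgb"
    else:
        data = np.asarray(patch.pixels)
        if data.dtype != np.uint16:
            data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
        photometric = "minisblack"
    tifffile.imwrite(
        path,
        data,
        photometric=photometric,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def write_ground_truth(truth: SceneGroundTruth, path) -> None:
    """JSON sidecar with the scene's exact ground truth."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def write_table(df: pd.DataFrame, path, config_hash: str, version: str) -> None:
    """CSV with a provenance comment header and stable column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# shgtex {version} config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_log(log: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(log, indent=1, sort_keys=True, default=str))
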