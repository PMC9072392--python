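"""DAB positive-pixel classification and the expression index (IE).

The expression index of an immunohistochemistry micrograph is the
percentage of pixels classified as positive for the DAB (diaminobenzidine)
reaction product:

    IE = positive_pixels / total_pixels * 100

Positivity is decided, by default, by color deconvolution with the
standard hematoxylin-DAB stain matrix followed by a threshold on the DAB
optical-density channel; a hue/saturation box classifier is provided as an
alternative. All classifier parameters are recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import hed_from_rgb, rgb2hsv, separate_stains
from skimage.util import img_as_float

from .image import ImagePatch

DEFAULT_DAB_THRESHOLD = 0.15
#: DAB brown in HSV: warm-hue band (fraction of the color circle) and
#: minimum saturation; hematoxylin blue sits near hue 0.67.
DEFAULT_HUE_RANGE = (0.0, 0.15)
DEFAULT_MIN_SATURATION = 0.25


@dataclass
class IHCResult:
    positive_pixels: int
    total_pixels: int
    ie: float
    classifier_config: dict

    def __post_init__(self) -> None:
        if not (0 <= self.positive_pixels <= self.total_pixels):
            raise ValueError("positive pixel count outside [0, total]")


def _as_rgb_float(rgb_image) -> np.ndarray:
    if isinstance(rgb_image, ImagePatch):
        if rgb_image.channel != "IHC_RGB":
            raise ValueError(
                f"expected an IHC_RGB patch, got channel {rgb_image.channel!r}"
            )
        rgb_image = rgb_image.pixels
    arr = np.asarray(rgb_image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("classify_positive_pixels requires a 3-channel RGB image")
    return img_as_float(arr)


def classify_positive_pixels(
    rgb_image,
    method: str = "deconvolution",
    dab_threshold: float = DEFAULT_DAB_THRESHOLD,
    stain_matrix: np.ndarray | None = None,
    hue_range=DEFAULT_HUE_RANGE,
    min_saturation: float = DEFAULT_MIN_SATURATION,
) -> np.ndarray:
    """Binary mask of DAB-positive pixels.

    ``method="deconvolution"`` separates stains with the hematoxylin-DAB
    optical-density matrix (``stain_matrix`` overrides the standard one)
    and thresholds the DAB channel at ``dab_threshold``.
    ``method="hsv"`` keeps pixels whose hue falls in ``hue_range`` with
    saturation above ``min_saturation``.
    """
    rgb = _as_rgb_float(rgb_image)
    if method == "deconvolution":
        matrix = hed_from_rgb if stain_matrix is None else np.asarray(stain_matrix)
        dab = separate_stains(rgb, matrix)[..., 2]
        return dab >= dab_threshold
    if method == "hsv":
        hsv = rgb2hsv(rgb)
        lo, hi = hue_range
        return (hsv[..., 0] >= lo) & (hsv[..., 0] <= hi) & (
            hsv[..., 1] >= min_saturation
        )
    raise ValueError(f"unknown classification method {method!r}")


def expression_index(mask: np.ndarray, classifier_config: dict | None = None) -> IHCResult:
    """IE = positive / total * 100 from a binary positivity mask."""
    m = np.asarray(mask)
    if m.size == 0:
        raise ValueError("empty mask")
    m = m.astype(bool)
    positive = int(m.sum())
    total = int(m.size)
    return IHCResult(
        positive_pixels=positive,
        total_pixels=total,
        ie=positive / total * 100.0,
        classifier_config=dict(classifier_config or {}),
    )


def quantify_ihc(
    rgb_image,
    method: str = "deconvolution",
    dab_threshold: float = DEFAULT_DAB_THRESHOLD,
    **kwargs,
) -> IHCResult:
    """Classify and score one micrograph in a single call."""
    mask = classify_positive_pixels(
        rgb_image, method=method, dab_threshold=dab_threshold, **kwargs
    )
    config = {"method": method, "dab_threshold": dab_threshold, **kwargs}
    config.pop("stain_matrix", None)
    return expression_index(mask, classifier_config=config)
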