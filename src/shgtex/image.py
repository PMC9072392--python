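"""Core image container shared by all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognized acquisition channels. SHG and 2PEF are single-channel
#: intensity images; IHC_RGB is a 3-channel brightfield color image.
CHANNELS = ("SHG", "2PEF", "IHC_RGB")


@dataclass
class ImagePatch:
    """A 2D intensity image (or RGB image) with physical pixel size.

    Parameters
    ----------
    pixels
        2D non-negative array for SHG/2PEF, or (H, W, 3) for IHC_RGB.
    pixel_size_um
        Physical size of one pixel in micrometres; must be positive.
    channel
        One of ``CHANNELS``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = "SHG"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.channel not in CHANNELS:
            raise ValueError(
                f"channel must be one of {CHANNELS}, got {self.channel!r}"
            )
        if self.channel == "IHC_RGB":
            if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
                raise ValueError("IHC_RGB patch requires an (H, W, 3) array")
        else:
            if self.pixels.ndim != 2:
                raise ValueError(
                    f"{self.channel} patch requires a 2D array, "
                    f"got ndim={self.pixels.ndim}"
                )
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise ValueError("pixel intensities must be finite")
        if np.any(np.asarray(self.pixels, dtype=float) < 0):
            raise ValueError("pixel intensities must be non-negative")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def side_um(self) -> tuple:
        """Physical extent (height, width) in micrometres."""
        return (
            self.pixels.shape[0] * self.pixel_size_um,
            self.pixels.shape[1] * self.pixel_size_um,
        )
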