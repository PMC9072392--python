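"""Synthetic SHG-like fiber scenes, vessel scenes and IHC-like RGB images.

Every generator is a pure function of its parameters and a ``seed`` and
returns both the rendered :class:`~shgtex.image.ImagePatch` and a
:class:`SceneGroundTruth` describing exactly what was drawn, so downstream
feature extractors can be validated against known truth.

Fibers are straight segments with a Gaussian cross-profile; orientations
follow an axial von Mises law (von Mises on doubled angles), the standard
model for axial orientation data such as collagen fibers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.color import combine_stains, rgb_from_hed

from .image import ImagePatch

#: Default physical pixel size: 0.15 um/px makes a 1000x1000 px tile
#: cover ~150 x 150 um^2, the tile geometry of wide-field SHG mosaics.
DEFAULT_PIXEL_SIZE_UM = 0.15

#: Gaussian read-noise default, as a fraction of the peak fiber intensity.
DEFAULT_NOISE_FRACTION = 0.05


@dataclass(frozen=True)
class FiberSpec:
    """Geometry and brightness of a single rendered fiber segment."""

    start_point: tuple  # (row, col), px
    orientation_deg: float  # axial angle in [0, 180)
    length_px: float
    width_px: float  # FWHM of the Gaussian cross-profile
    peak_intensity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.orientation_deg < 180.0):
            raise ValueError("orientation_deg must lie in [0, 180)")
        if self.length_px < 1:
            raise ValueError("length_px must be >= 1")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")


@dataclass
class SceneGroundTruth:
    """Exact description of a generated scene; the oracle for recovery tests."""

    fibers: list = field(default_factory=list)
    orientation_mean_deg: float = 90.0
    orientation_concentration: float = 0.0
    vessel_mask: np.ndarray | None = None
    positive_fraction: float | None = None
    positive_mask: np.ndarray | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.positive_fraction is not None and not (
            0.0 <= self.positive_fraction <= 1.0
        ):
            raise ValueError("positive_fraction must lie in [0, 1]")

    @property
    def orientations_deg(self) -> np.ndarray:
        return np.array([f.orientation_deg for f in self.fibers], dtype=float)

    def to_dict(self) -> dict:
        """JSON-serializable form (masks as nested lists)."""
        d = {
            "fibers": [dataclasses.asdict(f) for f in self.fibers],
            "orientation_mean_deg": self.orientation_mean_deg,
            "orientation_concentration": self.orientation_concentration,
            "positive_fraction": self.positive_fraction,
            "seed": self.seed,
            "params": self.params,
        }
        if self.vessel_mask is not None:
            d["vessel_mask"] = np.asarray(self.vessel_mask, dtype=int).tolist()
        if self.positive_mask is not None:
            d["positive_mask"] = np.asarray(self.positive_mask, dtype=int).tolist()
        return d


def sample_axial_orientations(
    rng: np.random.Generator,
    n: int,
    mean_deg: float,
    concentration: float,
) -> np.ndarray:
    """Draw ``n`` axial angles in [0, 180) from a von Mises law on 2*theta.

    ``concentration`` (kappa) = 0 gives the uniform axial distribution.
    """
    if concentration < 0:
        raise ValueError(f"orientation_concentration must be >= 0, got {concentration}")
    if concentration == 0:
        return rng.uniform(0.0, 180.0, size=n)
    mu = np.deg2rad(2.0 * mean_deg)
    doubled = stats.vonmises.rvs(concentration, loc=mu, size=n, random_state=rng)
    return (np.rad2deg(doubled) / 2.0) % 180.0


def _render_fiber(canvas: np.ndarray, fiber: FiberSpec) -> None:
    """Additively render one segment with a Gaussian cross-profile."""
    sigma = fiber.width_px / 2.355  # width is the FWHM
    pad = int(np.ceil(3.0 * sigma)) + 1
    r0, c0 = fiber.start_point
    theta = np.deg2rad(fiber.orientation_deg)
    # image rows grow downward: orientation measured from +col axis
    dr, dc = -np.sin(theta), np.cos(theta)
    r1, c1 = r0 + fiber.length_px * dr, c0 + fiber.length_px * dc

    h, w = canvas.shape
    rmin = max(int(np.floor(min(r0, r1))) - pad, 0)
    rmax = min(int(np.ceil(max(r0, r1))) + pad, h - 1)
    cmin = max(int(np.floor(min(c0, c1))) - pad, 0)
    cmax = min(int(np.ceil(max(c0, c1))) + pad, w - 1)
    if rmin > rmax or cmin > cmax:
        return  # segment lies fully outside the canvas

    rr, cc = np.meshgrid(
        np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij"
    )
    # distance from each pixel center to the segment
    vr, vc = r1 - r0, c1 - c0
    seg_len2 = vr * vr + vc * vc
    t = ((rr - r0) * vr + (cc - c0) * vc) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    dist2 = (rr - (r0 + t * vr)) ** 2 + (cc - (c0 + t * vc)) ** 2
    canvas[rmin : rmax + 1, cmin : cmax + 1] += fiber.peak_intensity * np.exp(
        -dist2 / (2.0 * sigma * sigma)
    )


def _apply_noise(
    rng: np.random.Generator,
    img: np.ndarray,
    noise_model,
    peak_intensity: float,
) -> np.ndarray:
    """Apply the configured noise model; returns a non-negative array."""
    if isinstance(noise_model, str):
        kind, param = noise_model, None
    else:
        try:
            kind, param = noise_model
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"noise_model must be a name or (name, param) pair, got {noise_model!r}"
            ) from exc
    if kind == "none":
        out = img
    elif kind == "gaussian":
        sigma = DEFAULT_NOISE_FRACTION * peak_intensity if param is None else param
        out = img + rng.normal(0.0, sigma, size=img.shape)
    elif kind == "poisson":
        # shot noise: each pixel replaced by a Poisson draw at its mean
        out = rng.poisson(np.clip(img, 0.0, None)).astype(float)
    else:
        raise ValueError(f"unknown noise_model {kind!r}")
    return np.clip(out, 0.0, None)


def generate_fiber_image(
    shape_px=(256, 256),
    n_fibers: int = 120,
    orientation_mean_deg: float = 90.0,
    orientation_concentration: float = 0.0,
    length_law=("uniform", 0.5, 1.0),
    width_px: float = 2.0,
    intensity: float = 100.0,
    noise_model="gaussian",
    background: float = 1.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int = 0,
) -> tuple:
    """Render a fiber-network SHG-like tile with known ground truth.

    Parameters
    ----------
    shape_px
        (rows, cols) of the tile; each must be >= 32.
    n_fibers
        Number of fiber segments to draw (>= 0).
    orientation_mean_deg, orientation_concentration
        Mean axis and kappa of the axial von Mises orientation law;
        kappa = 0 is isotropic.
    length_law
        ``("uniform", lo, hi)`` fractions of min(shape), ``("constant", frac)``,
        or ``("exponential", mean_frac)``; lengths are clipped to >= 1 px.
    width_px
        FWHM of the Gaussian fiber cross-profile, in px.
    intensity
        Peak per-fiber intensity (arbitrary SHG counts).
    noise_model
        ``"none"``, ``"gaussian"`` (sigma defaults to 5% of ``intensity``;
        override with ``("gaussian", sigma)``) or ``"poisson"``.
    background
        Constant background level added before noise.
    seed
        Mandatory RNG seed; identical seed + parameters give bit-identical
        output.

    Returns
    -------
    (ImagePatch, SceneGroundTruth)
    """
    shape_px = tuple(int(s) for s in shape_px)
    if len(shape_px) != 2 or min(shape_px) < 32:
        raise ValueError(f"shape_px must be 2D with sides >= 32, got {shape_px}")
    if n_fibers < 0:
        raise ValueError(f"n_fibers must be >= 0, got {n_fibers}")
    if orientation_concentration < 0:
        raise ValueError(
            f"orientation_concentration must be >= 0, got {orientation_concentration}"
        )
    if not (pixel_size_um > 0):
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")

    rng = np.random.default_rng(seed)
    h, w = shape_px
    angles = sample_axial_orientations(
        rng, n_fibers, orientation_mean_deg, orientation_concentration
    )
    scale = float(min(shape_px))
    kind = length_law[0]
    if kind == "uniform":
        lengths = rng.uniform(length_law[1], length_law[2], size=n_fibers) * scale
    elif kind == "constant":
        lengths = np.full(n_fibers, length_law[1] * scale)
    elif kind == "exponential":
        lengths = rng.exponential(length_law[1] * scale, size=n_fibers)
    else:
        raise ValueError(f"unknown length_law {kind!r}")
    lengths = np.clip(lengths, 1.0, None)

    starts = np.column_stack(
        [rng.uniform(0, h, size=n_fibers), rng.uniform(0, w, size=n_fibers)]
    )
    # center each segment on its sampled anchor so long fibers cross the tile
    fibers = []
    canvas = np.full(shape_px, float(background))
    for k in range(n_fibers):
        theta = np.deg2rad(angles[k])
        dr, dc = -np.sin(theta), np.cos(theta)
        r0 = starts[k, 0] - 0.5 * lengths[k] * dr
        c0 = starts[k, 1] - 0.5 * lengths[k] * dc
        fiber = FiberSpec(
            start_point=(float(r0), float(c0)),
            orientation_deg=float(angles[k]),
            length_px=float(lengths[k]),
            width_px=float(width_px),
            peak_intensity=float(intensity),
        )
        fibers.append(fiber)
        _render_fiber(canvas, fiber)

    canvas = _apply_noise(rng, canvas, noise_model, intensity)
    patch = ImagePatch(canvas, pixel_size_um=pixel_size_um, channel="SHG")
    truth = SceneGroundTruth(
        fibers=fibers,
        orientation_mean_deg=float(orientation_mean_deg),
        orientation_concentration=float(orientation_concentration),
        seed=int(seed),
        params={
            "shape_px": list(shape_px),
            "n_fibers": int(n_fibers),
            "length_law": list(length_law),
            "width_px": float(width_px),
            "intensity": float(intensity),
            "noise_model": noise_model if isinstance(noise_model, str) else list(noise_model),
            "background": float(background),
            "pixel_size_um": float(pixel_size_um),
        },
    )
    return patch, truth


def generate_vessel_scene(
    shape_px=(512, 512),
    vessel_radius_px: float = 60.0,
    wall_thickness_px: float = 15.0,
    collagen_params: dict | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int = 0,
) -> tuple:
    """Render a vessel cross-section: dark lumen, fiber-dense wall, parenchyma.

    The circular lumen (radius ``vessel_radius_px``, image center) is marked
    in ``vessel_mask``; the annular wall of the stated thickness is packed
    with tangentially oriented fibers, emulating perivascular collagen, and
    the rest of the tile carries background parenchyma fibers drawn from
    ``collagen_params`` (same keys as :func:`generate_fiber_image`).
    """
    shape_px = tuple(int(s) for s in shape_px)
    h, w = shape_px
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    outer = vessel_radius_px + wall_thickness_px
    if outer > min(cr, cc, h - 1 - cr, w - 1 - cc):
        raise ValueError(
            f"vessel (radius {vessel_radius_px} + wall {wall_thickness_px}) "
            f"does not fit inside image of shape {shape_px}"
        )
    params = {
        "n_fibers": 40,
        "orientation_mean_deg": 90.0,
        "orientation_concentration": 0.0,
        "length_law": ("uniform", 0.2, 0.5),
        "width_px": 3.0,
        "intensity": 100.0,
        "noise_model": "gaussian",
        "background": 1.0,
    }
    if collagen_params:
        params.update(collagen_params)

    rng = np.random.default_rng(seed)
    canvas = np.full(shape_px, float(params["background"]))

    # background parenchyma fibers
    fibers = []
    n_bg = int(params["n_fibers"])
    angles = sample_axial_orientations(
        rng, n_bg, params["orientation_mean_deg"], params["orientation_concentration"]
    )
    scale = float(min(shape_px))
    lo, hi = params["length_law"][1], params["length_law"][2]
    lengths = np.clip(rng.uniform(lo, hi, size=n_bg) * scale, 1.0, None)
    for k in range(n_bg):
        theta = np.deg2rad(angles[k])
        dr, dc = -np.sin(theta), np.cos(theta)
        anchor = (rng.uniform(0, h), rng.uniform(0, w))
        fiber = FiberSpec(
            start_point=(
                float(anchor[0] - 0.5 * lengths[k] * dr),
                float(anchor[1] - 0.5 * lengths[k] * dc),
            ),
            orientation_deg=float(angles[k]),
            length_px=float(lengths[k]),
            width_px=float(params["width_px"]),
            peak_intensity=float(params["intensity"]),
        )
        fibers.append(fiber)
        _render_fiber(canvas, fiber)

    # tangential wall fibers, densely packed in the annulus
    if wall_thickness_px > 0:
        r_mid = vessel_radius_px + 0.5 * wall_thickness_px
        circumference = 2.0 * np.pi * r_mid
        n_wall = max(4, int(circumference / max(params["width_px"], 1.0)))
        seg_len = max(2.0 * wall_thickness_px, 8.0)
        phis = rng.uniform(0.0, 2.0 * np.pi, size=n_wall)
        radii = r_mid + rng.uniform(
            -0.3 * wall_thickness_px, 0.3 * wall_thickness_px, size=n_wall
        )
        for phi, rad in zip(phis, radii):
            # tangent direction at angular position phi (rows grow downward)
            anchor_r = cr - rad * np.sin(phi)
            anchor_c = cc + rad * np.cos(phi)
            tang_deg = (np.rad2deg(phi) + 90.0) % 180.0
            theta = np.deg2rad(tang_deg)
            dr, dc = -np.sin(theta), np.cos(theta)
            fiber = FiberSpec(
                start_point=(
                    float(anchor_r - 0.5 * seg_len * dr),
                    float(anchor_c - 0.5 * seg_len * dc),
                ),
                orientation_deg=float(tang_deg),
                length_px=float(seg_len),
                width_px=float(params["width_px"]),
                peak_intensity=float(1.5 * params["intensity"]),
            )
            fibers.append(fiber)
            _render_fiber(canvas, fiber)

    rr, cc_grid = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    lumen = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= vessel_radius_px**2
    canvas[lumen] = 0.2 * float(params["background"])  # dark lumen

    canvas = _apply_noise(rng, canvas, params["noise_model"], params["intensity"])
    patch = ImagePatch(canvas, pixel_size_um=pixel_size_um, channel="SHG")
    truth = SceneGroundTruth(
        fibers=fibers,
        orientation_mean_deg=float(params["orientation_mean_deg"]),
        orientation_concentration=float(params["orientation_concentration"]),
        vessel_mask=lumen,
        seed=int(seed),
        params={
            "shape_px": list(shape_px),
            "vessel_radius_px": float(vessel_radius_px),
            "wall_thickness_px": float(wall_thickness_px),
            "collagen_params": {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()
            },
            "pixel_size_um": float(pixel_size_um),
        },
    )
    return patch, truth


def generate_ihc_image(
    shape_px=(256, 256),
    positive_fraction: float = 0.25,
    stain_colors=None,
    jitter: float = 0.03,
    seed: int = 0,
    dab_od: float = 0.4,
    hematoxylin_od: float = 0.4,
) -> tuple:
    """Render an IHC-like RGB image with an exact DAB-positive pixel count.

    Exactly ``round(positive_fraction * n_pixels)`` randomly placed pixels
    carry the DAB-brown stain class; the rest carry the hematoxylin
    counterstain class. Colors are produced by the standard H&E-DAB optical
    density model (``skimage.color.combine_stains``) with Gaussian jitter on
    the per-pixel stain concentrations, so color-deconvolution classifiers
    can be validated against the stored ground-truth mask.

    ``stain_colors`` optionally overrides the 3x3 stain-to-RGB optical
    density matrix (rows = hematoxylin, eosin, DAB); default is the
    standard published H-DAB matrix.
    """
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValueError(
            f"positive_fraction must lie in [0, 1], got {positive_fraction}"
        )
    shape_px = tuple(int(s) for s in shape_px)
    h, w = shape_px
    n = h * w
    n_pos = int(round(positive_fraction * n))

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    positive = np.zeros(n, dtype=bool)
    positive[order[:n_pos]] = True
    positive = positive.reshape(shape_px)

    conc = np.zeros((h, w, 3))  # hematoxylin, eosin, DAB concentrations
    conc[..., 0] = np.where(positive, 0.05, hematoxylin_od)
    conc[..., 2] = np.where(positive, dab_od, 0.0)
    if jitter > 0:
        conc += rng.normal(0.0, jitter, size=conc.shape)
    conc = np.clip(conc, 0.0, None)

    matrix = rgb_from_hed if stain_colors is None else np.asarray(stain_colors, float)
    rgb = np.clip(combine_stains(conc, matrix), 0.0, 1.0)
    rgb8 = np.round(rgb * 255.0).astype(np.uint8)

    patch = ImagePatch(rgb8, pixel_size_um=DEFAULT_PIXEL_SIZE_UM, channel="IHC_RGB")
    truth = SceneGroundTruth(
        fibers=[],
        positive_fraction=float(positive_fraction),
        positive_mask=positive,
        seed=int(seed),
        params={
            "shape_px": list(shape_px),
            "jitter": float(jitter),
            "dab_od": float(dab_od),
            "hematoxylin_od": float(hematoxylin_od),
            "n_positive": int(n_pos),
        },
    )
    return patch, truth
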