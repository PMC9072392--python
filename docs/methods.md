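# Methods

This note records the models, conventions and numerical choices behind
`shgtex`, in the order the pipeline applies them.

## Synthetic scene model

The generator emulates wide-field SHG tiles of fibrillar collagen.

**Geometry.** Fibers are straight segments with a Gaussian cross-profile;
`width_px` is the profile's full width at half maximum (σ = width/2.355).
Segment anchors are uniform over the tile and segments are centered on
their anchor, so long fibers cross the field of view. Default lengths are
uniform between 0.5 and 1.0 of the tile side: SHG images of fibrotic lung
show long assembled fibers forming dense networks, and tile-spanning
segments reproduce that appearance. Curvature is not modelled — the
downstream features quantify orientation and texture, not fiber shape.

**Orientation law.** Fiber axes are axial data (θ and θ+180° are the same
fiber), so orientations are drawn from a von Mises distribution on the
doubled angle 2θ with mean 2θ₀ and concentration κ; κ = 0 is the uniform
(isotropic) case. This is the standard circular-statistics model for fiber
orientation.

**Defaults.** 256 × 256 px tiles at 0.15 μm/px (a 1000 × 1000 px tile at
this scale covers ~150 × 150 μm², the usual SHG mosaic tile), 120 fibers
per tile, width 2 px (≈ 0.3 μm — thin collagen fibers render at roughly
the diffraction limit in these systems), peak intensity 100 on a
background of 1, additive Gaussian noise with σ = 5% of peak intensity.
Poisson shot noise and noise-free rendering are available. All of these
are plain function parameters and flow through the run config; none is
hard-coded downstream. Under these defaults the mean orientation index
recovered from 20 independent tiles rises monotonically with κ over
{0, 1, 4, 16} and exceeds 0.9 at κ = 16, which is the calibration the
recovery checks assert.

**Vessel scenes.** A circular lumen (low intensity, 20% of background) at
the tile center is surrounded by an annular wall of thickness `w` packed
with tangentially oriented fibers (one per fiber-width of circumference,
1.5× background fiber intensity), over background parenchyma fibers.
`wall_thickness = 0` produces a bare lumen disk. The returned
`vessel_mask` marks the lumen.

**IHC scenes.** Exactly `round(fraction × n_pixels)` randomly chosen
pixels carry the DAB stain class and the rest the hematoxylin class.
Colors come from the published optical-density stain matrix
(`skimage.color.combine_stains`), with Gaussian jitter (σ = 0.03) on the
per-pixel stain concentrations, so the rendered image is exactly the
inverse problem the deconvolution classifier solves — plus jitter,
clipping and 8-bit quantization.

**What the generator does not emulate.** Physical SHG contrast (phase
matching, polarization dependence, forward/backward ratio), 3D sectioning,
fiber curvature and branching, spatially correlated background (cellular
autofluorescence bleed-through), uneven illumination, and tissue-scale
anatomy. Passing recovery tests therefore demonstrates that the estimators
invert the stated generative model at realistic noise levels — not that
they are robust to every artifact of real micrographs.

## ROI selection

ROI side = round(side_um / pixel_size_um) px; the physical default is
150 μm. With a vessel mask, candidate origins lie on a half-side-stride
grid; an origin is feasible when the ROI **center** lies within 500 μm of
the vessel (the distance rule is applied to the center — corners would
make the band asymmetric for no benefit) and no ROI pixel falls inside the
lumen (the analysis targets perivascular tissue, not lumen). Distances are
Euclidean, computed with a distance transform on the mask complement, so
lumen-interior pixels are at distance 0. Feasible candidates are shuffled
with the run seed and accepted greedily under pairwise non-overlap, up to
the maximum count; fewer than the minimum raises a recorded warning, never
an error. Without a vessel mask a config flag enables whole-image tiling
on a full-side-stride grid (the mode used for pure synthetic runs). Greedy
selection returns a maximal, not necessarily maximum, non-overlapping set;
the tests assert maximality against brute-force enumeration.

## Orientation index

Per ROI: subtract the mean (suppresses the DC component), apply a
separable Hann taper (default on — without it the tile edges imprint an
axis-aligned cross on the spectrum that corrupts the axis estimate; the
flag is recorded), take the 2D FFT magnitude, shift DC to the center and
divide by the maximum. The magnitude — not log-magnitude or power — is
binarized at 0.38 with the ≥ convention at the boundary. The short and
long axes are those of the equivalent ellipse of the true-pixel point set:
with eigenvalues λ₁ ≥ λ₂ of the central second-moment matrix,
long = 4√λ₁ and short = 4√λ₂. Moments are rotation-covariant and defined
for arbitrary masks, which bounding-box extents are not. All true pixels
enter the moments (no connected-component filtering).

Degenerate cases: a constant ROI has an all-zero spectrum and OI is
reported missing (flagged); a collinear mask (λ₂ = 0) gives OI = 1; a
single-pixel mask (λ₁ = λ₂ = 0) is reported as the isotropic limit OI = 0
with the degenerate flag set. OI is invariant under multiplying the image
by a positive constant (the normalized spectrum is unchanged) and stable
under rotation to within resampling error (≤ 0.05 asserted at 37°).

## Texture features

**FOS** uses population (1/n²) moments; kurtosis is the non-excess fourth
standardized moment (3 for a normal law), matching the printed formula
rather than the excess convention. Skewness and kurtosis are undefined at
σ = 0 and reported missing.

**GLCM** construction: intensities are rebinned linearly to 64 levels over
the ROI's own [min, max] (exposure-invariant; a fixed-range option exists
via pre-scaling), pairs are accumulated at distance 1 px over the four
directions 0°, 45°, 90°, 135°, the transpose is added (symmetric), and the
matrix is normalized to sum 1. A constant ROI maps to the single entry
P₀₀ = 1. These are the standard Haralick conventions; all four parameters
are exposed in config and recorded in output.

**SOS**: entropy uses the natural logarithm with 0·ln 0 := 0. The
correlation of a zero-variance GLCM is 0/0 and is defined as 0, consistent
with "zero correlation for a uniform image". Implementations are
vectorized and are checked against explicit double-loop evaluation (1e-10)
and against `skimage.feature.graycoprops` on the pooled matrix.

## IHC quantification

Default classifier: stain separation with the standard hematoxylin–DAB
optical-density matrix, then DAB channel ≥ 0.15. The threshold sits midway
between the DAB response of counterstained pixels (≈ 0, up to deconvolution
cross-talk and quantization) and of DAB pixels at the default rendering
OD (0.4), and recovers synthetic fractions to well within one percentage
point. An HSV box classifier (warm hues 0–0.15, saturation ≥ 0.25) is the
alternative method. IE = positive/total × 100 exactly; the classifier
method and thresholds are recorded in every result.

## Group statistics

Pairwise comparisons use the classic equal-variance two-sample two-tailed
t-test (the "Student's" test; Welch is deliberately not the default so the
statistic matches the conventional analysis). A global one-way ANOVA
F-test is available separately. Stars follow the figure-caption
convention, including the permissive p < 0.1 single star; no
multiple-testing correction is applied by default (a Bonferroni option
would be a one-line wrapper, but the conventional presentation applies
none — this is a documented limitation, as is treating ROIs from the same
animal as independent). Identical samples give t = 0/0, reported as t = 0,
p = 1. Quantiles use linear interpolation between order statistics;
whiskers sit at quartile ± 1.5×IQR, clipped to the data range. Comparisons
run either each-group-versus-control (default) or all pairs.

## Pipeline and determinism

Per-image seeds derive from the run seed via `numpy` SeedSequence, so runs
are byte-reproducible end to end; every CSV embeds a hash of the
analysis-relevant config (output paths excluded). Degenerate ROIs stay in
the feature table with missing OI/skewness/kurtosis, are dropped pairwise
from statistics, and are counted in the run log. The 2PEF channel is
accepted for pass-through/QC only. Test and recovery workloads run on
256 × 256 px tiles and 20-seed replicates — the smallest sizes at which
the recovery behavior is stable and well separated.

## Known limitations

- The OI threshold (0.38) is a fixed convention of the method; the index
  is comparable across ROIs and groups but its absolute value depends on
  rendering/imaging contrast.
- Per-ROI [min, max] rebinning makes SOS features invariant to affine
  intensity changes but sensitive to single hot pixels (they stretch the
  bin range).
- The greedy ROI placement maximizes nothing globally; two seeds can
  return sets of slightly different size.
- IHC classification assumes the standard stain matrix; strongly deviating
  staining protocols need a custom matrix.
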