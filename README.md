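# shgtex

Quantitative texture and orientation analysis of collagen in
second-harmonic-generation (SHG) micrographs, built for tracking
fibrosis progression — e.g. the perivascular collagen remodelling that
accompanies pulmonary arterial hypertension — from label-free SHG tiles
of lung tissue.

The package turns a set of SHG micrographs (per experimental group) into a
per-ROI feature table and group-level statistics:

1. **ROI selection** — square 150 × 150 μm² regions placed no further than
   500 μm from the blood vessel wall (given a lumen mask), non-overlapping,
   50–80 per group, by a seeded reproducible procedure.
2. **Orientation index (OI)** — anisotropy of the fiber network from the
   2D Fourier spectrum of each ROI. The max-normalized, DC-suppressed FFT
   magnitude is binarized at threshold 0.38 and the equivalent-ellipse axes
   of the mask give

   OI = 1 − (short axis / long axis),

   so OI = 0 for isotropic collagen (circular spectrum) and OI = 1 for
   perfectly oriented fibers.
3. **First-order statistics (FOS)** — population mean μ, standard
   deviation σ, skewness s and (non-excess) kurtosis k of the ROI
   intensity histogram, each sum normalized by the pixel count n².
4. **Second-order statistics (SOS)** — from the gray-level co-occurrence
   matrix P<sub>ij</sub> (64 levels, distance 1 px, four directions,
   symmetric): energy Σ P<sub>ij</sub>², inertia (contrast)
   Σ (i−j)² P<sub>ij</sub>, correlation
   Σ (i−μ<sub>i</sub>)(j−μ<sub>j</sub>) P<sub>ij</sub> / (σ<sub>i</sub>σ<sub>j</sub>),
   inverse difference moment Σ P<sub>ij</sub>/(1+(i−j)²) and entropy
   −Σ P<sub>ij</sub> ln P<sub>ij</sub>.
5. **IHC expression index** — for RGB immunohistochemistry micrographs,
   DAB-positive pixels are classified by color deconvolution (standard
   hematoxylin–DAB stain matrix, threshold on the DAB optical-density
   channel) and IE = positive / total × 100.
6. **Group statistics** — equal-variance two-sample two-tailed t-tests per
   feature and group pair, starred p < 0.1 (\*), p < 0.01 (\*\*),
   p < 0.001 (\*\*\*); box summaries with 1.5×IQR whiskers.

Because real tissue micrographs are rarely shareable, the package ships a
first-class synthetic generator: SHG-like fiber networks with orientations
drawn from an axial von Mises law (mean axis and concentration κ are
parameters), vessel scenes with a dark lumen and fiber-dense wall, and
IHC-like RGB images with an exactly known positive-pixel fraction — all
deterministic given a seed, all returning ground truth for validation.

## Worked example

Simulate a control group (isotropic collagen, κ = 0) and a "disease" group
with concentrated fiber orientation (κ = 8), then run the full pipeline:

```python
from shgtex.pipeline import RunConfig, run_pipeline

config = RunConfig.from_dict({
    "seed": 1,
    "simulate": {
        "shape_px": [256, 256],
        "groups": {
            "control": {"n_images": 4, "orientation_concentration": 0.0},
            "week2":   {"n_images": 4, "orientation_concentration": 8.0},
        },
    },
    "roi": {"side_um": 19.2, "min_count": 1, "max_count": 4},
})
features, comparisons, log = run_pipeline(config)
print(features[["roi_id", "group", "oi", "mean", "energy", "entropy"]].head(4))
print(comparisons[comparisons.feature_name.isin(["oi", "entropy"])]
      [["feature_name", "t_statistic", "p_value", "stars"]])
```

prints

```
              roi_id   group       oi      mean   energy  entropy
control_img00_roi000 control 0.262966 72.854919 0.027531 5.666686
control_img00_roi001 control 0.337302 49.068944 0.070002 4.982739
control_img00_roi002 control 0.567032 61.185317 0.034124 5.639921
control_img00_roi003 control 0.475637 55.826383 0.045299 5.476092

feature_name  t_statistic      p_value stars
          oi   -12.666788 1.427800e-13   ***
     entropy    -0.768270 4.483323e-01
```

The OI rows show what the method is built to detect: the oriented (κ = 8)
group has a sharply higher orientation index than the isotropic control
(t = −12.7, p ≈ 1e−13, \*\*\*), while entropy — which responds to
intensity texture, not orientation — does not separate these two groups.

The same workflow is available from the shell:

```bash
shgtex simulate --config run.yaml --out sim/      # TIFFs + ground-truth JSON
shgtex analyze  --config run.yaml --out results/  # features.csv, comparisons.csv, run_log.json
shgtex report   --features results/features.csv --out report/
```

Every CSV carries the config hash in its header; identical config + seed
reproduces outputs byte for byte.

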