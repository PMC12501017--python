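# octavasc

Quantitative 4D-OCT angiography of tumor microvasculature.

Intravital optical coherence tomography (OCT) records the same tissue
volume repeatedly over time (XYZT). Static tissue reproduces its speckle
pattern from frame to frame, while voxels containing flowing blood
decorrelate — which makes flow visible without any contrast agent.
`octavasc` turns such a 4D scan into per-vessel morphometry and the
image-level endpoints used to compare treatment arms in tumor
angiogenesis studies: vessel length density and perfused vessel area.

The pipeline:

1. **Angiography reconstruction** — per-voxel mean amplitude
   decorrelation over consecutive frame pairs,

   D = (1/(N−1)) Σₙ [ 1 − 2·Iₙ·Iₙ₊₁ / (Iₙ² + Iₙ₊₁²) ],

   bounded in [0, 1], scale-invariant, with low-SNR voxels (time-mean
   intensity below a percentile noise floor) suppressed.
2. **Tubular enhancement** — multi-scale Hessian (Frangi-type) vesselness
   on the decorrelation volume, with per-axis Gaussian sigmas in voxel
   units so anisotropic voxels are handled in physical micrometers, and
   γ = 2 scale normalization across a ladder of physical scales.
3. **Lumen segmentation** — adaptive thresholding (local Gaussian mean +
   global-range offset) of the flow volume, gated by the vesselness
   support and an absolute flow-significance floor, followed by
   morphological closing and small-component removal.
4. **Centerlines** — 3D topological thinning on an isotropically
   resampled grid, converted to a graph of junction/endpoint nodes and
   polyline edges with physical arc lengths; short terminal spurs pruned.
5. **Morphometry** — per-sample vessel diameter as the full width at half
   maximum (FWHM) of flow profiles perpendicular to the local vessel
   axis (with chord-midpoint recentering), cross-sectional area from the
   binary lumen mask in the perpendicular plane, per-segment medians.
   Only vessels with diameter > 15 µm (system resolution limit) enter
   the summaries.
6. **Endpoints and statistics** — en-face vessel length density (mm of
   retained centerline per mm² of field), perfused vessel area fraction
   (depth-projected retained mask over field area), and group
   comparisons: unpaired Student's t-test for two groups, one-way ANOVA
   with Tukey's HSD for more.

Because no imaging data accompanies the study design this package
targets, a synthetic phantom generator (`octavasc.phantom`) produces 4D
volumes with exact vascular ground truth — tubes of known centerline,
radius and flow decorrelation inside static log-normal speckle — so
every stage is testable end to end.

## Worked example

```python
from octavasc import generate_phantom, run_pipeline
from octavasc.phantom import default_study_spec

spec = default_study_spec(noise_seed=5)      # 25/40/60 um vessels, (8,4,4) um voxels
volume, truth = generate_phantom(spec)
result = run_pipeline(volume)

print(result.segments.round(1).to_string(index=False))
for k, v in result.summary.as_dict().items():
    print(f"{k}: {v if isinstance(v, (int, str)) else round(v, 3)}")
```

prints

```
 segment_id  length_um  diameter_um  area_um2  n_samples
          0      554.9         54.6    2720.0         56
          1      636.3         22.5     480.0         64
          2      613.7         38.0    1280.0         62
vessel_length_density: 8.12
perfused_vessel_area_fraction: 0.327
n_vessels: 3
mean_diameter_um: 37.659
total_length_mm: 1.805
convention: enface
```

The three phantom vessels (true diameters 25, 40 and 60 µm) are
recovered at 22.5, 38.0 and 54.6 µm — within the quantization of the
anisotropic (8, 4, 4) µm voxel grid — each spanning the ~0.6 mm field,
giving 1.8 mm of centerline over a 0.22 mm² en-face field (density
8.1 mm⁻¹) with 33 % of the field covered by projected lumen.

The same stages are available from the shell:

```bash
octavasc simulate   --config phantom.yaml --out-dir phantom/
octavasc run        --input phantom/volume4d.tif --n-frames 8 \
                    --voxel-size 8 4 4 --out-dir out/
octavasc compare    --input per_animal_summaries.csv \
                    --metric vessel_length_density --out stats.csv
```

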