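# spect-iq

Optimization of acquisition time and reconstruction parameters for
quantitative SPECT image quality, studied end to end on a digital NEMA IEC
body phantom.

Whole-body SPECT/CT is attractive for bone imaging, but at 15 s per
projection angle a multi-bed scan is slow. How short can the acquisition
get before lesions disappear into the noise — and which OSEM iteration
count and Gaussian post-filter best trade contrast against noise at each
count level? `spect-iq` answers this with a fully simulated pipeline aimed
at medical physicists and reconstruction developers:

1. **Digital phantom** — a NEMA IEC torso phantom with six fillable
   spheres (internal diameters 37, 28, 22, 17, 13, 10 mm) at a
   sphere-to-background activity concentration ratio of 8.5:1, rasterised
   to activity (kBq/ml) and attenuation (cm⁻¹) maps.
2. **Acquisition simulation** — a dual-head step-and-shoot camera, 60
   views per head (120 projections) over 360°, 4.8 mm pixels, circular
   orbit, distance-dependent Gaussian collimator-detector blur,
   attenuation, Poisson noise. Each view is acquired as 15 gated 1 s bins
   so that partial bin sums (1–3, 1–8, 1–15) replay the identical scan at
   3, 8 and 15 s per view.
3. **Reconstruction** — 3D OSEM with resolution recovery and attenuation
   correction in a matched system model, followed by a 3D Gaussian
   post-filter (0–12 mm FWHM).
4. **NEMA NU 2-2018 analysis** — per sphere *s*:

   - contrast recovery RCₛ = 100 · (C_H,s / C_B,s − 1) / (R − 1)
   - background variability BVₛ = 100 · SDₛ / C_B,s, with
     SDₛ = √( Σₖ (C_B,s,k − C_B,s)² / (K − 1) ) over the K = 60
     background ROIs (12 positions × 5 slices)
   - contrast-to-noise ratio CNRₛ = (C_H,s − C_B,s) / SD_ROI, with
     visibility judged by the Rose criterion CNR > 5

   where C_H,s is the mean in the sphere ROI, C_B,s the mean of the
   matching-diameter background ROI means and R the true concentration
   ratio.
5. **Parameter sweep** — durations × iterations (4–24, 8 subsets) ×
   post-filter FWHM (0–12 mm) × seeds, with an RC convergence detector
   (successive change < 3.5 %) and figure/table outputs.

## Worked example

```python
import spectiq as sq
from spectiq.nema import build_roi_layout
from spectiq.recon import ReconParams, osem

plan = sq.compute_fill_plan(total_activity_mbq=214.2, stock_volume_ml=1200.0)
print(f"spheres {plan.sphere_concentration_kbq_ml:.1f} kBq/ml, "
      f"background {plan.background_concentration_kbq_ml:.1f} kBq/ml, "
      f"ratio {plan.ratio:.2f}")

spec = sq.default_phantom_spec()
phantom = sq.voxelize_phantom(spec, voxel_size_mm=4.8, grid_shape=(64, 64, 40))
geom = sq.AcquisitionGeometry(matrix=(40, 64))
model = sq.make_system_model(phantom, geom)
rates = model.forward(phantom.activity)
sens = sq.calibrate_sensitivity(rates, geom.time_per_view_s, total_counts=1e6)
geom = sq.AcquisitionGeometry(matrix=(40, 64), sensitivity_cps=sens)

stack = sq.simulate_gated_acquisition(sens * rates, geom, n_gate_bins=15, seed=0)
eight_s = sq.sum_bins(stack, (1, 8))            # bins 1-8 = 8 s per view

vol = osem(eight_s, phantom.mu_map,
           ReconParams(n_iterations=12, n_subsets=8, postfilter_fwhm_mm=8.0),
           model=model)
layout = build_roi_layout(spec, phantom.shape, 4.8, phantom.origin_mm)
for r in sq.evaluate_volume(vol.values, layout, spec.ratio, 4.8, phantom.origin_mm):
    print(f"{r.sphere_diameter_mm:4.0f} mm  RC {r.rc_percent:5.1f} %  "
          f"BV {r.bv_percent:5.1f} %  CNR {r.cnr:5.1f}  visible={r.rose_visible}")
```

Output:

```
spheres 178.5 kBq/ml, background 21.0 kBq/ml, ratio 8.49
  37 mm  RC  73.7 %  BV  18.3 %  CNR  30.2  visible=True
  28 mm  RC  71.0 %  BV  23.0 %  CNR  23.1  visible=True
  22 mm  RC  52.6 %  BV  25.1 %  CNR  15.7  visible=True
  17 mm  RC  36.7 %  BV  29.9 %  CNR   9.2  visible=True
  13 mm  RC  12.5 %  BV  29.6 %  CNR   3.2  visible=False
  10 mm  RC  11.8 %  BV  31.6 %  CNR   2.8  visible=False
```

Reading: the preparation arithmetic reproduces the intended 178.5 and
21 kBq/ml concentrations; at 8 s per view with 12 iterations × 8 subsets
and an 8 mm post-filter, contrast recovery falls with sphere size (the
partial-volume effect), background variability sits in the 18–32 % range
at this count level, and the two smallest spheres fall below the Rose
visibility threshold for this noise realization.

## Command line

```bash
spect-iq phantom  --grid 64,64,40 --out out/
spect-iq simulate --phantom-dir out/ --seed 1 --total-counts 1e6 --out out/proj.h5
spect-iq rebin    --in out/proj.h5 --bins 1-8 --out out/proj_8s.h5
spect-iq recon    --in out/proj_8s.h5 --phantom-dir out/ --iterations 12 --subsets 8 --fwhm 8 --out out/vol.nii.gz
spect-iq analyze  --vol out/vol.nii.gz --out out/metrics.csv
spect-iq sweep    --config sweep.yaml --out results/
spect-iq figures  --csv results/metrics.csv --out results/figs/
```

`sweep` runs the whole study (phantom → simulate → rebin → reconstruct
grid → analyze → convergence report) and writes tidy CSV metrics, a wide
CNR-by-iteration table, a JSON ROI layout and a checksummed manifest; all
randomness derives from the configured seeds.

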