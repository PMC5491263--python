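# prfclust

Nonlinear population receptive field (pRF) mapping with sweeping-bar
stimuli: forward models, grid fitting, cross-validated model comparison,
and visual-field-map metrics, plus a synthetic generator of clustered
retinotopic sheets so the whole pipeline can be validated end to end
against known ground truth.

## The problem

A voxel's *population receptive field* is the region of visual space whose
stimulation drives its aggregate BOLD response. Mapping pRFs with a bar
that sweeps across the visual field works well in early visual cortex, but
higher-order (parietal and frontal) regions respond weakly, have very
large receptive fields, and sum stimulus energy sub-additively — a linear
Gaussian model misfits them. `prfclust` implements the compressive spatial
summation (CSS) variant of the pRF model and the analysis machinery needed
to map such regions and to characterize the *clusters* of polar-angle maps
(adjacent mirrored angle gradients sharing a confluent fovea) that
organize them.

## The model

For a binary stimulus aperture S(x, y) at each time step, the neural
response of a site with pRF center (x₀, y₀), size σ, exponent n and
amplitude β is

    r(t) = β [ ∫∫ S(x, y) G(x, y) dx dy ]ⁿ ,
    G(x, y) = exp( −((x−x₀)² + (y−y₀)²) / 2σ² ),

with 0 < n ≤ 1 (n = 1 is the linear model). The static nonlinearity is
applied before convolution with a canonical double-gamma hemodynamic
response. Because the exponent broadens spatial pooling, the *effective*
pRF size is σ/n. Goodness of fit is variance explained,
ve = 1 − Σ(prediction−data)²/Σdata², computed on mean-removed series.

Fitting follows the coarse grid-fit strategy: time series are spatially
blurred on the cortical sheet (Gaussian, 5 mm FWHM), temporally decimated
(2×), and every candidate on a polar parameter grid (eccentricities ≤ 12°,
σ ≤ 12°, n ∈ {0.25, 0.5, 0.75, 1}) is evaluated with β solved in closed
form; a continuous search refinement on the unblurred series is available.
Sites with ve < 10% or centers beyond the 12° display limit are excluded.
Models (nonlinear, linear, contralateral-only) are compared by
leave-one-bar-width-out cross-validation, and maps are summarized by the
laterality index (contralateral Gaussian mass of each pRF, using σ/n),
coverage density (pointwise mean of peak-normalized pRFs), effective size
versus eccentricity, and polar-angle reversal detection along the sheet.

## Worked example

```python
from prfclust.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=1)          # study defaults, two-cluster synthetic sheet
res = run_pipeline(cfg, "demo_out")
ff = res["fit_frame"]
print("retained:", int(ff.retained.sum()), "of", len(ff))
print("median ve: %.3f" % ff.ve.median())
print("mean laterality: %.3f" % ff[ff.retained].laterality.mean())
print(res["comparison"].summary().head(3).to_string(index=False))
print("reversals at sheet rows:", res["reversals"])
```

prints (abridged):

```
retained: 800 of 800
median ve: 0.979
mean laterality: 0.661
region         model     mean      sem   n
  c0m0 contralateral 0.100687 0.006732 200
  c0m0        linear 0.906533 0.002635 200
  c0m0     nonlinear 0.963936 0.002051 200
reversals at sheet rows: [17, 37, 57]
```

The simulated sheet (two clusters × two maps, compressive n = 0.5, noise
at 0.5× signal SD) is fit almost perfectly by the generating model class;
the cross-validated accuracy orders nonlinear > linear > contralateral in
every region, exactly the signature that distinguishes spatially tuned
compressive responses from a mere contralateral preference; the mean
laterality index (0.5 = no lateral bias, 1 = fully contralateral) shows
the expected contralateral bias; and the three polar-angle reversals sit
at the planted map borders (rows 20/40/60, found within the smoothing
guard of the detector). `demo_out/` then contains `fits.csv`,
`model_comparison.csv`, `coverage_map.npz`, `size_vs_eccentricity.csv`
and a provenance manifest.

The same stages are scriptable from the shell:

```bash
prfclust simulate --seed 1 --out sheet
prfclust fit --dataset sheet --model css --blur-fwhm 5 --decimate 2 --out fits.csv
prfclust evaluate --dataset sheet --out comparison.csv
prfclust metrics --fits fits.csv --outdir metrics/
prfclust run --seed 1 --out demo_out   # everything at once
```

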