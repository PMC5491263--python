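# Methods

This note documents the models, numerical choices and limitations of
`prfclust` in one place. Everything quantitative stated here is computed
by the test suite or the acceptance script; nothing is asserted from
memory.

## Stimulus model

The mapping stimulus is a bar aperture sweeping across a square visual
field, 24° on a side, in 1.6° steps synchronized to a 2-s TR; bar widths
are 1, 2 or 3° and the long axis spans the field. With these values each
sweep visits 15 positions (centers from −12° + width/2 in 1.6° steps while
inside the field); the bar is clipped at the display edge on the final
step(s). Behavioral parameterization is included for completeness: each
bar carries three patches of moving dots (124/248/372 dots per patch for
the three widths, i.e. constant areal density anchored at the 1° count),
and flanker coherence follows a two-up-one-down staircase. Staircase step
sizes are not constrained by the procedure's description; both default to
0.05 coherence and are configurable. The rule as stated converges near
70.7% correct (the textbook value for two-up-one-down); the package
implements the rule, not a target percentage.

**Rasterization.** Apertures are binary masks on a regular raster
(pixel-center-in-rectangle rule). The default is 5 samples/deg: a 0.2°
pixel divides the 1.6° step and all three bar widths exactly, so bar edges
fall identically on the raster at every position. With an incommensurate
raster (e.g. 4 samples/deg, 6.4 px per step) the effective bar edge drifts
by a sub-pixel amount per position, which costs several percent RMS in the
predicted series for small pRFs; at 5 vs 10 samples/deg predictions agree
to ≤0.2% RMS for σ ≥ 0.5° (tested). Coordinates are visual degrees, x
rightward, y upward, origin at fixation, shared by all modules.

## Forward model

The CSS response is the overlap integral of mask and isotropic Gaussian,
raised to the exponent n, scaled by β, then convolved with a canonical
double-gamma HRF (positive lobe peaking ~5 s, undershoot ~15 s at ratio
1/6, unit-sum kernel sampled at the TR). The HRF is a package choice
isolated behind `HRFSpec`; it is not estimated from data. The Gaussian is
normalized to unit integral by default so that a full-field stimulus gives
exactly βⁿ·1 = β and β carries consistent units across σ; the raw peak-1
mode is retained for exactness checks. The exponent is applied to the
neural signal before HRF convolution (a static nonlinearity).

The contralateral model is deliberately shape-free: a binary regressor
that is 1 whenever any stimulus pixel lies strictly in the hemifield
opposite the site's hemisphere, HRF-convolved, with only its amplitude
fit. It is the null against which spatial tuning is demonstrated.

## Fitting

Series are converted to fluctuation units (per-run mean removal) before
fitting, so the Σdata² denominator of variance explained behaves as a
variance; predictions are mean-removed identically. A raw (no mean
removal) mode of `variance_explained` exists for completeness.

The grid fit evaluates every (x₀, y₀, σ, n) candidate: 8 polar angles × 12
log-spaced eccentricities (0.5–12°) plus the origin for centers, 10
log-spaced σ (0.25–12°), and exponents {0.25, 0.5, 0.75, 1} — the exact
center/σ sets of the original coarse-fit procedure are not recoverable, so
these density choices are package defaults and overridable. β is solved
per candidate by ordinary least squares, clipped at zero by default
(responses are modeled as positive). Exact score ties break to the smaller
σ, then the smaller n, then candidate order — a package rule chosen so the
least-flexible candidate wins. The fit is fully deterministic, and is
verified in tests against an independently coded exhaustive loop through
the public forward-model API.

Preprocessing follows the coarse-fit convention: spatial blurring on the
sheet with a Gaussian kernel of 5 mm FWHM (site-wise normalized weights
from pairwise sheet distances) and 2× temporal decimation (non-overlapping
block means, trailing partial block dropped), applied consistently to data
and predictions. The optional search stage refines a grid seed by
Nelder–Mead over (x₀, y₀, log σ, n) with β profiled out, on the unblurred,
undecimated series, bounded by the grid limits; if the optimizer cannot
improve on the seed, the seed is returned unchanged, so the search is
never worse in sample. Voxel filters retain a site iff variance explained
≥ 0.10 and center eccentricity ≤ 12°.

Interpolating solutions onto sites excluded from the blurred fit is not
implemented; synthetic sites are all fit directly.

## Model comparison

Leave-one-bar-width-out cross-validation: three folds, each bar width held
out once; the Gaussian models are fully re-solved on the training runs,
the contralateral model fits only its amplitude; each model is scored by
variance explained on the held-out width's runs, and per-site accuracy is
the mean over folds. Training and test runs never overlap (asserted by
fold bookkeeping). ROI summaries report mean ± SEM of per-site accuracy.

Two regimes are worth distinguishing, and the tests cover both. Under
compressive ground truth (n = 0.25) at 0.5× noise the nonlinear model
holds a large cross-validated margin over the linear model (~0.14 ve) and
both dominate the contralateral model in every region. Under linear
ground truth the margin collapses by more than an order of magnitude; at
low noise (0.1×), where nearly every site selects the correct exponent,
the paired nonlinear−linear difference is statistically indistinguishable
from zero. At higher noise the nonlinear model pays a small systematic
out-of-sample penalty (a few thousandths of ve) for its extra parameter —
cross-validation grants no advantage to flexibility, and under a simpler
truth it mildly punishes it.

## Map metrics

**Laterality.** The index is the fraction of a pRF's Gaussian mass in the
contralateral hemifield, *using the effective size σ/n as the Gaussian
SD*: Φ(x₀/(σ/n)) for a left-hemisphere site (contralateral field x > 0),
mirrored for the right hemisphere. Endpoints: 0 fully ipsilateral, 0.5 no
lateral bias, 1 fully contralateral; LI(x₀) + LI(−x₀) = 1. The closed form
is verified against 2D quadrature of the isotropic Gaussian over the
half-plane to < 10⁻⁶ across x₀ ∈ [−12, 12]. Larger σ/n at fixed centers
pulls the index toward 0.5 — the mechanism behind weaker laterality where
pRFs are large.

**Coverage density.** The pointwise *mean* (not envelope) of retained
pRFs, each rendered as a peak-1 Gaussian with SD σ/n, so the map reflects
both coverage and the density of centers. Peak normalization (rather than
β-weighting or unit-integral normalization) is the default so density
reflects the center/size distribution; β-weighting is an option. Maps are
not clipped at the display edge.

**Size vs. eccentricity.** Binned mean ± SEM of σ/n over retained fits;
empty bins are reported as missing, never zero.

**Angle reversals.** Along an ordered sheet path, the angle sequence is
smoothed (3-sample moving average), differenced, and a reversal is
declared where the derivative's sign flips with at least 3 same-sign steps
on each side (the guard against noise). Polar angle convention: 0° =
contralateral horizontal meridian, ±90° = vertical meridians.

## Synthetic data

The generator emulates the features the analysis depends on: clusters of
mirrored polar-angle gradients (each map ramps −90° → +90° along the
sheet, reversing in the adjacent map) sharing one eccentricity gradient
whose minimum — the confluent fovea — lies on the maps' common border; σ
growing linearly with eccentricity (default 0.5° + 0.25°/°); exponents
from the grid set, one per map; centers within 12°. Layout invariants are
checked explicitly after generation, not assumed. The sheet is a flat
2D grid at 1 mm spacing standing in for a flattened cortical patch; the
pipeline default is 20 rows per map × 10 eccentricity columns (2-cm maps,
800 sites for two two-map clusters), so the 5-mm blur kernel is
proportionate to map size as it is on real cortex.

Noise is additive white Gaussian with SD equal to `noise_sd` × the site's
noiseless signal SD (the source text gives no SNR figures for
frontoparietal voxels, so 0.5× is the package's default "moderate" level);
an AR(1) option provides temporally correlated noise. Ground-truth
exponents drawn from the grid set (and centers/σ snapped to grid values)
make exact grid recovery possible; continuous "off-grid" mode exercises
the search stage. Simulation is reproducible given its seed.

What passing synthetic tests do *not* show: robustness to motion, spikes,
drift, physiological noise, HRF variability across cortex, mesh-geodesic
(rather than Euclidean) blurring, or the irregular geometry of real
cortical maps. Results on real scans depend on those factors; the NIfTI
reading path exists but real-data validation is out of scope.

## Problem sizes and determinism

Tests and the acceptance suite run the full stimulus set (3 widths × 4
sweep directions × 15 steps per run, 2 runs per width) against sheets of
50–520 sites; the 500-site recovery experiment (noiseless + 0.5× noise)
completes in seconds on one core. Synthetic runs are shorter than real
scanning runs; run length is a package choice made to keep simulation
inexpensive, and every stage scales to longer runs unchanged. All
stochastic steps take explicit seeds; the grid fit is deterministic, and
identical configs reproduce pipeline outputs byte for byte.

## Known limitations

- The exact grid values of the cited coarse-fit implementation are not
  recoverable; recovery statements are relative to this package's grid.
- With 8 polar angles, snapping high-eccentricity ground truth to the grid
  can move a center to a neighboring (inner) ring, and spatial blurring
  pulls fitted centers slightly foveal on steep synthetic gradients; both
  effects are visible as mild eccentricity compression in pipeline output.
- β non-negativity is the default; allow negative amplitudes via
  `nonnegative_beta=False` where suppression is plausible.
- The contralateral model ignores blank periods' structure beyond the HRF;
  blanks are supported in aperture sequences but not required anywhere.
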