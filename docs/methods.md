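# Methods

## Blinking model

Each docking site carries `n_repeat_motifs` independent binding motifs.  A
motif alternates between unbound dwells ~ Exp(mean 1/`per_site_binding_rate`)
and bound dwells ~ Exp(mean `mean_bound_time` ×
`destabilizer_on_time_factor`).  This captures the three experimental
levers of DNA-PAINT kinetics: imager concentration (the binding rate is
proportional to it; only the rate is simulated, the concentration is
metadata), repeat-motif docking strands (event frequency multiplies by the
motif count), and duplex-destabilizing additives such as ethylene carbonate
(the bright time shrinks by a factor in (0, 1]).  Simultaneous occupancy of
distinct motifs is allowed by default and adds linearly in brightness
(`allow_simultaneous=False` collapses the site to a single blocking process
with the pooled rate).  Photobleaching is absent by default — exchangeable
imagers are replenished from the buffer — and the per-frame occupancy is
computed by exact interval intersection with the frame grid, so no sub-frame
discretization tolerance exists anywhere downstream.

Default kinetics in the bundled configuration (all stated here as package
choices, since published rate constants for specific sequences/buffers vary
widely): dense/SOFI mode — rate 0.4–2 /s/motif, bound time 0.25–0.5 s,
5 motifs, destabilizer factor 0.2; sparse/SMLM mode — rate 0.01 /s, bound
time 0.5 s, 1 motif.

## Optics and camera

Emission is a 2-D Gaussian PSF *integrated over pixel areas* (erf
differences), not center-sampled; this matters below ~2 px fwhm because the
effective sampled width is √(σ² + a²/12) for pixel size a.  Defaults:
100 nm pixels, 300 nm PSF fwhm, 100 Hz.  Photons per bound imager default to
5×10⁴ /s (hundreds to thousands of photons per frame — bright organic
dyes); the uniform diffusive-imager background is scaled by the illumination
mode (TIRF 1×, HILO 2.5×, EPI 8×), and an optional wide-Gaussian structural
background emulates out-of-focus signal.  Camera counts are
gain·Poisson(expected) + N(0, read noise) + offset, rounded and clipped at
zero (defaults: gain 2 counts/photon, offset 100, read noise 1.6 counts —
sCMOS-like).  One master seed derives per-site and per-acquisition child
streams (`SeedSequence` spawn keys), so adding a site or a tile never
perturbs existing traces.

## Cumulant estimation

Joint cumulants use the moment/partition formula with all series
mean-subtracted and biased (1/T) moment estimators; partitions containing
singleton blocks vanish identically and are skipped.  Cross-cumulants of
order n populate an n-fold oversampled lattice: the fine point (i + a/n,
j + b/n) takes the pixel multiset with offset sums (a, b) and minimal
spread Σ|rᵢ − r̄|² (the floor/ceil split per axis, which is the separable
global optimum; ties broken by pairing sorted dy with sorted dx).  The
Gaussian distance factor exp(−Σ|rᵢ − r̄|²/(2σ²)), σ from the configured
PSF, is recorded per lattice site.  Pixel borders are handled periodically
(np.roll); a 1-camera-pixel margin is flagged in provenance and cropped by
metrics.  Only fully degenerate pixel combinations (a = b = 0) carry
shot-noise bias — noise independent across pixels cancels from any mixed
cumulant — which is why the flattening stage includes a per-parity gain
equalization (ratio of sums against a smoothed reference over the
high-signal mask) on top of the analytic distance-factor division.

Acquisitions are split into 1000-frame subsequences (shorter inputs form a
single block; remainder frames beyond full blocks are dropped to keep block
variance equal).  Blocks are registered to the first by phase correlation
with sub-pixel upsampling; shifts are estimated on the order-2 images,
which have by far the best SNR, and rescaled to each order's lattice —
estimating shifts on order-4/6 blocks directly is unstable because a block
in which one emitter dominates the cumulant can masquerade as drift.

## Post-processing

Flatten → Richardson–Lucy → signed n-th root.  RL (scikit-image) runs on
the negativity-clipped image with reflective padding of one kernel width;
the signed cumulant values are retained in the `CumulantImage` for
diagnostics.  The kernel is Gaussian with fwhm `psf_fwhm_px`/√order camera
pixels (10 iterations): the order-n cumulant image has PSF fwhm psf/√n, so
a fixed-width kernel would over-deconvolve high orders — with a matched,
√n-scaled kernel the decorrelation resolution decreases monotonically
through orders 2→4→6 on the filament phantom, which is the behavior the
method exists to deliver.  `scale_kernel_with_order=False` restores a fixed
4.2 px kernel.  Brightness linearization (sign(v)|v|^(1/n)) converts the
n-th-power brightness weighting of raw cumulants back to linear; an
optional bSOFI-style re-convolution with a Gaussian of fwhm 4.2/√n px is
off by default.  Flattening is applied after drift-corrected combination
(the alternative order is not observably different on static simulations
but this keeps one flattening per order).

## Quality metrics

*Decorrelation resolution*: the apodized (Tukey α = 0.25) image spectrum is
correlated with its unit-modulus normalization under 100 binary circular
masks of radius 0–1 (Nyquist-normalized), for the raw image and 20 Gaussian
high-pass filtered versions (widths geometrically spaced from size/4 to
0.5 px); the cutoff is the largest local-maximum radius with amplitude
≥ 0.05 above the curve tail (a boundary maximum counts, so pure noise
reports the Nyquist cutoff); resolution = 2·pixel/cutoff.

*Jackknife SNR*: leave-one-frame-out order-n auto-cumulant images computed
from updatable raw power sums P_k = Σ x^k (binomial re-centering per
left-out frame — N reconstructions at the cost of ~one), σ =
√[(N−1)/N Σ(Iₙ − Ī)²] (the standard jackknife factor is adopted), SNR =
I/σ, NaN where σ = 0.  For order 1 this equals s/√N exactly.

*Cross-section FWHM*: bilinear profile sampling at ≤ 0.25 px, baseline =
mean of the outer 20 % of samples, half-max crossings by linear
interpolation; the caller passes the lattice pixel size (camera pixel /
oversampling).

*RSP/RSE*: the reference (std-projection by default) is resampled to the
reconstruction grid, registered by phase correlation, and compared against
α·(SR ⊗ Gaussian RSF) + β with the RSF fwhm optimized by bounded scalar
minimization on [0.5, 20] px and α, β in closed form; RSE is the minimized
RMSE, RSP the Pearson correlation at the optimum.

## SMLM branch

Detection is a difference-of-Gaussians band-pass (σ 1.0/2.0 px,
"equivalent defaults" — no bit-parity with any particular plugin version is
claimed) with 8-connected maxima above 3 × robust noise SD (1.4826·MAD).
Fitting is a pixel-integrated 2-D Gaussian plus constant background by
weighted least squares with weights 1/max(counts, 1), fit radius 4 px,
initial σ 1.6 px; non-converged or border fits are dropped.  Localization
uncertainty is the Thompson-style formula σ_loc² = (s² + a²/12)/N +
8πs⁴b²/(a²N²) in nm (the 15 nm default filter threshold is therefore in
nm).  Drift correction renders 500-frame blocks as 20 nm histograms
(σ = 2 bins smoothing), registers them by phase correlation, and applies a
per-frame linearly interpolated/extrapolated correction; at ~1500
localizations per block its registration precision is a few nm, which
bounds the residual after correcting a 0.2 nm/frame drift to < 5 nm RMS.
ASH rendering averages 2×2 shifted histograms on a 5× (default) finer grid
and conserves total mass.

## Mosaics

Grid plans step by tile×(1 − overlap) in raster order (defaults 10 %
overlap).  Simulated stage error is clipped-Gaussian jitter (SD 2 px,
bounded at ±2 SD — stages have repeatability specs).  Stitching measures
every adjacent pair by maximizing the normalized cross-correlation of the
overlap window over an integer search grid around the nominal step with
(i) a Fisher-z lower-confidence-bound correction so a smaller candidate
window cannot win on a chance correlation, and (ii) a weak Gaussian prior
(σ = 3 camera px) on deviation from the nominal step; the integer peak is
polished to sub-pixel precision on 4× spline-upsampled windows.  All pair
measurements are then solved jointly as a translation graph by weighted
least squares with a weak nominal anchor, dropping the worst-residual edge
while redundancy allows — a single spurious pair cannot displace a tile
that other overlaps constrain.  Blending is a linear feather over the
overlap ramps.  Registration runs on *flattened* order-2 images: raw
cross-cumulant tiles share a lattice-periodic gain pattern that phase- and
cross-correlation lock onto instead of the sample.

## What the simulations do and do not show

The generator reproduces the statistical structure the analysis relies on
(exponential dwells, motif superposition, PSF-shaped photon images,
shot/read noise, stage jitter) but not sample realism: no labeling
stochasticity beyond site placement, no dye photophysics, no 3-D defocus,
no photobleaching by default, uniform background.  Passing tests therefore
validate the estimators and the pipeline mechanics, not performance on real
microscope data, whose resolution numbers depend on sample and optics.

Problem sizes used in the test suite and acceptance script — 64 px fields,
3000-frame movies for the order-2/4/6 resolution series, 6000 frames for
the order-4 two-point target (two clusters of 4 docking strands, as on
DNA-origami resolution rulers), 500-frame tiles for the 2×3 mosaic,
200-repeat localization ensembles — are the package's choices for a
desk-scale, fully reproducible demonstration; per-site κ₄ estimator
variance sets the floor on what a *single* isolated emitter can show at
order 4, which is why the two-point target uses small strand clusters.

## Known limitations

* Cross-cumulant borders are periodic; the outermost camera pixel of each
  reconstruction is not trustworthy (flagged in provenance).
* Order-5/6 images from single sparse emitters are estimator-noise limited
  below ~10⁴ frames; dense structures average this out.
* The decorrelation peak-significance threshold (0.05) is a stated default;
  extremely smooth noise-free images can report conservative cutoffs.
* Drift correction assumes drift is slow relative to the 500-frame block
  (≲ 0.5 nm/frame at default settings).
* The stitcher's global solve handles translations only — no rotation,
  scale, or illumination flat-fielding.
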