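# paintsofi

Super-resolution imaging with DNA-PAINT probes is slow: sparse blinking and
long exposures make single-molecule localization microscopy (SMLM) a
minutes-to-hours technique. Super-resolution optical fluctuation imaging
(SOFI) extracts sub-diffraction information from the *statistics* of much
denser blinking, so the same exchangeable-label sample can be screened
orders of magnitude faster — at a lower, but tunable, resolution — and then
re-imaged by SMLM where it matters. `paintsofi` implements that whole
workflow on synthetic data:

* **`paintsofi.blink_sim`** — a DNA-PAINT blinking-movie simulator with
  programmable hybridization kinetics (binding rate ∝ imager concentration ×
  repeat motifs, bright time shortened by duplex destabilizers), a
  pixel-integrated Gaussian PSF, diffusive background, and an sCMOS camera
  model.
* **`paintsofi.cumulants`** — zero-lag auto- and cross-cumulant images of
  orders 2–6 via the partition formula
  κ(X₁…X_n) = Σ_π (−1)^{|π|−1}(|π|−1)! Π_{B∈π} E[Π_{i∈B} X_i],
  with virtual pixels on an n-fold oversampled lattice, per-lattice-site
  Gaussian distance factors, 1000-frame subsequence splitting and
  cross-correlation drift correction between subsequences.
* **`paintsofi.postproc`** — flattening (distance-factor and lattice-parity
  gain removal), Richardson–Lucy deconvolution, and bSOFI-style brightness
  linearization (signed n-th root), orchestrated by `sofi_pipeline`.
* **`paintsofi.metrics`** — image decorrelation resolution analysis
  (100 mask radii × 20 high-pass filters), leave-one-frame-out jackknife SNR
  maps (σ = √[(N−1)/N Σ(Iₙ−Ī)²], SNR = I/σ), cross-section FWHM, and
  SQUIRREL-style RSP/RSE artifact scores.
* **`paintsofi.localize`** — a minimal ThunderSTORM-style SMLM branch:
  DoG detection, pixel-integrated Gaussian fitting by weighted least squares
  (fit radius 4 px, initial σ 1.6 px), Thompson-formula uncertainties with a
  15 nm filter, cross-correlation drift correction, and averaged-shifted-
  histogram rendering at 5×.
* **`paintsofi.mosaics`** — multi-position grid acquisition (e.g. 4×9, 10 %
  overlap) over a large phantom, and stitching with NCC offset refinement
  and linear feather blending.

## Worked example

Simulate a filament sample under SOFI-optimized kinetics, reconstruct
orders 2–4, switch to sparse kinetics and localize — all from one command:

```bash
paintsofi workflow -o demo_out
```

which prints a QC report (`demo_out/qc_report.json`) like:

```json
{
  "seed": 1,
  "sofi_orders": [2, 3, 4],
  "decorrelation_resolution_nm": {
    "2": 217.4, "3": 196.1, "4": 161.3, "average": 350.9
  },
  "n_localizations_raw": 2623,
  "n_localizations_kept": 2004,
  "median_uncertainty_nm": 1.89,
  "rsp_sofi2": 0.997
}
```

Reading: the diffraction-limited average image of the 500-frame,
100 Hz movie resolves ~351 nm; second-, third- and fourth-order SOFI sharpen
that to 217/196/161 nm; after the simulated buffer switch the sparse movie
yields ~2000 localizations with ~2 nm predicted precision; and the order-2
reconstruction agrees with the std-projection wide-field reference at
RSP = 0.997 (1.0 = artifact-free).

The same pieces are available as a library:

```python
from paintsofi import (KineticParams, OpticsCamera, make_filament_phantom,
                       render_movie, sofi_pipeline, SofiConfig,
                       decorrelation_resolution)

kin = KineticParams(per_site_binding_rate=1.0, mean_bound_time=0.25,
                    n_repeat_motifs=5, destabilizer_on_time_factor=0.2)
phantom = make_filament_phantom(3, (6400., 6400.), 0.04, kin, seed=11)
movie = render_movie(phantom, OpticsCamera(n_frames=3000, seed=7))
recon = sofi_pipeline(movie, SofiConfig(orders=(2, 4), psf_fwhm_px=3.0))
print(decorrelation_resolution(recon.images[4], 25.0).resolution_nm)
```

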