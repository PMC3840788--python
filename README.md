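# septinsim

Geometric models of septin–Gic1–Cdc42 filament cables and a synthetic
cryo-electron-tomography pipeline to validate them: phantom rendering,
tilt-series simulation with CTF / noise / missing wedge, weighted
back-projection, and a quantification suite (cross-correlation,
z-elongation, inter-filament spacing, subunit-gap counting,
octamer/hexamer mixture classification, mask-based density extraction).

No external data is required — all inputs are generated by the package
itself.

## Package layout

| module               | contents |
|----------------------|----------|
| `septinsim.models`   | Subunit-order and ligand-binding rules for every complex variant; 3D cable lattices with cross-bridge contact records; analytic gap / contact counts. |
| `septinsim.phantom`  | Gaussian-blob (and flat-top ball) rendering of lattices into density volumes and projections; labelled 2D particle mixtures; Gaussian low-pass; block binning. |
| `septinsim.tiltsim`  | Tilt geometry (±60° in 2° steps by default), relativistic wavelength, CTF (200 kV, 4 µm underfocus defaults), projection, additive Gaussian noise. |
| `septinsim.recon`    | Weighted back-projection (ramp filter with raised-cosine rolloff, zero-padded), missing-wedge occupancy. |
| `septinsim.quant`    | Pearson CC (whole-volume or masked), bridge z-elongation, spacing recovery, gap counting, end-density/length particle classifier, mask-extract. |
| `septinsim.pipelines`| End-to-end replica parameterizations shared by tests, CLI and the acceptance report. |
| `septinsim.mrcio`    | Minimal MRC2014 (mode 2) I/O, `.tlt` angle files, YAML metadata sidecars. |

## CLI

```bash
septinsim build-phantom --variant WT_GIC1_CDC42GTP --size 128 phantom.mrc
septinsim simulate --tilt-range 60 --tilt-step 2 \
    --geometry long_axis_parallel_to_beam --defocus 4 --snr 0.1 \
    phantom.mrc series
septinsim reconstruct series recon.mrc
septinsim quantify --model phantom.mrc --resolution 45 recon.mrc
septinsim classify --n 1000 --fraction 0.9 --snr 5 --seed 1
```

## Calibrated / documented defaults

* **Per-image SNR 0.1** (`tiltsim.DEFAULT_SNR`) for the noisy
  simulation path. The emulated acquisition states a dose (~1 e⁻/Å²
  per image), not an SNR; per-image SNR well below 1 is characteristic
  of that dose, and 0.1 reproduces the reference correlation of ~0.95
  for the noisy replica. The correlation is evaluated over a structure
  mask (model low-passed to 40 Å, thresholded at 10% of maximum);
  whole-volume mode is also exposed and yields lower values because
  the CTF suppresses the low-frequency bulk of the blob phantom.
* **Subunit blobs**: isotropic Gaussians, FWHM = 4 nm subunit
  diameter. **Bridges**: FWHM spans the bridge footprint (2 subunits
  for Gic1, 4 for Gic1·Cdc42-GppNHp; mass scale 1.5 for the latter).
  For thresholded-extent (elongation) measurements the bridge is
  rendered as a flat-top uniform ball of the same diameter — a
  Gaussian's wedge elongation is scale-free (~40% at half maximum)
  whereas an edge-dominated compact body reproduces the published
  ~14% behaviour.
* **z-elongation protocol**: reconstruction least-squares
  intensity-normalized to the model, then both volumes thresholded at
  the *same* absolute level (0.5 × model component peak); sub-voxel
  crossings interpolated. Sensitivity to the threshold is reported by
  `fig_replica_elongation(threshold_frac=...)`.
* **CTF** sign convention: underfocus positive, contrast negative at
  low k; the simulation can re-invert the stack
  (`invert_contrast=True`) to keep protein density positive.
  Cs = 2.0 mm and amplitude contrast 0.07 defaults.
* **Ramp weighting** with raised-cosine rolloff over the top 5% of
  frequencies, zero-padded to avoid circular wraparound; per-image DC
  exactly zero.
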