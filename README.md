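# srpscat

Quantitative analysis for **stimulated Raman photothermal encoded
scattering (SRPSCAT)** single-molecule vibrational imaging.

SRPSCAT reads out the Raman spectrum of a single, label-free biomolecule
through elastic scattering: pump (ω_p) and Stokes (ω_s) beams deposit
vibrational energy ω_p − ω_s into the molecule; the resulting photothermal
temperature rise ΔT changes the particle's refractive index (Δn) and radius
(Δr), which modulates its interferometric scattering (iSCAT) contrast at
the excitation modulation frequency. A lock-in measurement of that
modulation therefore carries chemical information while retaining the
single-molecule sensitivity of iSCAT, whose contrast

&nbsp;&nbsp;&nbsp;&nbsp;C = 2(|s|/|r|)·cos φ + (|s|/|r|)²,&nbsp;&nbsp;
|s| ∝ k²·α,&nbsp;&nbsp; α = a³·(m² − 1)/(m² + 2)

is dominated by the interference term (∝ d³) for small particles, and is to
good approximation **linear in molecular mass** for proteins — the basis of
mass photometry.

The package covers the downstream analyses such a measurement supports:

| module | what it does |
| --- | --- |
| `srpscat.core_model` | analytic forward model: polarizability, iSCAT contrast, steady-state photothermal heating ΔT = P_abs/(4πκa), SRPSCAT/SRS modulation depths |
| `srpscat.synthetic_data` | seeded synthetic microscope: hyperspectral stacks, landing movies, two-state binding traces, step traces, amide-I spectra, calibration intensity sets — all with ground truth |
| `srpscat.image_quant` | spot detection (difference-of-Gaussians), subpixel 2D-Gaussian fitting, locked-position spectrum and time-trace extraction, frame-averaging denoise hook |
| `srpscat.mass_calibration` | intensity histograms, Gaussian-mixture fitting (EM), linear intensity–mass calibration with accuracy metrics, d³/d⁶ power-law fits |
| `srpscat.spectral_analysis` | pixel-wise non-negative LASSO unmixing, four-band amide-I deconvolution into α-helix/β-sheet/extended fractions, C–H band classification (2939 vs 2930 cm⁻¹) and band ratios |
| `srpscat.kinetics` | trace idealization, dwell-time bookkeeping, exponential-MLE k_on/k_off/K_D with bootstrap intervals, single change-point (step) detection |
| `srpscat.io` / `srpscat.cli` | TIFF + CSV-sidecar stack formats, validated YAML/JSON run configuration, reproducible pipeline stages, `srpscat` command line |

## Worked example

Simulate a field containing one IgM (CH₃ stretch at 2939 cm⁻¹) and one BSA
(2930 cm⁻¹) molecule, detect them, classify their C–H bands, and run the
mass-calibration pipeline:

```python
import numpy as np
from srpscat import synthetic_data as sd, image_quant as iq
from srpscat import mass_calibration as mc, spectral_analysis as sa

lib = sd.default_species_library()
scene = sd.SceneSpec(shape=(64, 64), pixel_size=100.0,
                     spots=((1500.0, 1500.0, "IgM"), (4500.0, 4500.0, "BSA")))
axis = np.arange(2800.0, 3101.0, 5.0)
stack, truth = sd.simulate_hyperspectral_stack(
    scene, lib, sd.NoiseSpec(sd=0.05, seed=1), axis)

spots = iq.detect_spots(stack.band(stack.band_nearest(2939.0)),
                        min_snr=5.0, pixel_size=100.0)
for s in sorted(spots, key=lambda r: r.x_nm):
    spec = iq.extract_spectrum(stack, s)
    center, label = sa.classify_ch_band(spec.wavenumbers, spec.intensities)
    print(f"spot at ({s.x_nm:.0f}, {s.y_nm:.0f}) nm: amplitude {s.amplitude:.2f}, "
          f"C-H peak {center:.1f} cm^-1 -> {label}")

table, _ = sd.simulate_calibration_set([66.5, 80.0, 150.0, 160.0, 950.0],
                                       slope=1.0, cv=0.10, n_per_species=500,
                                       seed=1)
means, masses = [], []
for mass, grp in table.groupby("mass_kda"):
    means.append(mc.fit_mixture(grp["intensity"].to_numpy(), k=1).primary_mean)
    masses.append(mass)
cal = mc.fit_calibration(means, masses)
print(f"calibration slope {cal.slope:.3f} per kDa, "
      f"average error {cal.average_error_pct:.2f}%")
analyte = np.random.default_rng(2).normal(142.2, 14.22, 500)
mass = mc.estimate_mass(mc.fit_mixture(analyte, k=1).primary_mean, cal)
print(f"analyte mass estimate: {mass:.1f} kDa")
```

Output:

```
spot at (1501, 1500) nm: amplitude 9.46, C-H peak 2937.9 cm^-1 -> immunoglobulin-like
spot at (4505, 4496) nm: amplitude 0.52, C-H peak 2930.4 cm^-1 -> non-immunoglobulin
calibration slope 0.998 per kDa, average error 0.49%
analyte mass estimate: 141.5 kDa
```

The two spots are found at their planted positions with their planted peak
amplitudes (contrast = 0.01 per kDa × mass), the C–H peak position sorts
immunoglobulins from other proteins, the five-calibrant line recovers the
configured unit slope with sub-percent average error, and a 142.2 kDa
analyte (a designed trimeric protein in its compact state) is estimated to
141.5 kDa from its intensity histogram alone.

## Command line

Each pipeline stage runs from a validated YAML/JSON configuration and
writes its artifacts plus a JSON report naming the config hash and seeds,
so identical configurations give byte-identical outputs:

```sh
srpscat simulate  --config run.yaml --seed 1 --out out/
srpscat quantify  --config run.yaml --out out/
srpscat calibrate --config run.yaml --out out/
srpscat unmix     --config run.yaml --out out/
srpscat structure --config run.yaml --out out/
srpscat kinetics  --config run.yaml --out out/
```

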