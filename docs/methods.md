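# Methods

## Signal model

A particle of diameter d and refractive index n_p in a medium of index n_m
is treated as a Rayleigh scatterer with polarizability volume
α = a³(m²−1)/(m²+2), a = d/2, m = n_p/n_m. The scattered field magnitude is
modeled as |s| = k²α/w with k = 2π/λ_probe and w = 0.61 λ/NA the focal
waist; the reference field is the interface reflection with amplitude
coefficient |r| (default 0.122, a glass n = 1.7 / water interface). The
iSCAT contrast is

    C = 2 (|s|/|r|) cos φ + (|s|/|r|)²

The interference phase is fixed at cos φ = 1 (constructive detection,
configurable): it reproduces the positive d³ intensity law measured on
polystyrene beads, and nothing in the measurement constrains φ further.
Only the ratio |s|/|r| enters the contrast, so any common rescaling of
both fields leaves every prediction unchanged.

Photothermal heating uses the steady-state point-source solution at the
particle surface, ΔT = P_abs/(4π κ a), valid because nanoparticle thermal
time constants (ns) are far below the 1 MHz modulation period. The absorbed
power is lumped into a per-species coefficient c_abs (W absorbed per W² of
pump×Stokes power product at band center, default 1e-5 W⁻¹); this stands in
for the full stimulated-Raman energy-deposition calculation, which needs
the vibrational cross-section and focal intensity distribution. The heated
particle has index n_p + (dn_p/dT)ΔT and radius a(1 + βΔT) with β the
linear thermal-expansion coefficient (defaults −1e-4 K⁻¹ and 2e-4 K⁻¹,
protein-like). The SRPSCAT modulation depth is the relative contrast change
between cold and heated particle; the SRS comparator is the relative pump
loss P_abs/P_pump.

With the default optics (20 mW pump, 10 mW Stokes, NA 1.3, 780 nm probe)
and an IgM-sized protein sphere (13 nm, n = 1.44), the model gives an
SRPSCAT modulation depth of 1.2e-5 and an SRS depth of 1.0e-7 — a two-order
separation. These are order-of-magnitude outputs of the analytic
approximation only. A known tension: the steady-state ΔT at these settings
is ~0.04 K, much smaller than transient peak temperatures obtained from
pulsed-excitation heat-transport models; the modulation-depth orders, which
depend on the product of thermo-optic sensitivity and duty-cycle-averaged
heating, are the quantities this model is meant to place, not ΔT itself.
A second tension is inherited from the measurement: absorbed power should
scale with particle volume (d³), which with contrast sensitivity would
steepen the size law beyond the observed d³; the synthetic microscope
therefore treats the per-particle modulation depth as a species property
independent of d, so simulated amplitudes follow the empirical d³
interference law.

## Synthetic microscope

Spots are isotropic 2D Gaussians with 230 nm FWHM (the instrument's
measured resolution), rendered on a 100 nm pixel grid; spot peak amplitude
at band ν is `contrast_per_kda × mass × S(ν)` with S the species band
spectrum (pseudo-Voigt peaks, unit maximum, mixing 0.5 by default). Readout
noise is additive Gaussian — a surrogate for shot-noise-limited lock-in
detection, which is Gaussian to excellent approximation — with no Poisson
photon budget, speckle background, stage drift, or focus wander. Landing
events are Poisson in time and uniform in space and persist once landed
(no photobleaching: the method is label-free). Two-state binding traces are
continuous-time Markov chains with exact exponential waiting times
(unbound→bound at k_on·C, bound→unbound at k_off) thinned onto the frame
grid, preserving the continuous-time model the rate fits assume; the
initial state is stationary. Every generator is a pure function of
(parameters, seed) and returns the ground truth needed to score downstream
stages.

Passing tests on these inputs demonstrates correctness of the estimators
under the stated noise model; it does not certify performance against
speckle, drift, or non-Gaussian instrument artifacts, which real stacks
contain and self-supervised learned denoisers target (the `denoise_hook`
provides the interface plus a √n frame-averaging baseline).

## Image quantification

Detection runs a difference-of-Gaussians band-pass (σ, 1.6σ at the PSF
width) and keeps local maxima above `min_snr` robust (median/MAD) standard
deviations of the filtered image; each candidate is refined by
least-squares 2D Gaussian + constant background over a ±3σ_max window.
Detections closer than one PSF FWHM merge keeping the higher amplitude, and
a fitted width > 1.05× the nominal PSF flags a likely unresolved pair.
Spectra and time traces are extracted with the centroid and width locked
(closed-form linear solve for amplitude and background per band/frame):
immobilized molecules do not move, and per-band refits would distort the
spectrum. The per-spot "intensity" statistic is the fitted peak amplitude;
the integrated intensity 2πAσ² is also reported for analyses that prefer
it. Positions are nm from the center of the top-left pixel, 0-based.

## Mass calibration

Mixtures are fitted on raw intensity values by EM (k-means initialization,
seeded, components sorted by mean) rather than by curve-fitting binned
histograms: the bin-free likelihood is better behaved at a few hundred
events. Histograms use Freedman–Diaconis bins and are for display. The
component count k is user-chosen with a BIC helper for k ∈ 1..5. Components
near 2× the primary mean are reported as dimer/coincidence peaks and
excluded from calibration. The intensity–mass line is ordinary least
squares with a free intercept (reported, not forced through zero);
residuals are re-expressed in kDa through the fitted slope, giving the
average relative error and the maximum absolute deviation (mass accuracy).
Size scaling is quantified as the OLS slope of log intensity on log
diameter.

## Spectral analysis

Unmixing solves, per pixel, min ‖y − Σᵢ cᵢ rᵢ‖² + λ Σᵢ|cᵢ| with cᵢ ≥ 0 by
cyclic coordinate descent (all pixels updated simultaneously; tolerance
1e-10 on the coefficient sup-norm). Non-negativity is on by default because
abundances are physical concentrations; λ = 0 reduces to non-negative least
squares, and a K-fold cross-validation helper over spectral channels is
provided for λ selection. References are normalized to unit maximum.

Amide-I deconvolution fits four pseudo-Voigt bands — aromatic ring modes
(1615 cm⁻¹), α-helix (1656), β-sheet (1671), extended structures (1680) —
with centers free within ±5 cm⁻¹, areas free, and a linear baseline
refined jointly with the bands. Component FWHMs (20/26/18/14 cm⁻¹) and the
Lorentzian mixing fraction (0.5) are **fixed by default**: the three
structural bands overlap within ~25 cm⁻¹, and releasing their shapes makes
the area split non-identifiable — at 1% noise a free-shape fit trades
several percentage points of area between neighboring bands while
improving χ² below the noise floor. `vary_widths` / `vary_fraction`
release these for well-separated spectra. Structural fractions are the
α/β/extended areas as percentages of their sum; ring modes are aromatic
side-chain vibrations, not secondary structure, and are excluded so the
fractions sum to 100. On synthetic compositions at 1% noise the mean
absolute fraction error is below 1 percentage point.

C–H classification takes the parabolically interpolated peak position in
2800–3100 cm⁻¹ and labels it immunoglobulin-like above the 2934.5 cm⁻¹
midpoint between the immunoglobulin CH₃ stretch (2939 cm⁻¹, β-sheet-
restricted side chains) and the 2930 cm⁻¹ position of other proteins.

## Kinetics

Idealization thresholds the trace with optional hysteresis (frames inside
the dead band keep their previous state); the automatic threshold is the
midpoint of a two-component Gaussian mixture of the trace values and
raises if the components are separated by less than twice their width.
Dwells are run lengths × dt; the first and last runs are censored by the
observation window and excluded from fits by default. Rates are closed-form
exponential MLEs (reciprocal mean dwell): k_off from bound dwells, k_on
from unbound dwells divided by the ligand concentration — a required input,
since a concentration-normalized k_on cannot be computed without it.
K_D = k_off/k_on by definition. Percentile bootstrap intervals
(1000 seeded resamples) accompany the point estimates; a histogram-fit
mode exists for comparison with binned analyses.

Limitations, measured on synthetic data: dwells shorter than one frame are
unobservable and no dead-time correction is applied; and dwell samples
collected from observation windows only ~10 mean dwells long overestimate
rates by ~10% even after censored dwells are excluded, because dwells that
complete inside a short window are a short-biased sample. The bias decays
with window length and is negligible at the ≥100× windows typical of
binding experiments. For exponential dwells the include/exclude choice for
the end-truncated dwell is nearly neutral (its length is the age of a
memoryless interval), but exclusion is kept as the default since real
kinetics need not be exponential.

Step detection is exhaustive single-change-point least squares (two
constant levels for every split, minimum residual sum of squares, O(n) via
cumulative sums) with a significance gate: the level difference must
exceed g = 3 pooled residual standard deviations. Both directions are
reported; the amplitude ratio post/pre maps a conformational mass change
onto the linear intensity–mass law.

## Problem sizes and reproducibility

Test-suite and acceptance-script problem sizes — 10⁴ dwells for rate
recovery, 500 events per calibrant across five calibrants, 141-point
amide-I spectra, 10³ null traces for the step-detector false-positive
rate — were chosen so that Monte-Carlo standard errors sit well below the
assertion tolerances while the full suite runs in seconds. All randomness
flows through explicit `numpy.random.default_rng` seeds passed as
arguments; no global state is used, and identical (parameters, seed) calls
are bit-identical.
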