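"""Seeded generators for every input the analysis pipeline consumes.

The module emulates an SRPSCAT microscope at the level the downstream
statistics see: diffraction-limited spots (2D Gaussian PSF, default 230 nm
FWHM), species Raman spectra built from pseudo-Voigt bands, per-spot contrast
linear in molecular mass, Gaussian readout noise standing in for
shot-noise-limited detection, Poisson landing events, continuous-time
two-state binding dynamics, and single-step conformational transitions.

Every generator is a pure function of its parameters and seed and returns
machine-readable ground truth (pandas tables / dataclasses) sufficient to
score the downstream stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kinetics import DwellSet
from .stacks import HyperspectralStack, IntensityTrace, TimeLapseStack

__all__ = [
    "SpeciesSpec",
    "SceneSpec",
    "NoiseSpec",
    "TwoStateParams",
    "pseudo_voigt",
    "pseudo_voigt_area",
    "default_species_library",
    "simulate_hyperspectral_stack",
    "simulate_landing_movie",
    "simulate_two_state_trace",
    "simulate_step_trace",
    "make_amide_spectrum",
    "simulate_calibration_set",
    "AMIDE_BAND_CENTERS",
    "AMIDE_BAND_WIDTHS",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Amide-I component bands: aromatic ring modes, alpha-helix, beta-sheet,
#: extended structures (centers in cm^-1).
AMIDE_BAND_CENTERS = {"ring": 1615.0, "alpha": 1656.0,
                      "beta": 1671.0, "extended": 1680.0}
#: Default FWHM (cm^-1) used when synthesizing amide-I spectra.
AMIDE_BAND_WIDTHS = {"ring": 20.0, "alpha": 26.0,
                     "beta": 18.0, "extended": 14.0}


class UnknownSpeciesError(KeyError):
    """A scene references a species absent from the library."""


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float,
                 eta: float = 0.5) -> np.ndarray:
    """Unit-peak-height pseudo-Voigt: eta Lorentzian + (1-eta) Gaussian.

    Both components share the same FWHM.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    x = np.asarray(x, dtype=float)
    sigma = fwhm * FWHM_TO_SIGMA
    gamma = fwhm / 2.0
    gauss = np.exp(-0.5 * ((x - center) / sigma) ** 2)
    lorentz = gamma**2 / ((x - center) ** 2 + gamma**2)
    return eta * lorentz + (1.0 - eta) * gauss


def pseudo_voigt_area(x: np.ndarray, center: float, fwhm: float, area: float,
                      eta: float = 0.5) -> np.ndarray:
    """Pseudo-Voigt with the given integrated area (same shape as lmfit's)."""
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    x = np.asarray(x, dtype=float)
    sigma = fwhm * FWHM_TO_SIGMA
    gamma = fwhm / 2.0
    gauss = np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    lorentz = (gamma / math.pi) / ((x - center) ** 2 + gamma**2)
    return area * (eta * lorentz + (1.0 - eta) * gauss)


@dataclass(frozen=True)
class SpeciesSpec:
    """A chemical species: Raman bands plus its mass-to-contrast law.

    ``peaks`` holds (center cm^-1, FWHM cm^-1, relative amplitude,
    Gaussian/Lorentzian mixing fraction eta) tuples; the composite spectrum
    is normalized to unit maximum on the simulated axis so that
    ``contrast_per_kda * mass`` is the spot amplitude at the strongest band.
    """

    name: str
    peaks: Tuple[Tuple[float, float, float, float], ...]
    contrast_per_kda: float = 0.01
    mass: float = 100.0     # kDa

    def __post_init__(self) -> None:
        for center, fwhm, amp, eta in self.peaks:
            if fwhm <= 0:
                raise ValueError(f"{self.name}: band width must be > 0")
            if amp < 0:
                raise ValueError(f"{self.name}: band amplitude must be >= 0")
            if not 0.0 <= eta <= 1.0:
                raise ValueError(f"{self.name}: mixing fraction in [0, 1]")
        if self.mass <= 0:
            raise ValueError("mass must be > 0")

    def spectrum(self, wavenumbers: np.ndarray,
                 normalize: bool = True) -> np.ndarray:
        """Composite band spectrum on the given axis (unit max if normalize)."""
        wavenumbers = np.asarray(wavenumbers, dtype=float)
        out = np.zeros_like(wavenumbers)
        for center, fwhm, amp, eta in self.peaks:
            out += amp * pseudo_voigt(wavenumbers, center, fwhm, eta)
        if normalize:
            peak = out.max()
            if peak > 0:
                out = out / peak
        return out

    @property
    def amplitude(self) -> float:
        """Spot amplitude at the strongest band, detector units."""
        return self.contrast_per_kda * self.mass


@dataclass(frozen=True)
class SceneSpec:
    """Field geometry and spot placement for synthetic images."""

    shape: Tuple[int, int] = (64, 64)          # (ny, nx) pixels
    pixel_size: float = 100.0                  # nm
    spots: Tuple[Tuple[float, float, str], ...] = ()  # (x nm, y nm, species)
    psf_fwhm: float = 230.0                    # nm

    def __post_init__(self) -> None:
        if self.psf_fwhm <= 0:
            raise ValueError("psf_fwhm must be > 0")
        ny, nx = self.shape
        for x, y, _ in self.spots:
            if not (0 <= x <= (nx - 1) * self.pixel_size
                    and 0 <= y <= (ny - 1) * self.pixel_size):
                raise ValueError(f"spot ({x}, {y}) outside field")

    @property
    def psf_sigma(self) -> float:
        return self.psf_fwhm * FWHM_TO_SIGMA

    def min_pairwise_distance(self) -> float:
        """Smallest spot separation in nm (inf when < 2 spots)."""
        if len(self.spots) < 2:
            return math.inf
        pos = np.array([(x, y) for x, y, _ in self.spots])
        d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
        return float(d[np.triu_indices(len(pos), k=1)].min())


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian readout noise (shot-noise-limited surrogate)."""

    background: float = 0.0      # detector units
    sd: float = 1.0              # detector units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class TwoStateParams:
    """First-order binding kinetics: unbound -> bound at k_on*C, back at k_off."""

    k_on: float                  # M^-1 s^-1
    concentration: float         # M
    k_off: float                 # s^-1
    dt: float                    # s, frame interval
    duration: float              # s
    bound_level: float = 10.0    # detector units
    unbound_level: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_on", "concentration", "k_off", "dt", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.bound_level <= self.unbound_level:
            raise ValueError("bound_level must exceed unbound_level")

    @property
    def k_obs(self) -> float:
        """Pseudo-first-order association rate k_on * C in s^-1."""
        return self.k_on * self.concentration


def _render_spots(shape: Tuple[int, int], pixel_size: float, sigma_nm: float,
                  positions: Sequence[Tuple[float, float]],
                  amplitudes: Sequence[float]) -> np.ndarray:
    """Sum of 2D Gaussians with given peak heights, sampled at pixel centers."""
    ny, nx = shape
    yy = np.arange(ny)[:, None] * pixel_size
    xx = np.arange(nx)[None, :] * pixel_size
    img = np.zeros((ny, nx), dtype=float)
    for (x, y), amp in zip(positions, amplitudes):
        img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma_nm**2))
    return img


def default_species_library() -> Dict[str, SpeciesSpec]:
    """Reference species used throughout tests and examples.

    Band positions follow the standard assignments: polystyrene aromatic C-H
    at 3055 cm^-1; immunoglobulin CH3 stretch at 2939 cm^-1 vs 2930 cm^-1
    for other proteins, with the 2880 cm^-1 shoulder; amide-I alpha-helix at
    1656 cm^-1 (apoferritin-like) and beta-sheet at 1671 cm^-1
    (fibronectin-like); DNA C-H stretch at 2959 cm^-1 for full viral capsids.
    """
    return {
        "PS": SpeciesSpec("PS", ((3055.0, 25.0, 1.0, 0.5),
                                 (2904.0, 40.0, 0.3, 0.5)),
                          contrast_per_kda=0.01, mass=8000.0),
        "IgM": SpeciesSpec("IgM", ((2939.0, 50.0, 1.0, 0.5),
                                   (2880.0, 45.0, 0.55, 0.5)),
                           contrast_per_kda=0.01, mass=950.0),
        "IgA": SpeciesSpec("IgA", ((2939.0, 50.0, 1.0, 0.5),
                                   (2880.0, 45.0, 0.55, 0.5)),
                           contrast_per_kda=0.01, mass=160.0),
        "IgG": SpeciesSpec("IgG", ((2939.0, 50.0, 1.0, 0.5),
                                   (2880.0, 45.0, 0.55, 0.5)),
                           contrast_per_kda=0.01, mass=150.0),
        "transferrin": SpeciesSpec("transferrin", ((2930.0, 50.0, 1.0, 0.5),
                                                   (2880.0, 45.0, 0.7, 0.5)),
                                   contrast_per_kda=0.01, mass=80.0),
        "BSA": SpeciesSpec("BSA", ((2930.0, 50.0, 1.0, 0.5),
                                   (2880.0, 45.0, 0.7, 0.5)),
                          contrast_per_kda=0.01, mass=66.5),
        "apoferritin": SpeciesSpec("apoferritin", ((1656.0, 30.0, 1.0, 0.5),
                                                   (1615.0, 20.0, 0.2, 0.5)),
                                   contrast_per_kda=0.01, mass=460.0),
        "fibronectin": SpeciesSpec("fibronectin", ((1671.0, 25.0, 1.0, 0.5),
                                                   (1615.0, 20.0, 0.2, 0.5)),
                                   contrast_per_kda=0.01, mass=470.0),
        "full_capsid": SpeciesSpec("full_capsid", ((2930.0, 50.0, 1.0, 0.5),
                                                   (2959.0, 35.0, 0.8, 0.5)),
                                   contrast_per_kda=0.01, mass=5000.0),
        "empty_capsid": SpeciesSpec("empty_capsid", ((2930.0, 50.0, 1.0, 0.5),
                                                     (2959.0, 35.0, 0.2, 0.5)),
                                    contrast_per_kda=0.01, mass=3700.0),
    }


def simulate_hyperspectral_stack(
    scene: SceneSpec,
    species: Dict[str, SpeciesSpec],
    noise: NoiseSpec,
    wavenumbers: np.ndarray,
) -> Tuple[HyperspectralStack, pd.DataFrame]:
    """Render a hyperspectral cube plus its ground-truth spot table.

    Each spot is a 2D Gaussian of the scene PSF whose peak height at band nu
    is ``contrast_per_kda * mass * spectrum(nu)`` (spectrum normalized to
    unit max on the axis).  Gaussian readout noise and a constant background
    are added per NoiseSpec.
    """
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if wavenumbers.ndim != 1 or len(wavenumbers) < 1:
        raise ValueError("wavenumber axis must be a non-empty 1D array")
    if len(wavenumbers) > 1 and not np.all(np.diff(wavenumbers) > 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    for _, _, name in scene.spots:
        if name not in species:
            raise UnknownSpeciesError(name)

    rng = np.random.default_rng(noise.seed)
    ny, nx = scene.shape
    cube = np.empty((ny, nx, len(wavenumbers)), dtype=float)

    positions = [(x, y) for x, y, _ in scene.spots]
    specs = [species[name] for _, _, name in scene.spots]
    norm_spectra = [sp.spectrum(wavenumbers) for sp in specs]

    for b in range(len(wavenumbers)):
        amps = [sp.amplitude * s[b] for sp, s in zip(specs, norm_spectra)]
        cube[:, :, b] = _render_spots(scene.shape, scene.pixel_size,
                                      scene.psf_sigma, positions, amps)
    cube += noise.background
    if noise.sd > 0:
        cube += rng.normal(0.0, noise.sd, size=cube.shape)

    truth = pd.DataFrame({
        "spot_id": np.arange(len(scene.spots)),
        "x_nm": [x for x, _, _ in scene.spots],
        "y_nm": [y for _, y, _ in scene.spots],
        "species": [n for _, _, n in scene.spots],
        "amplitude": [sp.amplitude for sp in specs],
        "mass_kda": [sp.mass for sp in specs],
        "min_pair_distance_nm": scene.min_pairwise_distance(),
    })
    stack = HyperspectralStack(cube, wavenumbers, scene.pixel_size,
                               metadata={"generator": "simulate_hyperspectral_stack",
                                         "seed": noise.seed})
    return stack, truth


def simulate_landing_movie(
    arrival_rate: float,
    species: SpeciesSpec,
    duration: float,
    dt: float,
    scene: SceneSpec,
    noise: NoiseSpec,
) -> Tuple[TimeLapseStack, pd.DataFrame]:
    """Poisson landing events: spots appear one at a time and persist.

    Event times are Poisson with the given rate, positions uniform over the
    field.  The event table records true times, positions, amplitudes, and
    an ``overlap`` flag set when an event lands within one PSF FWHM of an
    earlier one.
    """
    if arrival_rate < 0:
        raise ValueError("arrival_rate must be >= 0")
    if dt >= duration:
        raise ValueError("dt must be smaller than duration")
    rng = np.random.default_rng(noise.seed)
    ny, nx = scene.shape
    n_events = rng.poisson(arrival_rate * duration)
    t_events = np.sort(rng.uniform(0.0, duration, size=n_events))
    x_events = rng.uniform(0.0, (nx - 1) * scene.pixel_size, size=n_events)
    y_events = rng.uniform(0.0, (ny - 1) * scene.pixel_size, size=n_events)

    overlap = np.zeros(n_events, dtype=bool)
    for i in range(n_events):
        for j in range(i):
            d = math.hypot(x_events[i] - x_events[j], y_events[i] - y_events[j])
            if d < scene.psf_fwhm:
                overlap[i] = True
                break

    n_frames = max(2, int(round(duration / dt)))
    cube = np.empty((ny, nx, n_frames), dtype=float)
    amp = species.amplitude
    for k in range(n_frames):
        t = k * dt
        landed = t_events <= t
        cube[:, :, k] = _render_spots(
            scene.shape, scene.pixel_size, scene.psf_sigma,
            list(zip(x_events[landed], y_events[landed])),
            [amp] * int(landed.sum()))
    cube += noise.background
    if noise.sd > 0:
        cube += rng.normal(0.0, noise.sd, size=cube.shape)

    events = pd.DataFrame({
        "event_id": np.arange(n_events),
        "time_s": t_events,
        "x_nm": x_events,
        "y_nm": y_events,
        "amplitude": amp,
        "overlap": overlap,
    })
    movie = TimeLapseStack(cube, dt, scene.pixel_size,
                           metadata={"generator": "simulate_landing_movie",
                                     "seed": noise.seed})
    return movie, events


def simulate_two_state_trace(
    params: TwoStateParams, seed: int = 0
) -> Tuple[IntensityTrace, DwellSet]:
    """Continuous-time two-state Markov trace sampled on the frame grid.

    State dwell times are exact exponential draws (rate k_on*C out of the
    unbound state, k_off out of the bound state) thinned onto the frame
    grid, so that the continuous-time model downstream fits assume is
    preserved.  The initial state is drawn from the stationary distribution.
    The returned DwellSet holds the true (uncensored) exponential draws.
    """
    rng = np.random.default_rng(seed)
    k_ub = params.k_obs          # unbound -> bound
    k_bu = params.k_off          # bound -> unbound
    p_bound = k_ub / (k_ub + k_bu)

    state = 1 if rng.random() < p_bound else 0  # 1 = bound
    t = 0.0
    switch_times: List[float] = []
    states_seq: List[int] = [state]
    bound_dwells: List[float] = []
    unbound_dwells: List[float] = []
    while t < params.duration:
        rate = k_bu if state == 1 else k_ub
        dwell = rng.exponential(1.0 / rate)
        (bound_dwells if state == 1 else unbound_dwells).append(dwell)
        t += dwell
        switch_times.append(t)
        state = 1 - state
        states_seq.append(state)

    n_frames = max(2, int(round(params.duration / params.dt)))
    times = np.arange(n_frames) * params.dt
    # state at frame time: number of switches before t gives index into states_seq
    idx = np.searchsorted(switch_times, times, side="right")
    frame_state = np.array(states_seq)[idx]
    levels = np.where(frame_state == 1, params.bound_level, params.unbound_level)
    intensities = levels.astype(float)
    if params.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, params.noise_sd, n_frames)

    trace = IntensityTrace(times, intensities, params.dt)
    dwells = DwellSet(
        bound=np.asarray(bound_dwells, dtype=float),
        unbound=np.asarray(unbound_dwells, dtype=float),
        bound_censored=np.zeros(len(bound_dwells), dtype=bool),
        unbound_censored=np.zeros(len(unbound_dwells), dtype=bool),
        dt=params.dt,
    )
    return trace, dwells


def simulate_step_trace(
    pre_level: float,
    post_level: float,
    step_time: float,
    duration: float,
    dt: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[IntensityTrace, Dict[str, float]]:
    """Piecewise-constant trace with one upward step plus Gaussian noise.

    Models a single-molecule conformational transition seen as a one-step
    mass (intensity) increase; the ground-truth dict records the step frame
    and the two levels.
    """
    if not 0 < step_time < duration:
        raise ValueError("step_time must lie strictly inside (0, duration)")
    if post_level <= pre_level:
        raise ValueError("post_level must exceed pre_level (upward step)")
    if dt <= 0 or dt >= duration:
        raise ValueError("need 0 < dt < duration")
    rng = np.random.default_rng(seed)
    n_frames = max(2, int(round(duration / dt)))
    times = np.arange(n_frames) * dt
    intensities = np.where(times < step_time, pre_level, post_level).astype(float)
    step_frame = int(np.searchsorted(times, step_time))
    if noise_sd > 0:
        intensities = intensities + rng.normal(0.0, noise_sd, n_frames)
    truth = {
        "step_frame": float(step_frame),
        "step_time": float(step_time),
        "pre_level": float(pre_level),
        "post_level": float(post_level),
        "level_ratio": float(post_level / pre_level) if pre_level != 0 else math.inf,
    }
    return IntensityTrace(times, intensities, dt), truth


def make_amide_spectrum(
    fractions: Tuple[float, float, float],
    ring_amplitude: float = 0.15,
    noise_sd: float = 0.01,
    wavenumbers: Optional[np.ndarray] = None,
    seed: int = 0,
    total_area: float = 100.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Synthetic amide-I spectrum with known secondary-structure fractions.

    ``fractions`` are the (alpha, beta, extended) percentages, summing to
    100; each structural band's area is proportional to its fraction.  The
    aromatic ring-mode band at 1615 cm^-1 has area
    ``ring_amplitude * total_area`` and is not part of the structural
    fractions.  ``noise_sd`` is Gaussian noise as a fraction of the peak
    height.  Returns (wavenumbers, intensities).
    """
    alpha, beta, extended = fractions
    if min(alpha, beta, extended) < 0:
        raise ValueError("structural fractions must be non-negative")
    if abs(alpha + beta + extended - 100.0) > 0.1:
        raise ValueError("structural fractions must sum to 100")
    if wavenumbers is None:
        wavenumbers = np.arange(1580.0, 1720.0 + 1e-9, 1.0)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    rng = np.random.default_rng(seed)

    areas = {
        "ring": ring_amplitude * total_area,
        "alpha": alpha / 100.0 * total_area,
        "beta": beta / 100.0 * total_area,
        "extended": extended / 100.0 * total_area,
    }
    spectrum = np.zeros_like(wavenumbers)
    for band, area in areas.items():
        spectrum += pseudo_voigt_area(
            wavenumbers, AMIDE_BAND_CENTERS[band], AMIDE_BAND_WIDTHS[band],
            area, eta=0.5)
    peak = spectrum.max()
    if noise_sd > 0 and peak > 0:
        spectrum = spectrum + rng.normal(0.0, noise_sd * peak, len(wavenumbers))
    return wavenumbers, spectrum


def simulate_calibration_set(
    masses: Sequence[float],
    slope: float = 1.0,
    cv: float = 0.10,
    n_per_species: int = 500,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-event intensity samples for a set of calibrant masses.

    For each mass, ``n_per_species`` intensities are drawn Gaussian around
    ``slope * mass`` with sd ``cv * slope * mass`` — the single-molecule
    intensity histogram of a calibrant protein.  Returns the long-format
    sample table and the ground-truth law.
    """
    if slope <= 0 or n_per_species <= 0:
        raise ValueError("slope and n_per_species must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if any(m <= 0 for m in masses):
        raise ValueError("masses must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for m in masses:
        mu = slope * m
        samples = rng.normal(mu, cv * mu, size=n_per_species) if cv > 0 \
            else np.full(n_per_species, mu)
        rows.append(pd.DataFrame({"mass_kda": m, "intensity": samples}))
    table = pd.concat(rows, ignore_index=True)
    truth = {"slope": float(slope), "intercept": 0.0, "cv": float(cv)}
    return table, truth
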