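"""Single-molecule measurements from image stacks.

Detects diffraction-limited spots with a difference-of-Gaussians band-pass,
refines each candidate by least-squares 2D Gaussian fitting (subpixel
position, peak amplitude above local background, width), and extracts
per-spot spectra from hyperspectral stacks and intensity traces from
time-lapse movies with the centroid locked across bands/frames —
immobilized molecules do not move, and per-band refits would distort the
spectrum.

Conventions: pixel indices are 0-based; physical positions are nm from the
center of the top-left pixel.  Background statistics are robust (median and
MAD-derived sd) because spots bias mean-based estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from .stacks import HyperspectralStack, IntensityTrace, TimeLapseStack

__all__ = [
    "SpotRecord",
    "SpotSpectrum",
    "detect_spots",
    "fit_spot",
    "extract_spectrum",
    "track_spot_trace",
    "denoise_hook",
    "robust_background",
    "PartialWindowError",
]

_MAD_TO_SD = 1.4826
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
DEFAULT_PSF_SIGMA_NM = 230.0 * FWHM_TO_SIGMA


class PartialWindowError(ValueError):
    """Fit window extends beyond the image border."""


@dataclass
class SpotRecord:
    """A detected diffraction-limited feature."""

    spot_id: int
    x_nm: float
    y_nm: float
    amplitude: float            # fitted peak height above background
    integrated_intensity: float  # 2 pi amplitude sigma^2, units * nm^2
    background: float
    sigma_nm: float
    snr: float
    converged: bool = True
    overlapped: bool = False


@dataclass
class SpotSpectrum:
    """Per-band amplitude of one spot with its wavenumber axis."""

    spot_id: int
    wavenumbers: np.ndarray
    intensities: np.ndarray
    background_corrected: bool = True

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("axis and intensity lengths differ")

    def argmax_wavenumber(self) -> float:
        return float(self.wavenumbers[int(np.argmax(self.intensities))])


def robust_background(image: np.ndarray) -> Tuple[float, float]:
    """(median, MAD-based sd) of an image."""
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return med, _MAD_TO_SD * mad


def _window_slices(shape: Tuple[int, int], cy: int, cx: int,
                   half: int) -> Tuple[slice, slice]:
    ny, nx = shape
    if not (half <= cy < ny - half and half <= cx < nx - half):
        raise PartialWindowError(
            f"window of half-size {half} at ({cy}, {cx}) exceeds image {shape}")
    return slice(cy - half, cy + half + 1), slice(cx - half, cx + half + 1)


def fit_spot(image: np.ndarray, initial_xy_nm: Tuple[float, float],
             pixel_size: float = 100.0,
             expected_sigma_nm: float = DEFAULT_PSF_SIGMA_NM,
             sigma_bounds_nm: Optional[Tuple[float, float]] = None,
             spot_id: int = 0) -> SpotRecord:
    """Least-squares 2D Gaussian + constant background around a position.

    The window spans +-3 sigma_max.  Amplitude is the fitted peak height
    above background; integrated intensity is 2 pi A sigma^2.  A fit that
    fails to converge is returned flagged (``converged=False``).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if sigma_bounds_nm is None:
        sigma_bounds_nm = (0.4 * expected_sigma_nm, 2.5 * expected_sigma_nm)
    sig_lo, sig_hi = sigma_bounds_nm
    half = max(2, int(math.ceil(3.0 * sig_hi / pixel_size)))
    if min(image.shape) < 2 * half + 1:
        raise ValueError(
            f"image {image.shape} smaller than fit window {2 * half + 1}")

    x0, y0 = initial_xy_nm
    cx = int(round(x0 / pixel_size))
    cy = int(round(y0 / pixel_size))
    cy = min(max(cy, half), image.shape[0] - half - 1)
    cx = min(max(cx, half), image.shape[1] - half - 1)
    sy, sx = _window_slices(image.shape, cy, cx, half)
    win = image[sy, sx]
    yy = (np.arange(sy.start, sy.stop) * pixel_size)[:, None]
    xx = (np.arange(sx.start, sx.stop) * pixel_size)[None, :]

    bkg0 = float(np.median(win))
    amp0 = float(win.max() - bkg0)
    p0 = [amp0 if amp0 != 0 else 1.0, x0, y0, expected_sigma_nm, bkg0]
    lo = [-np.inf, xx.min(), yy.min(), sig_lo, -np.inf]
    hi = [np.inf, xx.max(), yy.max(), sig_hi, np.inf]
    p0 = np.clip(p0, lo, hi)

    def residual(p):
        a, px, py, s, b = p
        model = a * np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2 * s * s)) + b
        return (model - win).ravel()

    sol = least_squares(residual, p0, bounds=(lo, hi),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    a, px, py, s, b = sol.x
    _, noise_sd = robust_background(image)
    snr = abs(a) / noise_sd if noise_sd > 0 else np.inf
    return SpotRecord(
        spot_id=spot_id,
        x_nm=float(px), y_nm=float(py),
        amplitude=float(a),
        integrated_intensity=float(2.0 * math.pi * a * s * s),
        background=float(b),
        sigma_nm=float(s),
        snr=float(snr),
        converged=bool(sol.success),
    )


def detect_spots(image: np.ndarray, min_snr: float = 5.0,
                 pixel_size: float = 100.0,
                 expected_sigma_nm: float = DEFAULT_PSF_SIGMA_NM,
                 sigma_bounds_nm: Optional[Tuple[float, float]] = None,
                 overlap_sigma_factor: float = 1.05) -> List[SpotRecord]:
    """Detect diffraction-limited spots in a single band or frame.

    Candidates are local maxima of a difference-of-Gaussians band-pass
    exceeding ``min_snr`` robust background sds of the filtered image; each
    is refined by :func:`fit_spot`.  Detections closer than one PSF FWHM are
    merged keeping the higher amplitude; a fitted width exceeding
    ``overlap_sigma_factor`` times the expected PSF width marks a likely
    unresolved pair (``overlapped=True``).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if min_snr <= 0:
        raise ValueError("min_snr must be > 0")
    sigma_px = expected_sigma_nm / pixel_size
    dog = (ndimage.gaussian_filter(image, sigma_px)
           - ndimage.gaussian_filter(image, 1.6 * sigma_px))
    _, dog_sd = robust_background(dog)
    if dog_sd == 0:
        dog_sd = max(float(np.abs(dog).max()) * 1e-12, 1e-300)
    coords = peak_local_max(dog, min_distance=max(1, int(round(sigma_px))),
                            threshold_abs=min_snr * dog_sd, exclude_border=False)

    records: List[SpotRecord] = []
    for cy, cx in coords:
        try:
            rec = fit_spot(image, (cx * pixel_size, cy * pixel_size),
                           pixel_size=pixel_size,
                           expected_sigma_nm=expected_sigma_nm,
                           sigma_bounds_nm=sigma_bounds_nm,
                           spot_id=len(records))
        except PartialWindowError:
            continue
        if not rec.converged:
            continue
        rec.overlapped = rec.sigma_nm > overlap_sigma_factor * expected_sigma_nm
        records.append(rec)

    # merge duplicates within one PSF FWHM, keeping the higher amplitude
    fwhm = expected_sigma_nm / FWHM_TO_SIGMA
    records.sort(key=lambda r: -abs(r.amplitude))
    kept: List[SpotRecord] = []
    for rec in records:
        merged = False
        for other in kept:
            if math.hypot(rec.x_nm - other.x_nm, rec.y_nm - other.y_nm) < fwhm:
                other.overlapped = other.overlapped or rec.overlapped
                merged = True
                break
        if not merged:
            kept.append(rec)
    for i, rec in enumerate(kept):
        rec.spot_id = i
    return kept


def _locked_amplitude(image: np.ndarray, x_nm: float, y_nm: float,
                      sigma_nm: float, pixel_size: float) -> Tuple[float, float]:
    """Closed-form LSQ (amplitude, background) at fixed centroid and width."""
    half = max(2, int(math.ceil(3.0 * sigma_nm / pixel_size)))
    cy = int(round(y_nm / pixel_size))
    cx = int(round(x_nm / pixel_size))
    sy, sx = _window_slices(image.shape, cy, cx, half)
    win = image[sy, sx].astype(float)
    yy = (np.arange(sy.start, sy.stop) * pixel_size)[:, None]
    xx = (np.arange(sx.start, sx.stop) * pixel_size)[None, :]
    g = np.exp(-((xx - x_nm) ** 2 + (yy - y_nm) ** 2) / (2 * sigma_nm**2)).ravel()
    y = win.ravel()
    n = len(y)
    # solve [[g.g, g.1], [1.g, n]] [A, B] = [g.y, sum y]
    gg = float(g @ g)
    gs = float(g.sum())
    det = gg * n - gs * gs
    amp = (n * float(g @ y) - gs * float(y.sum())) / det
    bkg = (gg * float(y.sum()) - gs * float(g @ y)) / det
    return amp, bkg


def extract_spectrum(stack: HyperspectralStack, spot: SpotRecord) -> SpotSpectrum:
    """Per-band amplitude of a spot with position and width locked.

    At every wavenumber the amplitude and local background are solved in
    closed form for a Gaussian of the spot's fitted width at its fitted
    centroid; the returned intensities are background-corrected.
    """
    intensities = np.empty(len(stack.wavenumbers))
    for b in range(len(stack.wavenumbers)):
        amp, _ = _locked_amplitude(stack.band(b), spot.x_nm, spot.y_nm,
                                   spot.sigma_nm, stack.pixel_size)
        intensities[b] = amp
    return SpotSpectrum(spot.spot_id, stack.wavenumbers.copy(), intensities)


def track_spot_trace(stack: TimeLapseStack,
                     position_nm: Tuple[float, float],
                     sigma_nm: float = DEFAULT_PSF_SIGMA_NM,
                     spot_id: int = 0) -> IntensityTrace:
    """Per-frame amplitude at a fixed position (locked-position fit)."""
    x_nm, y_nm = position_nm
    n = stack.shape[2]
    intensities = np.empty(n)
    for k in range(n):
        amp, _ = _locked_amplitude(stack.frame(k), x_nm, y_nm,
                                   sigma_nm, stack.pixel_size)
        intensities[k] = amp
    return IntensityTrace(stack.times, intensities, stack.frame_interval,
                          spot_id=spot_id)


def denoise_hook(stack: Union[HyperspectralStack, TimeLapseStack],
                 method: str = "none", n: int = 1):
    """Denoising interface with a frame-averaging baseline.

    ``none`` returns the stack unchanged; ``frame_average`` applies a
    running mean of ``n`` frames along the stack's last axis, reducing
    independent noise by sqrt(n).  The hook exists so that learned
    denoisers can be slotted in without changing downstream code.
    """
    if method == "none":
        return stack
    if method != "frame_average":
        raise ValueError(f"unknown denoise method: {method!r}")
    if n < 1:
        raise ValueError("frame_average window must be >= 1")
    if n == 1:
        return stack
    data = ndimage.uniform_filter1d(stack.data.astype(float), size=n,
                                    axis=2, mode="nearest")
    if isinstance(stack, HyperspectralStack):
        return HyperspectralStack(data, stack.wavenumbers, stack.pixel_size,
                                  metadata=dict(stack.metadata))
    return TimeLapseStack(data, stack.frame_interval, stack.pixel_size,
                          metadata=dict(stack.metadata))
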