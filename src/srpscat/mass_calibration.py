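"""Intensity-to-mass conversion for single-molecule scattering contrast.

Single-molecule scattering contrast is, to good approximation, linear in
molecular mass (constant specific volume and refractive index of proteins),
so mass photometry reduces to: histogram the per-spot intensities of each
calibrant, extract component means with a Gaussian mixture, fit the linear
intensity-mass law, and invert it for unknown analytes.  A power-law fit on
log-log axes serves the nanoparticle size-scaling analysis (interference
d^3 vs pure scattering d^6).

Mixtures are fitted on the raw values by EM rather than by curve-fitting
binned histograms — the bin-free likelihood is better behaved at a few
hundred events; histograms (Freedman–Diaconis bins) are for display.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "IntensityHistogram",
    "MixtureFit",
    "CalibrationModel",
    "PowerLawFit",
    "make_histogram",
    "fit_mixture",
    "bic_scan",
    "fit_calibration",
    "estimate_mass",
    "fit_power_law",
]


@dataclass
class IntensityHistogram:
    values: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass
class MixtureFit:
    """Gaussian mixture of per-spot intensities, components sorted by mean."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    converged: bool
    seed: int
    bic: float = np.nan

    @property
    def primary_mean(self) -> float:
        """Mean of the heaviest component (the single-molecule peak)."""
        return float(self.means[int(np.argmax(self.weights))])

    def dimer_components(self, tol: float = 0.25) -> List[int]:
        """Indices of components near 2x the primary mean.

        These are protein dimers or two molecules closer than the
        diffraction limit; they are reported but excluded from calibration.
        """
        mu = self.primary_mean
        return [i for i, m in enumerate(self.means)
                if m != mu and abs(m / mu - 2.0) < tol]


@dataclass
class CalibrationModel:
    """Linear intensity = slope * mass + intercept law with accuracy metrics.

    ``residuals_kda`` are per-calibrant (measured - sequence) masses via the
    fitted line; ``average_error_pct`` is the mean relative deviation and
    ``mass_accuracy_kda`` the largest absolute deviation.
    """

    slope: float                  # intensity per kDa
    intercept: float
    masses: np.ndarray            # calibrant sequence masses, kDa
    intensities: np.ndarray       # calibrant mean intensities
    residuals_kda: np.ndarray
    residuals_pct: np.ndarray
    average_error_pct: float
    mass_accuracy_kda: float
    r_squared: float

    def to_json(self, path) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "calibrants": [
                {"mass_kda": float(m), "intensity": float(i)}
                for m, i in zip(self.masses, self.intensities)
            ],
            "average_error_pct": self.average_error_pct,
            "mass_accuracy_kda": self.mass_accuracy_kda,
            "r_squared": self.r_squared,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        masses = np.array([c["mass_kda"] for c in d["calibrants"]])
        intensities = np.array([c["intensity"] for c in d["calibrants"]])
        return fit_calibration(intensities, masses)


@dataclass
class PowerLawFit:
    exponent: float
    prefactor: float
    r_squared: float


def make_histogram(values: Sequence[float]) -> IntensityHistogram:
    """Freedman–Diaconis histogram of raw intensities (display only)."""
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins="fd")
    return IntensityHistogram(values, edges, counts)


def fit_mixture(values: Sequence[float], k: int, seed: int = 0) -> MixtureFit:
    """Maximum-likelihood Gaussian mixture on raw values.

    EM with k-means initialization from the given seed; components are
    reported sorted by mean.  Requires at least 10k values.
    """
    values = np.asarray(values, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(values) < 10 * k:
        raise ValueError(f"need at least {10 * k} values for k={k}")
    if np.ptp(values) == 0:
        raise ValueError("all values identical: mixture variance degenerate")
    gm = GaussianMixture(n_components=k, covariance_type="full",
                         init_params="kmeans", n_init=3, random_state=seed,
                         max_iter=500)
    gm.fit(values.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    ll = float(gm.score(values.reshape(-1, 1)) * len(values))
    return MixtureFit(k=k, means=means, sds=sds, weights=weights,
                      log_likelihood=ll, converged=bool(gm.converged_),
                      seed=seed, bic=float(gm.bic(values.reshape(-1, 1))))


def bic_scan(values: Sequence[float], k_max: int = 5,
             seed: int = 0) -> List[MixtureFit]:
    """Mixture fits for k = 1..k_max with BIC, lowest BIC first is best."""
    values = np.asarray(values, dtype=float)
    fits = []
    for k in range(1, k_max + 1):
        if len(values) < 10 * k:
            break
        fits.append(fit_mixture(values, k, seed=seed))
    return fits


def fit_calibration(intensities: Sequence[float],
                    masses: Sequence[float]) -> CalibrationModel:
    """Ordinary least-squares intensity vs mass line with accuracy metrics.

    The intercept is left free (not forced through zero) and reported.
    Residuals are re-expressed in kDa through the fitted slope:
    measured mass = (intensity - intercept)/slope.
    """
    intensities = np.asarray(intensities, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if len(masses) < 2 or len(intensities) != len(masses):
        raise ValueError("need >= 2 (mass, intensity) pairs of equal length")
    if len(np.unique(masses)) < 2:
        raise ValueError("masses must be distinct")
    res = stats.linregress(masses, intensities)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    measured = (intensities - intercept) / slope
    residuals_kda = measured - masses
    residuals_pct = residuals_kda / masses * 100.0
    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        masses=masses,
        intensities=intensities,
        residuals_kda=residuals_kda,
        residuals_pct=residuals_pct,
        average_error_pct=float(np.mean(np.abs(residuals_pct))),
        mass_accuracy_kda=float(np.max(np.abs(residuals_kda))),
        r_squared=float(res.rvalue**2),
    )


def estimate_mass(intensity: float, calibration: CalibrationModel) -> float:
    """Invert the calibration line: mass = (intensity - intercept)/slope.

    A non-positive estimate signals an intensity below the calibration
    range and raises.
    """
    if calibration.slope <= 0:
        raise ValueError("calibration slope must be > 0")
    mass = (intensity - calibration.intercept) / calibration.slope
    if mass <= 0:
        raise ValueError(f"non-physical mass estimate {mass:.3g} kDa")
    return float(mass)


def fit_power_law(diameters: Sequence[float],
                  intensities: Sequence[float]) -> PowerLawFit:
    """Least-squares slope of log intensity on log diameter."""
    d = np.asarray(diameters, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(d) < 2 or len(d) != len(y):
        raise ValueError("need >= 2 (diameter, intensity) pairs")
    if np.any(d <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive values on both axes")
    res = stats.linregress(np.log(d), np.log(y))
    return PowerLawFit(exponent=float(res.slope),
                       prefactor=float(math.exp(res.intercept)),
                       r_squared=float(res.rvalue**2))
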