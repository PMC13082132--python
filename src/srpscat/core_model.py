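"""Analytic forward model of the SRPSCAT signal.

SRPSCAT (stimulated Raman photothermal encoded scattering) detects a
particle's interferometric scattering (iSCAT) contrast and modulates it by
stimulated-Raman photothermal heating: pump and Stokes beams deposit
vibrational energy ``h(omega_p - omega_s)`` into the particle, the
nonradiative decay of which raises its temperature by ``dT``, which in turn
changes its refractive index (``dn``) and radius (``dr``) and therefore its
scattering contrast.  The relative contrast change at the modulation
frequency is the SRPSCAT modulation depth.

The model here is deliberately analytic and steady-state:

* the particle is a Rayleigh sphere — polarizability from the
  Clausius–Mossotti factor, scattered field ``|s| ~ k^2 * alpha / w`` with
  ``w`` the focal waist;
* iSCAT contrast is ``2(|s|/|r|) cos(phi) + (|s|/|r|)^2`` against the
  reference field reflected at the substrate interface with amplitude
  coefficient ``|r|``;
* heating uses the steady-state point-source solution
  ``dT = P_abs / (4 pi kappa a)`` evaluated at the particle surface, with
  the absorbed power lumped into a per-species coefficient (W absorbed per
  W^2 of pump x Stokes power product at band center).

Units: wavenumbers cm^-1, lengths nm, powers W, temperatures K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "OpticalConfig",
    "ParticleModel",
    "MediumModel",
    "SignalPrediction",
    "polarizability",
    "iscat_contrast",
    "absorbed_power",
    "srp_temperature_rise",
    "modulation_depths",
    "igm_like_particle",
    "water_medium",
    "default_optics",
]

_NM_TO_M = 1e-9


class InvalidParameterError(ValueError):
    """Raised when a physical parameter violates its validity domain."""


class UndefinedModulationError(ZeroDivisionError):
    """Raised when a modulation depth is requested for zero baseline contrast."""


@dataclass(frozen=True)
class OpticalConfig:
    """Excitation/detection geometry and powers.

    ``field_reflection_coefficient`` is the amplitude reflection |r| of the
    substrate interface supplying the iSCAT reference field.  ``cos_phi``
    sets the interference phase convention; the default +1 (constructive
    detection) reproduces the positive d^3 intensity law seen for
    polystyrene beads.
    """

    pump_wavenumber: float = 9384.0   # cm^-1 (~1065 nm)
    stokes_wavenumber: float = 6329.0  # cm^-1 (~1580 nm); shift ~3055 cm^-1
    probe_wavelength: float = 780.0    # nm
    numerical_aperture: float = 1.3
    pump_power: float = 20e-3          # W
    stokes_power: float = 10e-3        # W
    probe_power: float = 1e-3          # W
    modulation_frequency: float = 1e6  # Hz
    field_reflection_coefficient: float = 0.122  # glass(n=1.7)/water
    substrate_refractive_index: float = 1.7
    cos_phi: float = 1.0

    def __post_init__(self) -> None:
        if not self.pump_wavenumber > self.stokes_wavenumber > 0:
            raise InvalidParameterError(
                "require pump_wavenumber > stokes_wavenumber > 0 "
                "(positive Raman shift)"
            )
        if self.numerical_aperture <= 0:
            raise InvalidParameterError("numerical_aperture must be > 0")
        for name in ("pump_power", "stokes_power", "probe_power"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0 < self.field_reflection_coefficient <= 1:
            raise InvalidParameterError("field_reflection_coefficient in (0, 1]")
        if not -1.0 <= self.cos_phi <= 1.0:
            raise InvalidParameterError("cos_phi must lie in [-1, 1]")

    @property
    def raman_shift(self) -> float:
        """Raman shift omega_p - omega_s in cm^-1."""
        return self.pump_wavenumber - self.stokes_wavenumber

    @property
    def focal_waist(self) -> float:
        """Diffraction-limited focal radius 0.61 lambda / NA in nm."""
        return 0.61 * self.probe_wavelength / self.numerical_aperture


@dataclass(frozen=True)
class ParticleModel:
    """A Rayleigh scatterer with a lumped vibrational absorption coefficient.

    ``absorbed_power_coefficient`` is a species property: watts absorbed per
    W^2 of pump x Stokes power product when driven at band center.  It lumps
    the Raman cross-section, focal intensities and vibrational relaxation
    into one number.
    """

    diameter: float                     # nm
    refractive_index: float
    thermo_optic_coefficient: float = -1.0e-4    # dn/dT, K^-1
    thermal_expansion_coefficient: float = 2.0e-4  # linear, K^-1
    raman_band_center: float = 2930.0   # cm^-1
    absorbed_power_coefficient: float = 1.0e-5   # W per W^2
    mass: Optional[float] = None        # kDa

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidParameterError("diameter must be > 0")
        if self.refractive_index <= 0:
            raise InvalidParameterError("refractive_index must be > 0")
        if self.mass is not None and self.mass <= 0:
            raise InvalidParameterError("mass must be > 0 when given")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class MediumModel:
    """Host medium around the particle."""

    refractive_index: float = 1.33
    thermal_conductivity: float = 0.6   # W m^-1 K^-1 (water)
    thermo_optic_coefficient: float = -1.0e-4  # K^-1

    def __post_init__(self) -> None:
        if self.refractive_index < 1:
            raise InvalidParameterError("medium refractive_index must be >= 1")
        if self.thermal_conductivity <= 0:
            raise InvalidParameterError("thermal_conductivity must be > 0")


@dataclass(frozen=True)
class SignalPrediction:
    """Forward-model outputs; contrasts are dimensionless."""

    interference_term: float
    scattering_term: float
    total_contrast: float
    delta_T: float = 0.0        # K
    delta_n: float = 0.0
    delta_r: float = 0.0        # nm
    srpscat_modulation_depth: float = 0.0
    srs_modulation_depth: float = 0.0


def polarizability(d: float, n_p: float, n_m: float) -> float:
    """Polarizability volume a^3 (m^2-1)/(m^2+2) in nm^3, a = d/2, m = n_p/n_m.

    Negative for particles optically rarer than the medium.
    """
    if d <= 0:
        raise InvalidParameterError("diameter must be > 0")
    if n_p <= 0 or n_m <= 0:
        raise InvalidParameterError("refractive indices must be > 0")
    m = n_p / n_m
    denom = m * m + 2.0
    if denom == 0:  # pragma: no cover - unreachable for real positive m
        raise InvalidParameterError("degenerate Clausius-Mossotti denominator")
    a = d / 2.0
    return a**3 * (m * m - 1.0) / denom


def _field_ratio(particle: ParticleModel, medium: MediumModel,
                 optics: OpticalConfig) -> float:
    """|s|/|r|: scattered-to-reference field amplitude ratio."""
    if optics.field_reflection_coefficient == 0:
        raise ZeroDivisionError("no reference field (|r| = 0)")
    alpha = polarizability(particle.diameter, particle.refractive_index,
                           medium.refractive_index)
    k = 2.0 * math.pi / optics.probe_wavelength  # nm^-1
    s = k * k * abs(alpha) / optics.focal_waist  # dimensionless
    return s / optics.field_reflection_coefficient


def iscat_contrast(particle: ParticleModel, medium: MediumModel,
                   optics: OpticalConfig) -> SignalPrediction:
    """Interferometric scattering contrast split into its two terms.

    interference = 2 (|s|/|r|) cos(phi), scattering = (|s|/|r|)^2.  The
    interference term scales as d^3 (through the polarizability) and the
    pure scattering term as d^6.
    """
    ratio = _field_ratio(particle, medium, optics)
    interference = 2.0 * ratio * optics.cos_phi
    scattering = ratio * ratio
    return SignalPrediction(
        interference_term=interference,
        scattering_term=scattering,
        total_contrast=interference + scattering,
    )


def absorbed_power(particle: ParticleModel, optics: OpticalConfig) -> float:
    """Absorbed power in W from the lumped per-species coefficient."""
    return (particle.absorbed_power_coefficient
            * optics.pump_power * optics.stokes_power)


def srp_temperature_rise(absorbed_power: float, particle_radius: float,
                         medium: MediumModel) -> float:
    """Steady-state surface temperature rise dT = P_abs / (4 pi kappa a), K.

    Point-source conduction into an infinite medium; valid when the
    modulation period is long compared with the nanoparticle thermal time
    constant (nanoseconds at these sizes), which holds at MHz modulation.
    """
    if absorbed_power < 0:
        raise InvalidParameterError("absorbed power must be >= 0")
    if particle_radius <= 0:
        raise InvalidParameterError("particle radius must be > 0")
    a_m = particle_radius * _NM_TO_M
    return absorbed_power / (4.0 * math.pi * medium.thermal_conductivity * a_m)


def modulation_depths(particle: ParticleModel, medium: MediumModel,
                      optics: OpticalConfig) -> SignalPrediction:
    """Full signal prediction including SRPSCAT and SRS modulation depths.

    The SRPSCAT depth is the relative change of the iSCAT contrast between
    the cold particle and the heated particle (index n_p + dn, diameter
    d + 2 dr); the SRS depth is the relative pump intensity change
    P_abs / P_pump, an order-of-magnitude comparator for stimulated Raman
    loss.  Both are lock-in amplitudes at the modulation frequency.
    """
    base = iscat_contrast(particle, medium, optics)
    if base.total_contrast == 0:
        raise UndefinedModulationError(
            "baseline contrast is zero; modulation depth undefined")

    p_abs = absorbed_power(particle, optics)
    dT = srp_temperature_rise(p_abs, particle.radius, medium)
    dn = particle.thermo_optic_coefficient * dT
    dr = particle.radius * particle.thermal_expansion_coefficient * dT

    hot = ParticleModel(
        diameter=particle.diameter + 2.0 * dr,
        refractive_index=particle.refractive_index + dn,
        thermo_optic_coefficient=particle.thermo_optic_coefficient,
        thermal_expansion_coefficient=particle.thermal_expansion_coefficient,
        raman_band_center=particle.raman_band_center,
        absorbed_power_coefficient=particle.absorbed_power_coefficient,
        mass=particle.mass,
    )
    hot_contrast = iscat_contrast(hot, medium, optics).total_contrast
    srpscat_depth = abs(hot_contrast - base.total_contrast) / abs(base.total_contrast)

    srs_depth = 0.0
    if optics.pump_power > 0:
        srs_depth = p_abs / optics.pump_power

    return SignalPrediction(
        interference_term=base.interference_term,
        scattering_term=base.scattering_term,
        total_contrast=base.total_contrast,
        delta_T=dT,
        delta_n=dn,
        delta_r=dr,
        srpscat_modulation_depth=srpscat_depth,
        srs_modulation_depth=srs_depth,
    )


def igm_like_particle() -> ParticleModel:
    """A single IgM molecule (950 kDa) as an equivalent protein sphere.

    Volume from the standard protein specific volume (~1.21 A^3/Da) gives a
    ~13 nm equivalent diameter; protein refractive index 1.44.
    """
    return ParticleModel(
        diameter=13.0,
        refractive_index=1.44,
        raman_band_center=2939.0,
        mass=950.0,
    )


def water_medium() -> MediumModel:
    return MediumModel()


def default_optics() -> OpticalConfig:
    return OpticalConfig()
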