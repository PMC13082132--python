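"""Formats, run configuration and the pipeline driver.

Image stacks travel as multi-page 32-bit float TIFF (page order = spectral
band or time frame, ascending) with a CSV sidecar carrying the axis — one
row per page with ``page_index`` and either ``wavenumber_cm1`` or
``time_s`` — plus an optional constant ``pixel_size_nm`` column.  The axis
never lives in TIFF tags, avoiding metadata dialect ambiguity.  Tables are
comma-separated UTF-8 CSV with a mandatory header row; results are JSON.

Every pipeline run writes a machine-readable report naming the
configuration hash and seeds that produced it, so identical configurations
yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Any, Dict, List, Literal, Optional, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .stacks import HyperspectralStack, TimeLapseStack

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "load_config",
    "config_hash",
    "run_pipeline",
    "FormatError",
    "ConsistencyError",
]

SCHEMA_VERSION = 1
logger = logging.getLogger("srpscat")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[srpscat:%(stage)s] %(message)s"))


class FormatError(ValueError):
    """File does not conform to the expected on-disk format."""


class ConsistencyError(ValueError):
    """TIFF pages and sidecar rows disagree."""


# --------------------------------------------------------------------------
# stack I/O

def write_stack(stack: Union[HyperspectralStack, TimeLapseStack],
                tiff_path, sidecar_path) -> None:
    """Write a stack as float32 multi-page TIFF + CSV sidecar axis."""
    data = stack.data.astype(np.float32)
    pages = np.moveaxis(data, 2, 0)          # (n, y, x)
    tifffile.imwrite(str(tiff_path), pages)
    n = pages.shape[0]
    if isinstance(stack, HyperspectralStack):
        axis_col, axis = "wavenumber_cm1", stack.wavenumbers
    else:
        axis_col, axis = "time_s", stack.times
    pd.DataFrame({
        "page_index": np.arange(n),
        axis_col: axis,
        "pixel_size_nm": stack.pixel_size,
    }).to_csv(sidecar_path, index=False)


def read_stack(tiff_path, sidecar_path
               ) -> Union[HyperspectralStack, TimeLapseStack]:
    """Read a TIFF + sidecar pair; the axis column decides the stack type."""
    tiff_path, sidecar_path = Path(tiff_path), Path(sidecar_path)
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar: {sidecar_path}")
    pages = tifffile.imread(str(tiff_path))
    if pages.ndim == 2:
        pages = pages[None]
    sidecar = pd.read_csv(sidecar_path)
    if len(sidecar) != pages.shape[0]:
        raise ConsistencyError(
            f"{pages.shape[0]} TIFF pages but {len(sidecar)} sidecar rows")
    pixel_size = float(sidecar["pixel_size_nm"].iloc[0]) \
        if "pixel_size_nm" in sidecar.columns else 100.0
    data = np.moveaxis(pages, 0, 2)
    if "wavenumber_cm1" in sidecar.columns:
        return HyperspectralStack(data, sidecar["wavenumber_cm1"].to_numpy(),
                                  pixel_size)
    if "time_s" in sidecar.columns:
        times = sidecar["time_s"].to_numpy(dtype=float)
        dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
        return TimeLapseStack(data, dt, pixel_size)
    raise FormatError("sidecar must have a wavenumber_cm1 or time_s column")


# --------------------------------------------------------------------------
# configuration schema

class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhysicsParticle(_Section):
    diameter: float = 13.0
    refractive_index: float = 1.44
    thermo_optic_coefficient: float = -1.0e-4
    thermal_expansion_coefficient: float = 2.0e-4
    raman_band_center: float = 2930.0
    absorbed_power_coefficient: float = 1.0e-5
    mass: Optional[float] = None


class PhysicsMedium(_Section):
    refractive_index: float = 1.33
    thermal_conductivity: float = 0.6
    thermo_optic_coefficient: float = -1.0e-4


class PhysicsOptics(_Section):
    pump_wavenumber: float = 9384.0
    stokes_wavenumber: float = 6329.0
    probe_wavelength: float = 780.0
    numerical_aperture: float = 1.3
    pump_power: float = 20e-3
    stokes_power: float = 10e-3
    probe_power: float = 1e-3
    modulation_frequency: float = 1e6
    field_reflection_coefficient: float = 0.122
    substrate_refractive_index: float = 1.7
    cos_phi: float = 1.0


class PhysicsConfig(_Section):
    particle: PhysicsParticle = PhysicsParticle()
    medium: PhysicsMedium = PhysicsMedium()
    optics: PhysicsOptics = PhysicsOptics()


class SceneConfig(_Section):
    shape: Tuple[int, int] = (64, 64)
    pixel_size: float = 100.0
    psf_fwhm: float = 230.0
    spots: List[Tuple[float, float, str]] = Field(default_factory=list)


class NoiseConfig(_Section):
    background: float = 0.0
    sd: float = 0.05


class AxisConfig(_Section):
    start: float = 2800.0
    stop: float = 3100.0
    step: float = 5.0

    def grid(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 1e-9, self.step)


class SimulateConfig(_Section):
    kind: Literal["hyperspectral", "landing", "calibration"] = "hyperspectral"
    seed: int = 0
    scene: SceneConfig = SceneConfig()
    noise: NoiseConfig = NoiseConfig()
    wavenumbers: AxisConfig = AxisConfig()
    # landing-movie parameters
    arrival_rate: float = 0.5
    species: str = "IgA"
    duration: float = 20.0
    dt: float = 0.03
    # calibration-set parameters
    masses: List[float] = Field(default_factory=lambda: [66.5, 80.0, 150.0, 160.0, 950.0])
    slope: float = 1.0
    cv: float = 0.10
    n_per_species: int = 500


class QuantifyConfig(_Section):
    stack_tiff: str = "stack.tiff"
    stack_sidecar: str = "stack_axis.csv"
    min_snr: float = 5.0
    band: Optional[float] = None    # cm^-1; None = band of max mean signal


class CalibrateConfig(_Section):
    intensity_csv: str = "calibration_set.csv"
    k: int = 1
    seed: int = 0


class UnmixConfig(_Section):
    stack_tiff: str = "stack.tiff"
    stack_sidecar: str = "stack_axis.csv"
    library_csv: str = "library.csv"
    lam: float = 0.0
    nonnegative: bool = True


class StructureConfig(_Section):
    spectrum_csv: str = "spectrum.csv"
    center_window: float = 5.0
    fwhm_min: float = 8.0
    fwhm_max: float = 40.0


class KineticsConfig(_Section):
    trace_csv: str = "trace.csv"
    concentration: float = 6.0e-9
    threshold: Optional[float] = None
    hysteresis: float = 0.0
    n_boot: int = 1000
    bootstrap_seed: int = 0
    step_gate: float = 3.0


class RunConfig(_Section):
    """Validated run configuration; unknown keys are rejected."""

    schema_version: int = SCHEMA_VERSION
    physics: PhysicsConfig = PhysicsConfig()
    simulate: SimulateConfig = SimulateConfig()
    quantify: QuantifyConfig = QuantifyConfig()
    calibrate: CalibrateConfig = CalibrateConfig()
    unmix: UnmixConfig = UnmixConfig()
    structure: StructureConfig = StructureConfig()
    kinetics: KineticsConfig = KineticsConfig()


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration and validate the schema."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise FormatError("config must be a mapping")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise FormatError(f"unsupported schema_version {version}; "
                          f"expected {SCHEMA_VERSION}")
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# pipeline stages

def _log(stage: str, msg: str) -> None:
    logging.getLogger("srpscat").info(msg, extra={"stage": stage})


def _report(out: Path, stage: str, config: RunConfig,
            payload: Dict[str, Any]) -> Dict[str, Any]:
    report = {
        "stage": stage,
        "config_hash": config_hash(config),
        "schema_version": config.schema_version,
        "versions": {"srpscat": __version__, "numpy": np.__version__},
        **payload,
    }
    (out / f"{stage}_report.json").write_text(json.dumps(report, indent=2,
                                                         sort_keys=True))
    return report


def _stage_simulate(config: RunConfig, out: Path) -> Dict[str, Any]:
    from . import synthetic_data as sd
    sim = config.simulate
    scene = sd.SceneSpec(shape=tuple(sim.scene.shape),
                         pixel_size=sim.scene.pixel_size,
                         spots=tuple(tuple(s) for s in sim.scene.spots),
                         psf_fwhm=sim.scene.psf_fwhm)
    noise = sd.NoiseSpec(background=sim.noise.background, sd=sim.noise.sd,
                         seed=sim.seed)
    library = sd.default_species_library()
    if sim.kind == "hyperspectral":
        stack, truth = sd.simulate_hyperspectral_stack(
            scene, library, noise, sim.wavenumbers.grid())
        write_stack(stack, out / "stack.tiff", out / "stack_axis.csv")
        truth.to_csv(out / "ground_truth.csv", index=False)
        return {"kind": sim.kind, "seed": sim.seed, "n_spots": len(truth),
                "outputs": ["stack.tiff", "stack_axis.csv", "ground_truth.csv"]}
    if sim.kind == "landing":
        movie, events = sd.simulate_landing_movie(
            sim.arrival_rate, library[sim.species], sim.duration, sim.dt,
            scene, noise)
        write_stack(movie, out / "movie.tiff", out / "movie_axis.csv")
        events.to_csv(out / "events.csv", index=False)
        return {"kind": sim.kind, "seed": sim.seed, "n_events": len(events),
                "outputs": ["movie.tiff", "movie_axis.csv", "events.csv"]}
    # calibration intensity set
    table, truth = sd.simulate_calibration_set(
        sim.masses, slope=sim.slope, cv=sim.cv,
        n_per_species=sim.n_per_species, seed=sim.seed)
    table.to_csv(out / "calibration_set.csv", index=False)
    return {"kind": sim.kind, "seed": sim.seed, "truth": truth,
            "outputs": ["calibration_set.csv"]}


def _stage_quantify(config: RunConfig, out: Path) -> Dict[str, Any]:
    from . import image_quant as iq
    q = config.quantify
    stack = read_stack(q.stack_tiff, q.stack_sidecar)
    if not isinstance(stack, HyperspectralStack):
        raise FormatError("quantify expects a hyperspectral stack")
    if q.band is None:
        band = int(np.argmax(stack.data.mean(axis=(0, 1))))
    else:
        band = stack.band_nearest(q.band)
    sigma_nm = config.simulate.scene.psf_fwhm * iq.FWHM_TO_SIGMA
    spots = iq.detect_spots(stack.band(band), min_snr=q.min_snr,
                            pixel_size=stack.pixel_size,
                            expected_sigma_nm=sigma_nm)
    rows = []
    spectra_rows = []
    for spot in spots:
        rows.append({"spot_id": spot.spot_id, "x_nm": spot.x_nm,
                     "y_nm": spot.y_nm, "amplitude": spot.amplitude,
                     "integrated_intensity": spot.integrated_intensity,
                     "background": spot.background, "sigma_nm": spot.sigma_nm,
                     "snr": spot.snr, "overlapped": spot.overlapped})
        try:
            spec = iq.extract_spectrum(stack, spot)
        except iq.PartialWindowError:
            continue
        for nu, inten in zip(spec.wavenumbers, spec.intensities):
            spectra_rows.append({"spot_id": spot.spot_id,
                                 "wavenumber_cm1": nu, "intensity": inten})
    pd.DataFrame(rows, columns=["spot_id", "x_nm", "y_nm", "amplitude",
                                "integrated_intensity", "background",
                                "sigma_nm", "snr", "overlapped"]
                 ).to_csv(out / "spots.csv", index=False)
    pd.DataFrame(spectra_rows, columns=["spot_id", "wavenumber_cm1",
                                        "intensity"]
                 ).to_csv(out / "spectra.csv", index=False)
    return {"n_spots": len(spots), "detection_band_cm1":
            float(stack.wavenumbers[band]),
            "outputs": ["spots.csv", "spectra.csv"]}


def _stage_calibrate(config: RunConfig, out: Path) -> Dict[str, Any]:
    from . import mass_calibration as mc
    c = config.calibrate
    table = pd.read_csv(c.intensity_csv)
    means, masses = [], []
    for mass, group in table.groupby("mass_kda"):
        fit = mc.fit_mixture(group["intensity"].to_numpy(), k=c.k, seed=c.seed)
        means.append(fit.primary_mean)
        masses.append(float(mass))
    cal = mc.fit_calibration(means, masses)
    cal.to_json(out / "calibration.json")
    return {"slope": cal.slope, "intercept": cal.intercept,
            "average_error_pct": cal.average_error_pct,
            "mass_accuracy_kda": cal.mass_accuracy_kda,
            "outputs": ["calibration.json"]}


def _stage_unmix(config: RunConfig, out: Path) -> Dict[str, Any]:
    from . import spectral_analysis as sa
    u = config.unmix
    stack = read_stack(u.stack_tiff, u.stack_sidecar)
    lib_table = pd.read_csv(u.library_csv)
    axis = lib_table["wavenumber_cm1"].to_numpy(dtype=float)
    refs = {c: lib_table[c].to_numpy(dtype=float)
            for c in lib_table.columns if c != "wavenumber_cm1"}
    library = sa.ReferenceLibrary(axis, refs)
    amap = sa.lasso_unmix(stack, library, lam=u.lam,
                          nonnegative=u.nonnegative)
    pages = np.stack([amap.coefficients[n] for n in library.names], axis=0)
    tifffile.imwrite(str(out / "abundance.tiff"), pages.astype(np.float32))
    summary = pd.DataFrame({
        "reference": library.names,
        "total_abundance": [float(amap.coefficients[n].sum())
                            for n in library.names],
    })
    summary.to_csv(out / "abundance_summary.csv", index=False)
    return {"lam": u.lam, "references": library.names,
            "outputs": ["abundance.tiff", "abundance_summary.csv"]}


def _stage_structure(config: RunConfig, out: Path) -> Dict[str, Any]:
    from . import spectral_analysis as sa
    s = config.structure
    table = pd.read_csv(s.spectrum_csv)
    decomp = sa.deconvolve_amide(
        table["wavenumber_cm1"].to_numpy(dtype=float),
        table["intensity"].to_numpy(dtype=float),
        center_window=s.center_window,
        fwhm_bounds=(s.fwhm_min, s.fwhm_max))
    payload = {
        "fractions_pct": decomp.fractions,
        "bands": {label: {"center_cm1": b.center, "fwhm_cm1": b.fwhm,
                          "area": b.area}
                  for label, b in decomp.bands.items()},
        "converged": decomp.converged,
    }
    (out / "structure.json").write_text(json.dumps(payload, indent=2,
                                                   sort_keys=True))
    return {**payload, "outputs": ["structure.json"]}


def _stage_kinetics(config: RunConfig, out: Path) -> Dict[str, Any]:
    from . import kinetics as kin
    from .stacks import IntensityTrace
    k = config.kinetics
    table = pd.read_csv(k.trace_csv)
    times = table["time_s"].to_numpy(dtype=float)
    dt = float(times[1] - times[0])
    trace = IntensityTrace(times, table["intensity"].to_numpy(dtype=float), dt)
    states = kin.idealize(trace, threshold=k.threshold,
                          hysteresis=k.hysteresis)
    dwellset = kin.dwells(states)
    result = kin.fit_rates(dwellset, k.concentration, n_boot=k.n_boot,
                           seed=k.bootstrap_seed)
    pd.DataFrame({
        "dwell_s": np.concatenate([dwellset.bound, dwellset.unbound]),
        "state": ["bound"] * len(dwellset.bound)
        + ["unbound"] * len(dwellset.unbound),
        "censored": np.concatenate([dwellset.bound_censored,
                                    dwellset.unbound_censored]),
    }).to_csv(out / "dwells.csv", index=False)
    payload = {
        "k_on_per_M_per_s": result.k_on,
        "k_off_per_s": result.k_off,
        "K_D_M": result.K_D,
        "concentration_M": result.concentration,
        "k_on_ci": list(result.k_on_ci),
        "k_off_ci": list(result.k_off_ci),
        "n_bound": result.n_bound,
        "n_unbound": result.n_unbound,
    }
    (out / "kinetics.json").write_text(json.dumps(payload, indent=2,
                                                  sort_keys=True))
    return {**payload, "outputs": ["dwells.csv", "kinetics.json"]}


_STAGES = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "calibrate": _stage_calibrate,
    "unmix": _stage_unmix,
    "structure": _stage_structure,
    "kinetics": _stage_kinetics,
}


def run_pipeline(config: RunConfig, subcommand: str, out_dir,
                 seed: Optional[int] = None) -> Dict[str, Any]:
    """Run one pipeline stage; write its artifacts and a JSON report.

    ``seed`` overrides the stage's configured seed.  Identical
    configuration and seed give byte-identical outputs.
    """
    if subcommand not in _STAGES:
        raise ValueError(f"unknown subcommand {subcommand!r}; "
                         f"choose from {sorted(_STAGES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = config.model_copy(deep=True)
        config.simulate.seed = seed
        config.calibrate.seed = seed
        config.kinetics.bootstrap_seed = seed
    _log(subcommand, f"running with config hash {config_hash(config)}")
    try:
        payload = _STAGES[subcommand](config, out)
    except Exception as exc:
        raise type(exc)(f"[stage {subcommand}] {exc}") from exc
    return _report(out, subcommand, config, payload)
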