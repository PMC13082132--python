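"""Spot detection, Gaussian fitting, spectrum/trace extraction, denoising."""

import numpy as np
import pytest

from srpscat import image_quant as iq
from srpscat import synthetic_data as sd
from srpscat.stacks import HyperspectralStack, TimeLapseStack

PIX = 100.0
SIGMA = 230.0 * iq.FWHM_TO_SIGMA


def _single_spot_image(shape=(32, 32), x=1600.0, y=1600.0, amp=10.0,
                       bkg=0.0, noise_sd=0.0, seed=0):
    scene = sd.SceneSpec(shape=shape, pixel_size=PIX,
                         spots=((x, y, "IgM"),), psf_fwhm=230.0)
    lib = {"IgM": sd.SpeciesSpec("IgM", ((2939.0, 50.0, 1.0, 0.5),),
                                 contrast_per_kda=amp / 950.0, mass=950.0)}
    stack, _ = sd.simulate_hyperspectral_stack(
        scene, lib, sd.NoiseSpec(background=bkg, sd=noise_sd, seed=seed),
        np.array([2939.0]))
    return stack.band(0)


class TestFitSpot:
    def test_noiseless_parameters_recovered_exactly(self):
        img = _single_spot_image(amp=7.5, bkg=2.0)
        rec = iq.fit_spot(img, (1600.0, 1600.0), pixel_size=PIX)
        assert rec.converged
        assert rec.amplitude == pytest.approx(7.5, rel=1e-6)
        assert rec.x_nm == pytest.approx(1600.0, abs=1e-3)
        assert rec.y_nm == pytest.approx(1600.0, abs=1e-3)
        assert rec.sigma_nm == pytest.approx(SIGMA, rel=1e-6)
        assert rec.background == pytest.approx(2.0, abs=1e-6)

    def test_amplitude_linearity(self):
        img = _single_spot_image(amp=4.0)
        r1 = iq.fit_spot(img, (1600.0, 1600.0), pixel_size=PIX)
        r2 = iq.fit_spot(3.0 * img, (1600.0, 1600.0), pixel_size=PIX)
        assert r2.amplitude == pytest.approx(3.0 * r1.amplitude, rel=1e-6)

    def test_constant_offset_absorbed_by_background(self):
        img = _single_spot_image(amp=4.0)
        r1 = iq.fit_spot(img, (1600.0, 1600.0), pixel_size=PIX)
        r2 = iq.fit_spot(img + 5.0, (1600.0, 1600.0), pixel_size=PIX)
        assert r2.amplitude == pytest.approx(r1.amplitude, rel=1e-6)
        assert r2.background == pytest.approx(r1.background + 5.0, abs=1e-6)

    def test_integrated_intensity_definition(self):
        img = _single_spot_image(amp=6.0)
        rec = iq.fit_spot(img, (1600.0, 1600.0), pixel_size=PIX)
        assert rec.integrated_intensity == pytest.approx(
            2 * np.pi * rec.amplitude * rec.sigma_nm**2, rel=1e-12)

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError):
            iq.fit_spot(np.zeros((5, 5)), (200.0, 200.0), pixel_size=PIX)

    def test_amplitude_unbiased_at_snr10(self):
        """Mean fitted amplitude within 2% of truth over 200 noisy spots."""
        amps = []
        for seed in range(200):
            img = _single_spot_image(amp=10.0, noise_sd=1.0, seed=seed)
            rec = iq.fit_spot(img, (1600.0, 1600.0), pixel_size=PIX)
            if rec.converged:
                amps.append(rec.amplitude)
        assert abs(np.mean(amps) - 10.0) / 10.0 < 0.02


class TestDetectSpots:
    def test_blank_noise_image_yields_nothing(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            img = rng.normal(0.0, 1.0, (64, 64))
            assert iq.detect_spots(img, min_snr=5.0, pixel_size=PIX) == []

    def test_five_planted_spots_all_found(self):
        positions = [(800, 800), (800, 2400), (2400, 800), (2400, 2400),
                     (1600, 1600)]
        scene = sd.SceneSpec(shape=(32, 32), pixel_size=PIX,
                             spots=tuple((x, y, "IgM") for x, y in positions),
                             psf_fwhm=230.0)
        lib = sd.default_species_library()
        stack, _ = sd.simulate_hyperspectral_stack(
            scene, lib, sd.NoiseSpec(sd=0.95, seed=4), np.array([2939.0]))
        spots = iq.detect_spots(stack.band(0), min_snr=5.0, pixel_size=PIX)
        assert len(spots) == 5
        found = {(round(s.x_nm / PIX) * PIX, round(s.y_nm / PIX) * PIX)
                 for s in spots}
        for x, y in positions:
            assert any(abs(fx - x) <= PIX and abs(fy - y) <= PIX
                       for fx, fy in found)

    def test_unresolved_pair_single_flagged_detection(self):
        """Two spots 0.4 FWHM apart merge into one overlapped detection."""
        sep = 0.4 * 230.0
        scene = sd.SceneSpec(shape=(32, 32), pixel_size=PIX,
                             spots=((1600.0, 1600.0, "IgM"),
                                    (1600.0 + sep, 1600.0, "IgM")),
                             psf_fwhm=230.0)
        stack, _ = sd.simulate_hyperspectral_stack(
            scene, sd.default_species_library(), sd.NoiseSpec(sd=0.0),
            np.array([2939.0]))
        spots = iq.detect_spots(stack.band(0), min_snr=5.0, pixel_size=PIX)
        assert len(spots) == 1
        assert spots[0].overlapped

    def test_translation_equivariance(self):
        img = _single_spot_image(shape=(40, 40), x=1500.0, y=1700.0, amp=10.0)
        shifted = np.roll(np.roll(img, 3, axis=0), 5, axis=1)
        r0 = iq.detect_spots(img, min_snr=5.0, pixel_size=PIX)[0]
        r1 = iq.detect_spots(shifted, min_snr=5.0, pixel_size=PIX)[0]
        assert r1.x_nm - r0.x_nm == pytest.approx(5 * PIX, abs=1e-3)
        assert r1.y_nm - r0.y_nm == pytest.approx(3 * PIX, abs=1e-3)


class TestExtractSpectrum:
    @pytest.mark.parametrize("species,peak", [("PS", 3055.0), ("IgM", 2939.0)])
    def test_argmax_at_species_band(self, species, peak, species_library, ch_axis):
        scene = sd.SceneSpec(shape=(32, 32), pixel_size=PIX,
                             spots=((1600.0, 1600.0, species),), psf_fwhm=230.0)
        stack, _ = sd.simulate_hyperspectral_stack(
            scene, species_library, sd.NoiseSpec(sd=0.0), ch_axis)
        spot = iq.detect_spots(stack.band(stack.band_nearest(peak)),
                               min_snr=5.0, pixel_size=PIX)[0]
        spec = iq.extract_spectrum(stack, spot)
        on_grid = ch_axis[np.argmin(np.abs(ch_axis - peak))]
        assert spec.argmax_wavenumber() == pytest.approx(on_grid)

    def test_zero_stack_zero_spectrum(self, ch_axis):
        stack = HyperspectralStack(np.zeros((32, 32, len(ch_axis))), ch_axis, PIX)
        spot = iq.SpotRecord(0, 1600.0, 1600.0, 1.0, 1.0, 0.0, SIGMA, 10.0)
        spec = iq.extract_spectrum(stack, spot)
        assert np.allclose(spec.intensities, 0.0)

    def test_noiseless_spectrum_matches_species_shape(self, species_library, ch_axis):
        """Cosine similarity > 0.999 against the generating spectrum."""
        scene = sd.SceneSpec(shape=(32, 32), pixel_size=PIX,
                             spots=((1600.0, 1600.0, "IgM"),), psf_fwhm=230.0)
        stack, _ = sd.simulate_hyperspectral_stack(
            scene, species_library, sd.NoiseSpec(sd=0.0), ch_axis)
        spot = iq.fit_spot(stack.band(stack.band_nearest(2939.0)),
                           (1600.0, 1600.0), pixel_size=PIX)
        spec = iq.extract_spectrum(stack, spot)
        ref = species_library["IgM"].spectrum(ch_axis)
        cos = np.dot(spec.intensities, ref) / (
            np.linalg.norm(spec.intensities) * np.linalg.norm(ref))
        assert cos > 0.999

    def test_border_spot_raises_partial_window(self, ch_axis):
        stack = HyperspectralStack(np.zeros((32, 32, len(ch_axis))), ch_axis, PIX)
        spot = iq.SpotRecord(0, 100.0, 100.0, 1.0, 1.0, 0.0, SIGMA, 10.0)
        with pytest.raises(iq.PartialWindowError):
            iq.extract_spectrum(stack, spot)


class TestTrackSpotTrace:
    def test_constant_movie_constant_trace(self):
        img = _single_spot_image(amp=8.0)
        movie = TimeLapseStack(np.repeat(img[:, :, None], 10, axis=2), 0.1, PIX)
        trace = iq.track_spot_trace(movie, (1600.0, 1600.0))
        assert np.allclose(trace.intensities, trace.intensities[0])
        assert trace.intensities[0] == pytest.approx(8.0, rel=1e-3)

    def test_landing_step_at_event_frame(self, species_library):
        scene = sd.SceneSpec(shape=(24, 24), pixel_size=PIX, psf_fwhm=230.0)
        movie, events = sd.simulate_landing_movie(
            0.05, species_library["IgM"], 40.0, 1.0, scene,
            sd.NoiseSpec(sd=0.0, seed=12))
        assert len(events) >= 1
        ev = events.iloc[0]
        x = float(np.clip(ev.x_nm, 700, 1600))  # keep fit window inside
        trace = iq.track_spot_trace(movie, (ev.x_nm, ev.y_nm))
        k_true = int(np.ceil(ev.time_s / 1.0))
        step = np.flatnonzero(np.diff(trace.intensities) >
                              0.5 * events.amplitude.iloc[0])
        assert len(step) >= 1
        assert abs((step[0] + 1) - k_true) <= 1

    def test_two_state_trace_recovered_from_movie(self):
        """Tracked amplitude correlates > 0.95 with true levels at SNR 10."""
        p = sd.TwoStateParams(k_on=1e9, concentration=5e-9, k_off=2.0,
                              dt=0.05, duration=10.0, bound_level=10.0,
                              unbound_level=0.0, noise_sd=0.0)
        trace, _ = sd.simulate_two_state_trace(p, seed=21)
        ny = nx = 24
        rng = np.random.default_rng(0)
        frames = np.empty((ny, nx, len(trace)))
        yy, xx = np.mgrid[0:ny, 0:nx]
        g = np.exp(-(((xx - 12) ** 2 + (yy - 12) ** 2) * PIX**2)
                   / (2 * SIGMA**2))
        for k, level in enumerate(trace.intensities):
            frames[:, :, k] = level * g + rng.normal(0, 1.0, (ny, nx))
        movie = TimeLapseStack(frames, p.dt, PIX)
        tracked = iq.track_spot_trace(movie, (1200.0, 1200.0))
        r = np.corrcoef(tracked.intensities, trace.intensities)[0, 1]
        assert r > 0.95


class TestDenoiseHook:
    def test_none_is_identity(self, ch_axis):
        stack = HyperspectralStack(
            np.random.default_rng(0).normal(size=(16, 16, len(ch_axis))),
            ch_axis, PIX)
        assert iq.denoise_hook(stack, "none") is stack

    def test_frame_average_1_is_identity(self, ch_axis):
        stack = HyperspectralStack(
            np.random.default_rng(0).normal(size=(16, 16, len(ch_axis))),
            ch_axis, PIX)
        assert iq.denoise_hook(stack, "frame_average", n=1) is stack

    def test_frame_average_sqrt_n_noise_reduction(self):
        rng = np.random.default_rng(3)
        movie = TimeLapseStack(rng.normal(0, 1, (32, 32, 400)), 0.1, PIX)
        out = iq.denoise_hook(movie, "frame_average", n=4)
        interior = out.data[:, :, 10:-10]
        assert np.std(interior) == pytest.approx(0.5, rel=0.05)

    def test_unknown_method_raises(self, ch_axis):
        stack = HyperspectralStack(np.zeros((16, 16, len(ch_axis))), ch_axis, PIX)
        with pytest.raises(ValueError):
            iq.denoise_hook(stack, "wavelet")
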