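"""Trace idealization, dwell bookkeeping, rate fitting, step detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srpscat import kinetics as kin
from srpscat import synthetic_data as sd
from srpscat.stacks import IntensityTrace


def _trace(values, dt=0.01):
    values = np.asarray(values, dtype=float)
    return IntensityTrace(np.arange(len(values)) * dt, values, dt)


def _dwellset(bound, unbound, dt=0.01):
    return kin.DwellSet(np.asarray(bound, float), np.asarray(unbound, float),
                        np.zeros(len(bound), bool), np.zeros(len(unbound), bool),
                        dt)


class TestIdealize:
    def test_constant_low_trace_all_unbound(self):
        states = kin.idealize(_trace(np.zeros(50)), threshold=5.0)
        assert np.all(states.states == kin.UNBOUND)

    def test_noiseless_square_wave_exact(self):
        levels = np.tile([0.0] * 10 + [10.0] * 10, 5)
        states = kin.idealize(_trace(levels))  # auto-threshold
        assert np.array_equal(states.states, (levels > 5).astype(int))

    def test_noisy_trace_low_misclassification(self):
        """Frame misclassification < 5% at SNR 5 with 1-sd hysteresis."""
        p = sd.TwoStateParams(k_on=1e9, concentration=5e-9, k_off=2.0,
                              dt=0.01, duration=100.0, bound_level=10.0,
                              unbound_level=0.0, noise_sd=2.0)
        trace, _ = sd.simulate_two_state_trace(p, seed=8)
        truth_trace, _ = sd.simulate_two_state_trace(
            sd.TwoStateParams(**{**p.__dict__, "noise_sd": 1e-12}), seed=8)
        truth = (truth_trace.intensities > 5.0).astype(int)
        states = kin.idealize(trace, threshold=5.0, hysteresis=2.0)
        assert np.mean(states.states != truth) < 0.05

    def test_unimodal_trace_auto_threshold_fails(self):
        rng = np.random.default_rng(0)
        with pytest.raises(kin.CannotThresholdError):
            kin.idealize(_trace(rng.normal(5.0, 1.0, 200)))


class TestDwells:
    def test_alternating_frames_all_single_dt(self):
        states = kin.StateSequence(np.tile([0, 1], 20), 0.01, 0.5)
        ds = kin.dwells(states)
        inner_bound = ds.bound[~ds.bound_censored]
        inner_unbound = ds.unbound[~ds.unbound_censored]
        assert np.all(inner_bound == pytest.approx(0.01))
        assert np.all(inner_unbound == pytest.approx(0.01))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_duration_conservation_exact(self, seed):
        """Sum of all dwells (censored included) equals n_frames * dt."""
        rng = np.random.default_rng(seed)
        s = kin.StateSequence(rng.integers(0, 2, 500), 0.03, 0.5)
        ds = kin.dwells(s)
        assert ds.total_time == pytest.approx(500 * 0.03, rel=1e-12)

    @given(seq=st.lists(st.integers(0, 1), min_size=2, max_size=300))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_duration_conservation_property(self, seq):
        """Bookkeeping identity on arbitrary state sequences."""
        ds = kin.dwells(kin.StateSequence(np.array(seq), 0.01, 0.5))
        assert ds.total_time == pytest.approx(len(seq) * 0.01, rel=1e-12)

    def test_transition_count_matches_simulator(self):
        p = sd.TwoStateParams(k_on=1e9, concentration=5e-9, k_off=2.0,
                              dt=0.002, duration=50.0, bound_level=10.0,
                              unbound_level=0.0, noise_sd=1e-9)
        trace, true_dwells = sd.simulate_two_state_trace(p, seed=14)
        ds = kin.dwells(kin.idealize(trace, threshold=5.0))
        n_true = len(true_dwells.bound) + len(true_dwells.unbound)
        n_obs = len(ds.bound) + len(ds.unbound)
        # sub-frame dwells are unobservable; allow a small deficit
        assert abs(n_obs - n_true) <= 0.1 * n_true + 2


class TestFitRates:
    def test_equal_bound_dwells_exact_koff(self):
        ds = _dwellset([2.0] * 20, [1.0] * 20)
        res = kin.fit_rates(ds, concentration=1e-9, n_boot=0)
        assert res.k_off == pytest.approx(0.5, rel=1e-12)

    def test_kd_is_ratio_to_machine_precision(self):
        rng = np.random.default_rng(1)
        ds = _dwellset(rng.exponential(0.2, 100), rng.exponential(0.5, 100))
        res = kin.fit_rates(ds, concentration=5e-9, n_boot=0)
        assert res.K_D == res.k_off / res.k_on

    def test_molecule3_rates_recovered(self):
        """10,000 exponential dwells at k_off=7.8, k_on=1.3e9 M^-1 s^-1."""
        k_off, k_on, conc = 7.8, 1.3e9, 10e-9
        rng = np.random.default_rng(2)
        n = 10_000
        ds = _dwellset(rng.exponential(1 / k_off, n),
                       rng.exponential(1 / (k_on * conc), n))
        res = kin.fit_rates(ds, concentration=conc, n_boot=200, seed=0)
        assert abs(res.k_off - k_off) < 3 * k_off / np.sqrt(n)
        assert abs(res.k_on - k_on) < 3 * k_on / np.sqrt(n)
        # bootstrap interval brackets the estimate with ~4 SE width
        assert res.k_off_ci[0] < res.k_off < res.k_off_ci[1]
        assert res.k_off_ci[1] - res.k_off_ci[0] < 6 * k_off / np.sqrt(n)

    def test_histogram_mode_agrees_roughly(self):
        rng = np.random.default_rng(3)
        ds = _dwellset(rng.exponential(0.2, 5000), rng.exponential(0.4, 5000))
        mle = kin.fit_rates(ds, concentration=1e-8, n_boot=0)
        hist = kin.fit_rates_histogram(ds, concentration=1e-8)
        assert hist.k_off == pytest.approx(mle.k_off, rel=0.15)

    def test_insufficient_dwells_raise(self):
        ds = _dwellset([0.1] * 3, [0.2] * 3)
        with pytest.raises(kin.InsufficientDataError):
            kin.fit_rates(ds, concentration=1e-9)

    def test_consistency_bias_vanishes_at_large_n(self):
        """k_off bias < 1% at n = 1e5 exponential dwells."""
        rng = np.random.default_rng(4)
        n = 100_000
        ds = _dwellset(rng.exponential(1 / 7.8, n), rng.exponential(0.1, n))
        res = kin.fit_rates(ds, concentration=1e-8, n_boot=0)
        assert abs(res.k_off - 7.8) / 7.8 < 0.01

    @staticmethod
    def _windowed_dwellset(k_off: float, window_over_mean: float,
                           n_traces: int, seed: int,
                           flag_first: bool = True) -> kin.DwellSet:
        """Bound dwells collected from fixed observation windows.

        The dwell straddling the window end is truncated and flagged
        censored, as `dwells` does for real traces.
        """
        rng = np.random.default_rng(seed)
        mean = 1 / k_off
        window = window_over_mean * mean
        dwell_list, flags = [], []
        for _ in range(n_traces):
            t = 0.0
            first = True
            while t < window:
                d = rng.exponential(mean)
                if t + d > window:
                    dwell_list.append(window - t)
                    flags.append(True)
                else:
                    dwell_list.append(d)
                    flags.append(first and flag_first)
                t += d
                first = False
        dwell_arr = np.array(dwell_list)
        flag_arr = np.array(flags)
        unbound = rng.exponential(mean, len(dwell_arr))
        return kin.DwellSet(dwell_arr, unbound, flag_arr,
                            np.zeros(len(unbound), bool), 0.001)

    def test_window_truncation_biases_rates_upward(self):
        """Dwells observed in short windows overestimate rates.

        Only complete dwells are kept, and dwells that complete inside a
        short window are a length-biased (short) sample, so the fitted rate
        exceeds the truth when the window is only ~10 mean dwells long; the
        bias falls below 3 SE once the window is ~100 mean dwells.
        """
        k_off = 10.0
        short = self._windowed_dwellset(k_off, 10.0, n_traces=1200, seed=5)
        n_short = len(short.uncensored_bound())
        r_short = kin.fit_rates(short, concentration=1e-9, n_boot=0)
        assert r_short.k_off > k_off + 3 * k_off / np.sqrt(n_short)

        long = self._windowed_dwellset(k_off, 100.0, n_traces=100, seed=6)
        n_long = len(long.uncensored_bound())
        r_long = kin.fit_rates(long, concentration=1e-9, n_boot=0)
        assert abs(r_long.k_off - k_off) < 3 * k_off / np.sqrt(n_long)

    def test_truncated_dwell_inclusion_neutral_for_exponentials(self):
        """Memorylessness: the end-truncated dwell has the same mean as a
        full dwell, so including censored dwells barely moves the estimate
        (the choice matters for non-exponential kinetics, not here)."""
        ds = self._windowed_dwellset(10.0, 20.0, n_traces=500, seed=7,
                                     flag_first=False)
        # age of the in-progress interval at the window end ~ Exp(mean)
        cens = ds.bound[ds.bound_censored]
        assert cens.mean() == pytest.approx(0.1, rel=0.15)
        excl = kin.fit_rates(ds, concentration=1e-9, n_boot=0)
        incl = kin.fit_rates(ds, concentration=1e-9, n_boot=0,
                             include_censored=True)
        assert incl.k_off == pytest.approx(excl.k_off, rel=0.05)

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        b, u = rng.exponential(0.2, 200), rng.exponential(0.3, 200)
        c = 7.0
        r1 = kin.fit_rates(_dwellset(b, u), concentration=1e-9, n_boot=0)
        r2 = kin.fit_rates(_dwellset(c * b, c * u, dt=0.01 * c),
                           concentration=1e-9, n_boot=0)
        assert r2.k_off * c == pytest.approx(r1.k_off, rel=1e-12)
        assert r2.k_on * c == pytest.approx(r1.k_on, rel=1e-12)


class TestDetectStep:
    def test_constant_noisy_trace_rarely_flags(self):
        """False-positive rate < 5% at gate 3 over 1000 null traces."""
        hits = 0
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            trace = _trace(rng.normal(0.0, 1.0, 100))
            if kin.detect_step(trace) is not None:
                hits += 1
        assert hits / 1000 < 0.05

    def test_planted_step_localized_within_one_frame(self):
        """>= 95% of 200 noisy step traces localized to +-1 frame."""
        good = 0
        for seed in range(200):
            trace, truth = sd.simulate_step_trace(
                10.0, 20.0, 1.5, 3.0, 0.03, noise_sd=1.0, seed=seed)
            fit = kin.detect_step(trace)
            if fit is not None and abs(fit.change_frame - truth["step_frame"]) <= 1:
                good += 1
        assert good >= 190

    def test_matches_bruteforce_reimplementation(self):
        """Identical split index to an independent O(n^2) search, 50 traces."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = rng.normal(0, 1, 60)
            y[rng.integers(10, 50):] += rng.uniform(2, 8)
            trace = _trace(y)
            fit = kin.detect_step(trace, gate=0.0)
            best_k, best_rss = None, np.inf
            for k in range(2, len(y) - 1):
                rss = (np.sum((y[:k] - y[:k].mean()) ** 2)
                       + np.sum((y[k:] - y[k:].mean()) ** 2))
                if rss < best_rss:
                    best_k, best_rss = k, rss
            assert fit.change_frame == best_k

    def test_conformational_switch_amplitude_ratio(self):
        """Levels at the trimer/tetramer masses give ratio 317.0/142.2."""
        trace, _ = sd.simulate_step_trace(142.2, 317.0, 2.0, 4.0, 0.03,
                                          noise_sd=14.2, seed=9)
        fit = kin.detect_step(trace)
        assert fit is not None
        assert fit.direction == "up"
        assert fit.amplitude_ratio == pytest.approx(317.0 / 142.2, rel=0.05)

    def test_downward_step_detected_with_direction(self):
        y = np.concatenate([np.full(30, 10.0), np.full(30, 4.0)])
        fit = kin.detect_step(_trace(y + np.random.default_rng(0).normal(0, 0.3, 60)))
        assert fit.direction == "down"

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            kin.detect_step(_trace([1.0, 2.0, 3.0, 4.0]))
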