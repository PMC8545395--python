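"""Ripple-band preprocessing, ripple detection, multitaper coherence."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from condpipe import lfp as L
from condpipe.synthetic import LFPBlock

FS = 2000.0


def sine(freq, dur=2.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestPreprocess:
    def test_common_mode_removed(self):
        common = sine(200.0)
        block = LFPBlock(np.tile(common, (4, 1)), FS)
        filt = L.preprocess_ripple_band(block)
        assert np.abs(filt).max() < 1e-6

    def test_single_channel_component_preserved(self):
        data = np.zeros((4, int(2 * FS)))
        data[2] = sine(200.0, amp=100.0)
        filt = L.preprocess_ripple_band(LFPBlock(data, FS))
        mid = slice(int(0.5 * FS), int(1.5 * FS))
        # channel keeps (1 - 1/n) of its amplitude after CAR
        assert np.abs(filt[2, mid]).max() == pytest.approx(75.0, rel=0.05)

    def test_out_of_band_attenuation(self):
        data = np.zeros((2, int(4 * FS)))
        data[0] = sine(50.0, dur=4.0, amp=100.0)
        filt = L.preprocess_ripple_band(LFPBlock(data, FS))
        mid = slice(int(1 * FS), int(3 * FS))
        atten_db = 20 * np.log10(np.abs(filt[0, mid]).max() / 100.0)
        assert atten_db <= -40.0

    def test_low_fs_raises(self):
        with pytest.raises(ValueError, match="too low"):
            L.preprocess_ripple_band(LFPBlock(np.zeros((2, 1000)), 500.0))


class TestChannelSelection:
    def test_planted_depth_profile_peak_channel(self, lfp_session):
        spec, bundle, _ = lfp_session
        filt = L.preprocess_ripple_band(bundle.lfp["ca1"])
        assert L.select_ripple_channel(filt) == spec.ripple_peak_channel

    def test_tie_breaks_to_lowest_index(self):
        x = np.vstack([sine(200.0), sine(200.0)])
        assert L.select_ripple_channel(x) == 0


class TestDetection:
    def test_planted_ripples_and_artifacts(self, lfp_session):
        """All planted ripples detected (precision = recall = 1) and all
        planted artifacts rejected by the high-cut."""
        spec, bundle, truth = lfp_session
        ev = L.detect_ripples_from_bundle(bundle)
        ret = ev.retained["time_s"].to_numpy()
        planted = truth.ripple_times_s
        assert len(ret) == len(planted)
        assert all(np.min(np.abs(planted - t)) < 0.05 for t in ret)
        n_art = ev.events.artifact.sum()
        assert n_art == len(truth.artifact_times_s) == 3

    @staticmethod
    def burst(sig, t0, amp=200.0, freq=200.0, env_sd=0.01):
        t = np.arange(len(sig)) / FS
        sig += amp * np.exp(-0.5 * ((t - t0) / env_sd) ** 2) \
            * np.sin(2 * np.pi * freq * (t - t0))

    def test_refractory_keeps_first(self):
        env_sig = np.zeros(int(2 * FS))
        self.burst(env_sig, 0.5)
        self.burst(env_sig, 0.65)                  # 150 ms apart
        ev = L.detect_ripples(env_sig, FS, np.empty(0),
                              pd.DataFrame(columns=["onset_s"]))
        assert ev.events.retained.sum() == 1
        assert ev.retained.time_s.iloc[0] == pytest.approx(0.5, abs=0.02)

    def test_lick_exclusion(self):
        env_sig = np.zeros(int(2 * FS))
        self.burst(env_sig, 1.0)
        ev = L.detect_ripples(env_sig, FS, np.array([0.9]),
                              pd.DataFrame(columns=["onset_s"]))
        assert ev.events.near_lick.all()
        assert ev.events.retained.sum() == 0

    def test_refractory_invariant_on_output(self, lfp_session):
        _, bundle, _ = lfp_session
        ev = L.detect_ripples_from_bundle(bundle)
        times = ev.retained["time_s"].to_numpy()
        assert np.all(np.diff(times) >= 0.2)
        amps = ev.retained["amplitude_uv"].to_numpy()
        assert np.all((amps >= 100.0) & (amps < 500.0))

    def test_bad_thresholds_raise(self):
        with pytest.raises(ValueError):
            L.detect_ripples(np.zeros(100), FS, np.empty(0),
                             pd.DataFrame(columns=["onset_s"]),
                             low_cut_uv=500, high_cut_uv=100)


class TestRateDynamics:
    def test_uniform_process_iti_rate(self, lfp_session):
        spec, bundle, truth = lfp_session
        ev = L.detect_ripples_from_bundle(bundle)
        rates = L.ripple_rate_dynamics(ev, bundle.trials, bundle.duration_s)
        # planted rate 0.15 Hz in the ITI; Poisson error over ~200 s
        assert rates["period_rates_hz"]["iti"] == pytest.approx(
            spec.ripple_rate_hz, abs=0.08)

    def test_no_events_all_zero(self):
        ev = L.detect_ripples(np.zeros(int(FS)), FS, np.empty(0),
                              pd.DataFrame(columns=["onset_s"]))
        rates = L.ripple_rate_dynamics(ev, pd.DataFrame(columns=["onset_s"]),
                                       60.0)
        assert rates["n_retained"] == 0
        assert all(v == 0 for v in rates["period_rates_hz"].values())

    def test_blocks_conserve_event_count(self, lfp_session):
        _, bundle, _ = lfp_session
        ev = L.detect_ripples_from_bundle(bundle)
        rates = L.ripple_rate_dynamics(ev, bundle.trials, bundle.duration_s)
        assert rates["blocks"]["n_events"].sum() == rates["n_retained"]


class TestCoherence:
    def test_identical_signals_coherence_one(self):
        rng = np.random.default_rng(0)
        segs = [rng.standard_normal(2000) for _ in range(6)]
        f, coh = L.multitaper_coherence(segs, segs, FS)
        assert np.all(coh[1:-1] > 0.999)

    def test_independent_noise_bias_decreases_with_segments(self):
        rng = np.random.default_rng(1)

        def bias(n_seg):
            xs = [rng.standard_normal(2000) for _ in range(n_seg)]
            ys = [rng.standard_normal(2000) for _ in range(n_seg)]
            _, coh = L.multitaper_coherence(xs, ys, FS)
            return coh.mean()
        assert bias(40) < bias(5) < 0.5

    def test_planted_shared_component_in_trace_only(self, lfp_session):
        _, bundle, _ = lfp_session
        res = L.coherence_analysis(bundle, n_perm=50, seed=0)
        f, tr = res["coherence"][("plus", "trace")]
        _, ba = res["coherence"][("plus", "baseline")]
        band = (f >= 60) & (f <= 100)
        out_band = (f >= 10) & (f <= 40)
        assert tr[band].mean() > ba[band].mean() + 0.2
        assert tr[out_band].mean() < tr[band].mean()

    def test_zero_gain_leaves_bias_floor(self):
        from condpipe.synthetic import SessionSpec, generate_session
        spec = SessionSpec(seed=8, n_units_ca1=2, n_units_pfc=2,
                           n_trials_csplus=8, n_trials_csminus=8,
                           iti_range_s=(6.0, 9.0), coherence_gain_uv=0.0,
                           baseline_rate_hz=1.0, ripple_rate_hz=0.02)
        bundle, _ = generate_session(spec)
        res = L.coherence_analysis(bundle, n_perm=1, seed=0)
        f, tr = res["coherence"][("plus", "trace")]
        band = (f >= 60) & (f <= 100)
        assert tr[band].mean() < 0.45      # near the few-segment bias floor

    def test_segment_validation(self):
        with pytest.raises(ValueError):
            L.multitaper_coherence([np.zeros(10)], [np.zeros(10)], FS)
        with pytest.raises(ValueError):
            L.multitaper_coherence([np.zeros(2000)], [np.zeros(1000)], FS)


class TestPermutationTest:
    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(2)

        def seg():
            return [rng.standard_normal(1000) for _ in range(10)]
        fracs = []
        for _ in range(3):
            _, _, p, sig = L.per_frequency_permutation_test(
                seg(), seg(), seg(), seg(), FS, n_perm=200, seed=0)
            fracs.append(sig.mean())
        assert 0.0 <= np.mean(fracs) <= 0.15

    def test_planted_band_difference_detected(self):
        rng = np.random.default_rng(3)
        shared_band = signal.butter(4, (70, 90), "bandpass", fs=FS, output="sos")

        def cond(shared_gain):
            xs, ys = [], []
            for _ in range(10):
                s = signal.sosfiltfilt(shared_band, rng.standard_normal(1000))
                s /= s.std()
                xs.append(rng.standard_normal(1000) + shared_gain * s)
                ys.append(rng.standard_normal(1000) + shared_gain * s)
            return xs, ys
        xa, ya = cond(2.0)
        xb, yb = cond(0.0)
        f, d, p, sig = L.per_frequency_permutation_test(
            xa, ya, xb, yb, FS, n_perm=200, seed=0)
        assert sig[np.argmin(np.abs(f - 80.0))]
        assert d[np.argmin(np.abs(f - 80.0))] > 0

    def test_zero_permutations_rejected(self):
        segs = [np.zeros(1000)] * 5
        with pytest.raises(ValueError):
            L.per_frequency_permutation_test(segs, segs, segs, segs, FS,
                                             n_perm=0)
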