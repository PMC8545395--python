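"""Ripple detection and CA1-PFC coherence.

Awake sharp-wave ripples are detected on the CA1 channel with the
strongest ripple-band power after zero-phase 150-300 Hz band-pass
filtering and common-average referencing.  Candidate events are envelope
(analytic-signal magnitude) excursions above a low-cut threshold
(100 µV default); peaks above the high-cut (500 µV) are rejected as
artifacts, events within 200 ms of a retained earlier event or within
200 ms of any lick are excluded.  Coherence between the CA1 ripple
channel and the PFC channel uses multitaper (Slepian) averaging with a
per-frequency permutation test between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic import LFPBlock, TRIAL_SPAN_S

RIPPLE_BAND = (150.0, 300.0)
REFRACTORY_S = 0.2
LICK_GUARD_S = 0.2
TASK_PERIODS = {"stim": (0.0, 2.0), "trace": (2.0, 3.0), "reward": (3.0, 3.5)}


def preprocess_ripple_band(lfp: LFPBlock, band=RIPPLE_BAND) -> np.ndarray:
    """Zero-phase band-pass then common-average reference.

    Returns channels x samples ripple-band signal.  4th-order Butterworth
    applied forward-backward.
    """
    data = np.asarray(lfp.data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need >= 2 channels for common-average referencing")
    if lfp.fs_hz < 2 * band[1]:
        raise ValueError(f"sampling rate {lfp.fs_hz} Hz too low for "
                         f"{band[1]} Hz band edge")
    sos = signal.butter(4, band, "bandpass", fs=lfp.fs_hz, output="sos")
    filt = signal.sosfiltfilt(sos, data, axis=1)
    return filt - filt.mean(axis=0, keepdims=True)


def select_ripple_channel(filtered: np.ndarray) -> int:
    """Channel with the strongest mean squared ripple-band amplitude.
    Ties resolve to the lowest index."""
    power = np.mean(filtered ** 2, axis=1)
    return int(np.argmax(power))


@dataclass
class RippleEvents:
    events: pd.DataFrame            # time_s, amplitude_uv, retained + flag columns
    channel: int
    fs_hz: float
    low_cut_uv: float
    high_cut_uv: float

    @property
    def retained(self) -> pd.DataFrame:
        return self.events[self.events.retained]


def detect_ripples(filtered_channel: np.ndarray, fs_hz: float,
                   licks: np.ndarray, trials: pd.DataFrame,
                   low_cut_uv: float = 100.0, high_cut_uv: float = 500.0,
                   channel: int = 0) -> RippleEvents:
    """Envelope-threshold ripple detection with exclusion rules.

    Event time is the envelope peak within each supra-threshold epoch.
    Flags: ``artifact`` (peak >= high_cut), ``near_lick`` (within 200 ms
    of any lick), ``merged`` (within 200 ms of a retained earlier event,
    keep-first), ``in_iti`` (outside all trial windows onset..onset+4 s).
    """
    if not 0 < low_cut_uv < high_cut_uv:
        raise ValueError("need 0 < low_cut < high_cut")
    env = np.abs(signal.hilbert(np.asarray(filtered_channel, dtype=float)))
    above = env >= low_cut_uv
    # contiguous supra-threshold epochs
    d = np.diff(above.astype(int))
    starts = np.where(d == 1)[0] + 1
    stops = np.where(d == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, len(above)]
    times, amps = [], []
    for a, b in zip(starts, stops):
        peak = a + int(np.argmax(env[a:b]))
        times.append(peak / fs_hz)
        amps.append(env[peak])
    times = np.asarray(times)
    amps = np.asarray(amps)

    artifact = amps >= high_cut_uv
    licks = np.sort(np.asarray(licks, dtype=float))
    if len(licks):
        d_lick = np.array([np.min(np.abs(licks - t)) if len(licks) else np.inf
                           for t in times])
        near_lick = d_lick <= LICK_GUARD_S
    else:
        near_lick = np.zeros(len(times), dtype=bool)

    merged = np.zeros(len(times), dtype=bool)
    last_kept = -np.inf
    for i in range(len(times)):
        if artifact[i] or near_lick[i]:
            continue
        if times[i] - last_kept < REFRACTORY_S:
            merged[i] = True
        else:
            last_kept = times[i]

    onsets = trials["onset_s"].to_numpy() if len(trials) else np.empty(0)
    if len(onsets):
        in_trial = np.array([np.any((t >= onsets) & (t < onsets + TRIAL_SPAN_S))
                             for t in times])
    else:
        in_trial = np.zeros(len(times), dtype=bool)

    events = pd.DataFrame({
        "time_s": times, "amplitude_uv": amps,
        "artifact": artifact, "near_lick": near_lick, "merged": merged,
        "in_iti": ~in_trial,
        "retained": ~(artifact | near_lick | merged),
    })
    return RippleEvents(events=events, channel=channel, fs_hz=fs_hz,
                        low_cut_uv=low_cut_uv, high_cut_uv=high_cut_uv)


def detect_ripples_from_bundle(bundle, low_cut_uv: float = 100.0,
                               high_cut_uv: float = 500.0) -> RippleEvents:
    filt = preprocess_ripple_band(bundle.lfp["ca1"])
    ch = select_ripple_channel(filt)
    return detect_ripples(filt[ch], bundle.lfp["ca1"].fs_hz, bundle.licks,
                          bundle.trials, low_cut_uv, high_cut_uv, channel=ch)


def ripple_rate_dynamics(ripples: RippleEvents, trials: pd.DataFrame,
                         duration_s: float, n_blocks: int = 10) -> dict:
    """Retained-event rates per task period and per equal-trial block."""
    times = ripples.retained["time_s"].to_numpy()
    onsets = trials["onset_s"].to_numpy() if len(trials) else np.empty(0)

    period_rates = {}
    trial_time = 0.0
    for name, (lo, hi) in TASK_PERIODS.items():
        count = 0
        total = 0.0
        for o in onsets:
            count += int(np.sum((times >= o + lo) & (times < o + hi)))
            total += hi - lo
        trial_time += total
        period_rates[name] = count / total if total > 0 else 0.0
    # ITI occupancy: everything outside trial windows
    in_trial = np.zeros(len(times), dtype=bool)
    for o in onsets:
        in_trial |= (times >= o) & (times < o + TRIAL_SPAN_S)
    iti_time = duration_s - len(onsets) * TRIAL_SPAN_S
    period_rates["iti"] = int(np.sum(~in_trial)) / iti_time if iti_time > 0 else 0.0

    blocks = []
    if len(onsets) >= n_blocks:
        bounds = np.linspace(0, len(onsets), n_blocks + 1).astype(int)
        for b in range(n_blocks):
            t0 = 0.0 if b == 0 else onsets[bounds[b]]
            t1 = duration_s if b == n_blocks - 1 else onsets[bounds[b + 1]]
            n = int(np.sum((times >= t0) & (times < t1)))
            blocks.append({"block": b, "t0": t0, "t1": t1, "n_events": n,
                           "rate_hz": n / (t1 - t0) if t1 > t0 else 0.0})
    return {"period_rates_hz": period_rates, "blocks": pd.DataFrame(blocks),
            "n_retained": len(times)}


# ---------------------------------------------------------------------------
# multitaper coherence
# ---------------------------------------------------------------------------

def _tapered_ffts(segs: np.ndarray, tapers: np.ndarray) -> np.ndarray:
    """rFFTs of tapered segments: (n_segments, n_tapers, n_freqs)."""
    return np.fft.rfft(segs[:, None, :] * tapers[None, :, :], axis=2)


def _coh_from_ffts(Fx: np.ndarray, Fy: np.ndarray) -> np.ndarray:
    sxy = np.sum(Fx * np.conj(Fy), axis=(0, 1))
    sxx = np.sum(np.abs(Fx) ** 2, axis=(0, 1))
    syy = np.sum(np.abs(Fy) ** 2, axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.abs(sxy) / np.sqrt(sxx * syy)


def multitaper_coherence(x_segments, y_segments, fs_hz: float,
                         nw: float = 3.0, n_tapers: int = 5):
    """Magnitude coherence per frequency, averaged over segments and tapers.

    All segments must share one length; a Slepian family with
    time-bandwidth product ``nw`` and ``n_tapers`` tapers is used.
    Returns ``(freqs, coherence)``.
    """
    x_segments = [np.asarray(s, dtype=float) for s in x_segments]
    y_segments = [np.asarray(s, dtype=float) for s in y_segments]
    if len(x_segments) == 0 or len(x_segments) != len(y_segments):
        raise ValueError("need equal, non-empty x/y segment lists")
    L = len(x_segments[0])
    if any(len(s) != L for s in x_segments + y_segments):
        raise ValueError("all segments must have the same length")
    if L < 4 * n_tapers:
        raise ValueError(f"segments of {L} samples too short for {n_tapers} tapers")
    tapers = signal.windows.dpss(L, nw, n_tapers)
    Fx = _tapered_ffts(np.asarray(x_segments), tapers)
    Fy = _tapered_ffts(np.asarray(y_segments), tapers)
    freqs = np.fft.rfftfreq(L, 1.0 / fs_hz)
    return freqs, _coh_from_ffts(Fx, Fy)


def per_frequency_permutation_test(x_a, y_a, x_b, y_b, fs_hz: float,
                                   n_perm: int = 1000, nw: float = 3.0,
                                   n_tapers: int = 5, alpha: float = 0.05,
                                   seed: int = 0):
    """Permutation test of the coherence difference per frequency.

    The statistic is coh(A) - coh(B); the null is built by shuffling the
    condition labels of the pooled (x, y) segment pairs.  Two-sided p per
    frequency; returns ``(freqs, diff, p, significant_mask)``.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be > 0")
    if len(x_a) < 5 or len(x_b) < 5:
        raise ValueError("need >= 5 segments per condition")
    L = len(x_a[0])
    tapers = signal.windows.dpss(L, nw, n_tapers)
    Fx = _tapered_ffts(np.asarray(list(x_a) + list(x_b), dtype=float), tapers)
    Fy = _tapered_ffts(np.asarray(list(y_a) + list(y_b), dtype=float), tapers)
    na = len(x_a)
    n_tot = Fx.shape[0]
    obs = _coh_from_ffts(Fx[:na], Fy[:na]) - _coh_from_ffts(Fx[na:], Fy[na:])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(obs.shape, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        ia, ib = perm[:na], perm[na:]
        null = _coh_from_ffts(Fx[ia], Fy[ia]) - _coh_from_ffts(Fx[ib], Fy[ib])
        exceed += np.abs(null) >= np.abs(obs)
    p = (1 + exceed) / (n_perm + 1)
    freqs = np.fft.rfftfreq(L, 1.0 / fs_hz)
    return freqs, obs, p, p < alpha


def extract_trial_segments(bundle, area: str, channel: int,
                           window: tuple, trial_mask=None) -> list:
    """Per-trial LFP segments of one channel, ``window`` relative to onset."""
    block = bundle.lfp[area]
    fs = block.fs_hz
    n = block.data.shape[1]
    trials = bundle.trials if trial_mask is None else bundle.trials[trial_mask]
    L = int(round((window[1] - window[0]) * fs))
    segs = []
    for o in trials["onset_s"]:
        a = int(round((o + window[0]) * fs))
        if a >= 0 and a + L <= n:
            segs.append(np.asarray(block.data[channel, a:a + L], dtype=float))
    return segs


def coherence_analysis(bundle, windows=None, n_perm: int = 200, seed: int = 0,
                       nw: float = 3.0, n_tapers: int = 5) -> dict:
    """CS-aligned CA1-PFC coherence per trial period, with the baseline-vs-
    trace permutation contrast per CS type."""
    if windows is None:
        windows = {"baseline": (-1.0, 0.0), "stim_early": (0.5, 1.5),
                   "trace": (2.0, 3.0)}
    filt = preprocess_ripple_band(bundle.lfp["ca1"])
    ch = select_ripple_channel(filt)
    out = {"channel": ch, "coherence": {}, "tests": {}}
    for cs in ("plus", "minus"):
        mask = bundle.trials.cs_type == cs
        segs = {}
        for name, win in windows.items():
            xa = extract_trial_segments(bundle, "ca1", ch, win, mask)
            ya = extract_trial_segments(bundle, "pfc", 0, win, mask)
            segs[name] = (xa, ya)
            if len(xa) >= 2:
                f, coh = multitaper_coherence(xa, ya, bundle.lfp["ca1"].fs_hz,
                                              nw=nw, n_tapers=n_tapers)
                out["coherence"][(cs, name)] = (f, coh)
        if len(segs.get("trace", ([], []))[0]) >= 5:
            f, diff, p, sig = per_frequency_permutation_test(
                *segs["trace"], *segs["baseline"], bundle.lfp["ca1"].fs_hz,
                n_perm=n_perm, nw=nw, n_tapers=n_tapers, seed=seed)
            out["tests"][cs] = {"freqs": f, "diff": diff, "p": p, "sig": sig}
    return out
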