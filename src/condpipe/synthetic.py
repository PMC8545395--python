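"""Synthetic session generator for appetitive auditory trace conditioning.

Emulates a head-fixed conditioning session with paired CA1 / PFC
extracellular recordings: a CS+ sound (2 s) predicts a liquid reward
delivered after a 1 s silent trace period; a CS- sound predicts nothing.
The generator produces

* a trial schedule with randomized CS order and uniform inter-trial
  intervals,
* licking with learning-dependent anticipatory bouts,
* inhomogeneous-Poisson spike trains with planted response classes
  (sound-evoked, trace-up/-down, lick, reward, unmodulated), planted
  synchronous cell assemblies, and an optional shared low-rank drive
  linking the two areas,
* a multichannel CA1 LFP with planted sharp-wave-ripple bursts (plus
  optional large artifacts) and a PFC LFP channel sharing a band-limited
  component during trials to create coherence,

together with a :class:`GroundTruth` record so every downstream analysis
can be validated against the planted structure.

All randomness flows from ``SessionSpec.seed`` through a single
``numpy.random.Generator``; identical specs yield identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

# Task geometry (seconds, relative to CS onset)
CS_DUR_S = 2.0          # sound duration
TRACE_DUR_S = 1.0       # silent gap between CS offset and reward
REWARD_DELAY_S = 3.0    # reward at onset + 3 s (CS+ only)
REWARD_DUR_S = 0.5
TRIAL_SPAN_S = 4.0      # analysis window extends to onset + 4 s
TRIAL_PRE_S = 1.0       # pre-onset baseline window

RESPONSE_CLASSES = ("evoked", "trace_up", "trace_down", "lick", "reward", "unmodulated")


@dataclass
class AssemblyDef:
    """A planted synchronous cell assembly.

    Members receive excess, jointly timed spikes within a shared 20 ms
    window at assembly event times.  Events arise from a homogeneous
    background process, an optional extra in-trial process (biased to a
    trial period / CS type), and optionally co-occur with ripples.
    """

    area: str
    members: tuple
    event_rate_hz: float = 0.2          # background rate, whole session
    participation_p: float = 0.9        # per-member within-event spike probability
    bias_cs: Optional[str] = None       # "plus", "minus" or None (all trials)
    bias_period: str = "stim+trace"     # {"stim", "trace", "stim+trace"}
    bias_rate_hz: float = 1.0           # extra event rate inside biased windows
    ripple_coupling_p: float = 0.0      # P(event at a given ripple)
    coupling_ramp: bool = False         # coupling grows linearly 0 -> 2p over the session


def _default_fractions(area: str, stage: str) -> dict:
    """Per-area response-class fractions emulating the learning-dependent mix.

    Post-learning CA1 is dominated by trace-suppressed cells while PFC is
    dominated by trace-activated cells; pre-learning the trace classes are
    closer to balanced and evoked responses are weaker in CA1.
    """
    if area == "ca1":
        if stage == "post":
            return {"evoked": 0.10, "trace_up": 0.15, "trace_down": 0.35,
                    "lick": 0.04, "reward": 0.08}
        return {"evoked": 0.06, "trace_up": 0.25, "trace_down": 0.17,
                "lick": 0.02, "reward": 0.12}
    if stage == "post":
        return {"evoked": 0.20, "trace_up": 0.33, "trace_down": 0.15,
                "lick": 0.06, "reward": 0.08}
    return {"evoked": 0.20, "trace_up": 0.28, "trace_down": 0.18,
            "lick": 0.02, "reward": 0.12}


@dataclass
class SessionSpec:
    """Parameters of one synthetic session.

    Defaults mirror the task constants (2 s CS, 1 s trace, reward at
    onset + 3 s, ITIs uniform in 30-45 s, 50 CS+ / 50 CS- trials) and
    plausible acute-recording statistics (unit counts near the reported
    per-session averages, 0.09 Hz awake-ripple rate, 150-300 Hz ripple
    band).
    """

    seed: int = 0
    stage: str = "post"                         # {"pre", "post"}
    n_units_ca1: int = 34
    n_units_pfc: int = 54
    n_trials_csplus: int = 50
    n_trials_csminus: int = 50
    iti_range_s: tuple = (30.0, 45.0)
    fs_lfp_hz: float = 2000.0
    n_lfp_channels_ca1: int = 16
    baseline_rate_hz: float = 5.0
    response_fractions: Optional[dict] = None   # area -> class -> fraction
    # effect sizes (Hz)
    evoked_effect_hz: float = 5.0
    trace_effect_hz: float = 5.0   # peak of the within-trace ramp
    lick_effect_hz: float = 6.0
    reward_effect_hz: float = 5.0
    # CS- gain on evoked responses per area (post-learning PFC discriminates)
    cs_minus_evoked_gain: Optional[dict] = None
    assembly_defs: list = field(default_factory=list)
    ripple_rate_hz: float = 0.09
    ripple_amp_uv: float = 200.0
    ripple_freq_hz: float = 180.0
    ripple_peak_channel: int = 7
    n_artifacts: int = 0
    artifact_amp_uv: float = 650.0
    comm_rank: int = 0                          # latent rank of shared CA1->PFC drive
    comm_gain_hz: float = 2.0                   # sd of latent loadings (Hz)
    comm_bin_s: float = 0.1
    lfp_noise_uv: float = 60.0
    coherence_gain_uv: float = 25.0             # shared gamma-band component amplitude
    coherence_band_hz: tuple = (60.0, 100.0)
    with_lfp: bool = True

    def __post_init__(self):
        if self.response_fractions is None:
            self.response_fractions = {
                "ca1": _default_fractions("ca1", self.stage),
                "pfc": _default_fractions("pfc", self.stage),
            }
        if self.cs_minus_evoked_gain is None:
            # post-learning: PFC CS- evoked responses have decayed
            self.cs_minus_evoked_gain = (
                {"ca1": 1.0, "pfc": 0.3} if self.stage == "post"
                else {"ca1": 1.0, "pfc": 1.0})

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.stage not in ("pre", "post"):
            raise ValueError(f"stage must be 'pre' or 'post', got {self.stage!r}")
        for name in ("n_units_ca1", "n_units_pfc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_trials_csplus < 0 or self.n_trials_csminus < 0:
            raise ValueError("trial counts must be >= 0")
        if not self.iti_range_s[0] < self.iti_range_s[1]:
            raise ValueError("iti_range_s must satisfy min < max")
        if not (150.0 <= self.ripple_freq_hz <= 300.0):
            raise ValueError("ripple_freq_hz must lie in the 150-300 Hz ripple band")
        if self.ripple_amp_uv <= 0:
            raise ValueError("ripple_amp_uv must be > 0")
        for area, fracs in self.response_fractions.items():
            total = sum(fracs.get(c, 0.0) for c in RESPONSE_CLASSES if c != "unmodulated")
            if total > 1.0 + 1e-9:
                raise ValueError(f"response fractions for {area} sum to {total} > 1")
        for adef in self.assembly_defs:
            n = {"ca1": self.n_units_ca1, "pfc": self.n_units_pfc}[adef.area]
            if any(m < 0 or m >= n for m in adef.members):
                raise ValueError("assembly member index out of range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["assembly_defs"] = [asdict(a) for a in self.assembly_defs]
        return d

    def spec_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Planted structure of a synthetic session (recovery target for tests)."""

    unit_class: dict                    # area -> list of class labels
    assembly_membership: list           # list of dicts (area, members, weights, coupling)
    ripple_times_s: np.ndarray
    artifact_times_s: np.ndarray
    planted_comm_rank: int
    lick_bout_onsets_s: np.ndarray
    learned: bool

    def validate(self) -> None:
        if np.any(np.diff(self.ripple_times_s) <= 0):
            raise ValueError("ripple times must be strictly increasing")


@dataclass
class LFPBlock:
    data: np.ndarray                    # channels x samples, float32, µV
    fs_hz: float


@dataclass
class SessionBundle:
    """All data for one (synthetic or recorded) session."""

    trials: pd.DataFrame                # onset_s, cs_type, reward_time_s (NaN if none)
    licks: np.ndarray                   # sorted lick times (s)
    spikes: dict                        # area -> list of sorted per-unit spike-time arrays
    lfp: dict                           # area -> LFPBlock
    duration_s: float
    meta: dict

    @property
    def areas(self):
        return sorted(self.spikes)

    def n_units(self, area: str) -> int:
        return len(self.spikes[area])


# ---------------------------------------------------------------------------
# schedule / licks
# ---------------------------------------------------------------------------

def generate_trial_schedule(spec: SessionSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Randomly interleaved CS+/CS- trials with uniform ITIs.

    The ITI is the gap between the end of one trial window (onset + 4 s)
    and the next onset.  Reward is delivered at onset + 3 s on CS+ trials
    only.
    """
    spec.validate()
    n_plus, n_minus = spec.n_trials_csplus, spec.n_trials_csminus
    labels = np.array(["plus"] * n_plus + ["minus"] * n_minus)
    rng.shuffle(labels)
    n = len(labels)
    itis = rng.uniform(*spec.iti_range_s, size=n)
    onsets = np.empty(n)
    t = itis[0] if n else 0.0
    for i in range(n):
        onsets[i] = t
        t += TRIAL_SPAN_S + (itis[i + 1] if i + 1 < n else 0.0)
    reward = np.where(labels == "plus", onsets + REWARD_DELAY_S, np.nan)
    return pd.DataFrame({"onset_s": onsets, "cs_type": labels, "reward_time_s": reward})


def session_duration(trials: pd.DataFrame, spec: SessionSpec) -> float:
    if len(trials) == 0:
        return 60.0
    return float(trials["onset_s"].iloc[-1] + TRIAL_SPAN_S + np.mean(spec.iti_range_s))


def _lick_bout(t0: float, dur: float, rng: np.random.Generator,
               rate_hz: float = 7.0) -> np.ndarray:
    """Regular lick train at ~7 Hz with 10% ISI jitter."""
    n = max(int(dur * rate_hz) + 2, 3)
    isi = (1.0 / rate_hz) * (1.0 + 0.1 * rng.standard_normal(n))
    times = t0 + np.cumsum(np.abs(isi))
    return times[times < t0 + dur]


def generate_licks(trials: pd.DataFrame, stage: str, rng: np.random.Generator,
                   duration_s: float = None,
                   p_anticipate: float = 0.9,
                   baseline_rate_hz: float = 0.05):
    """Lick times plus anticipatory-bout onsets.

    Post-learning, most CS+ trials carry a lick bout starting during the
    trace period (anticipatory licking) which continues through reward
    consumption; pre-learning, bouts begin only after reward delivery.
    Sparse baseline licks occur throughout the session.
    """
    licks = []
    bout_onsets = []
    if duration_s is None:
        dur = float(trials["onset_s"].iloc[-1] + TRIAL_SPAN_S + 30.0) if len(trials) else 60.0
    else:
        dur = duration_s
    for _, tr in trials.iterrows():
        if tr.cs_type != "plus":
            continue
        onset = tr.onset_s
        reward = onset + REWARD_DELAY_S
        if stage == "post" and rng.random() < p_anticipate:
            t0 = onset + CS_DUR_S + rng.uniform(0.1, 0.5)
            bout_dur = (reward - t0) + rng.uniform(1.0, 1.8)
        else:
            t0 = reward + rng.uniform(0.08, 0.2)
            bout_dur = rng.uniform(1.0, 1.8)
        bout = _lick_bout(t0, bout_dur, rng)
        if len(bout):
            licks.append(bout)
            bout_onsets.append(bout[0])
    # sparse baseline licking anywhere in the session
    n_base = rng.poisson(baseline_rate_hz * dur)
    licks.append(rng.uniform(0, dur, size=n_base))
    all_licks = np.sort(np.concatenate(licks)) if licks else np.empty(0)
    return all_licks, np.sort(np.asarray(bout_onsets))


# ---------------------------------------------------------------------------
# ripples
# ---------------------------------------------------------------------------

def generate_ripple_times(spec: SessionSpec, trials: pd.DataFrame,
                          licks: np.ndarray, duration_s: float,
                          rng: np.random.Generator,
                          min_sep_s: float = 0.3,
                          lick_guard_s: float = 0.25) -> np.ndarray:
    """Awake-ripple times: Poisson in the inter-trial intervals.

    Candidates inside trial windows (onset - 1 .. onset + 4 s), within the
    lick guard, or closer than ``min_sep_s`` to an accepted earlier event
    are discarded, so planted ripples are detectable by construction.
    """
    n_cand = rng.poisson(spec.ripple_rate_hz * duration_s)
    cand = np.sort(rng.uniform(0, duration_s, size=n_cand))
    onsets = trials["onset_s"].to_numpy() if len(trials) else np.empty(0)
    keep = []
    last = -np.inf
    for t in cand:
        if t < 1.0 or t > duration_s - 1.0:
            continue
        if len(onsets) and np.any((t > onsets - TRIAL_PRE_S) & (t < onsets + TRIAL_SPAN_S)):
            continue
        if len(licks) and np.min(np.abs(licks - t)) < lick_guard_s:
            continue
        if t - last < min_sep_s:
            continue
        keep.append(t)
        last = t
    return np.asarray(keep)


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def _windows_for_bias(trials: pd.DataFrame, bias_cs, bias_period):
    sel = trials
    if bias_cs is not None:
        sel = trials[trials.cs_type == bias_cs]
    starts = {"stim": 0.0, "trace": CS_DUR_S, "stim+trace": 0.0}[bias_period]
    stops = {"stim": CS_DUR_S, "trace": REWARD_DELAY_S, "stim+trace": REWARD_DELAY_S}[bias_period]
    on = sel["onset_s"].to_numpy()
    return on + starts, on + stops


def _assembly_event_times(adef: AssemblyDef, trials: pd.DataFrame,
                          ripple_times: np.ndarray, duration_s: float,
                          rng: np.random.Generator) -> np.ndarray:
    events = []
    n_bg = rng.poisson(adef.event_rate_hz * duration_s)
    events.append(rng.uniform(0, duration_s, size=n_bg))
    if adef.bias_rate_hz > 0 and len(trials):
        lo, hi = _windows_for_bias(trials, adef.bias_cs, adef.bias_period)
        for a, b in zip(lo, hi):
            n = rng.poisson(adef.bias_rate_hz * (b - a))
            events.append(rng.uniform(a, b, size=n))
    if adef.ripple_coupling_p > 0 and len(ripple_times):
        p = np.full(len(ripple_times), adef.ripple_coupling_p)
        if adef.coupling_ramp:
            p = adef.ripple_coupling_p * 2.0 * ripple_times / duration_s
        mask = rng.random(len(ripple_times)) < p
        events.append(ripple_times[mask] + rng.uniform(-0.005, 0.005, size=mask.sum()))
    return np.sort(np.concatenate(events)) if events else np.empty(0)


def _assign_classes(n_units: int, fractions: dict, rng: np.random.Generator):
    counts = {c: int(round(fractions.get(c, 0.0) * n_units))
              for c in RESPONSE_CLASSES if c != "unmodulated"}
    labels = []
    for c, k in counts.items():
        labels.extend([c] * k)
    labels.extend(["unmodulated"] * (n_units - len(labels)))
    labels = np.array(labels[:n_units])
    rng.shuffle(labels)
    return labels


def generate_spike_trains(spec: SessionSpec, trials: pd.DataFrame,
                          licks: np.ndarray, bout_onsets: np.ndarray,
                          ripple_times: np.ndarray, duration_s: float,
                          rng: np.random.Generator):
    """Inhomogeneous-Poisson spike trains with planted structure.

    Baseline homogeneous Poisson spikes are modulated additively:
    evoked units gain rate in 0-350 ms after either CS (CS- scaled by the
    per-area learning gain), trace_up/trace_down units gain/lose rate in
    2-3 s after CS+ onset, lick units gain rate in ±250 ms around bout
    onsets, reward units in 0-0.5 s post reward.  Assembly members receive
    extra near-synchronous spikes within a shared 20 ms window at assembly
    event times.  A rank-``comm_rank`` latent drive shared between areas is
    added inside trial windows.

    Returns ``(spikes, unit_class, assembly_truth)``.
    """
    spec.validate()
    onsets = trials["onset_s"].to_numpy()
    cs = trials["cs_type"].to_numpy()
    rewards = trials["reward_time_s"].to_numpy()

    spikes = {}
    unit_class = {}
    areas = {"ca1": spec.n_units_ca1, "pfc": spec.n_units_pfc}

    # shared latent drive (per 100 ms bin inside trial windows)
    latent = None
    if spec.comm_rank > 0 and len(trials):
        nb = int(round((TRIAL_SPAN_S + TRIAL_PRE_S) / spec.comm_bin_s))
        latent = rng.standard_normal((len(trials), nb, spec.comm_rank))

    for area, n_units in areas.items():
        labels = _assign_classes(n_units, spec.response_fractions[area], rng)
        unit_class[area] = labels
        loadings = (rng.standard_normal((n_units, spec.comm_rank)) * spec.comm_gain_hz
                    if latent is not None else None)
        area_spikes = []
        for u in range(n_units):
            spk = rng.uniform(0, duration_s, size=rng.poisson(
                spec.baseline_rate_hz * duration_s))
            cls = labels[u]
            extra = []
            if cls == "evoked":
                for o, c in zip(onsets, cs):
                    gain = 1.0 if c == "plus" else spec.cs_minus_evoked_gain[area]
                    lam = spec.evoked_effect_hz * gain * 0.35
                    extra.append(o + rng.uniform(0, 0.35, size=rng.poisson(lam)))
            elif cls == "trace_up":
                # ramping sustained activity: 0 at trace onset, peak at reward
                for o in onsets[cs == "plus"]:
                    lam = spec.trace_effect_hz * TRACE_DUR_S  # peak-rate candidates
                    cand = rng.uniform(0, TRACE_DUR_S, size=rng.poisson(lam))
                    cand = cand[rng.random(len(cand)) < cand / TRACE_DUR_S]
                    extra.append(o + CS_DUR_S + cand)
            elif cls == "trace_down":
                # ramping suppression, deepest just before reward
                p_peak = min(1.0, spec.trace_effect_hz / spec.baseline_rate_hz)
                for o in onsets[cs == "plus"]:
                    rel = (spk - o - CS_DUR_S) / TRACE_DUR_S
                    in_win = (rel >= 0) & (rel < 1)
                    kill = in_win & (rng.random(len(spk)) < p_peak * np.clip(rel, 0, 1))
                    spk = spk[~kill]
            elif cls == "lick":
                for b in bout_onsets:
                    lam = spec.lick_effect_hz * 0.5
                    extra.append(b + rng.uniform(-0.25, 0.25, size=rng.poisson(lam)))
            elif cls == "reward":
                for r in rewards[~np.isnan(rewards)]:
                    lam = spec.reward_effect_hz * REWARD_DUR_S
                    extra.append(r + rng.uniform(0, REWARD_DUR_S, size=rng.poisson(lam)))
            if latent is not None:
                drive = latent @ loadings[u]          # trials x nb
                for ti, o in enumerate(onsets):
                    d = drive[ti]
                    add = d > 0
                    for bi in np.nonzero(add)[0]:
                        lam = d[bi] * spec.comm_bin_s
                        t0 = o - TRIAL_PRE_S + bi * spec.comm_bin_s
                        extra.append(t0 + rng.uniform(0, spec.comm_bin_s,
                                                      size=rng.poisson(lam)))
                    # thinning for negative drive
                    neg = np.nonzero(d < 0)[0]
                    if len(neg):
                        t0s = o - TRIAL_PRE_S + neg * spec.comm_bin_s
                        for bi, t0 in zip(neg, t0s):
                            p = min(1.0, -d[bi] / spec.baseline_rate_hz)
                            in_bin = (spk >= t0) & (spk < t0 + spec.comm_bin_s)
                            kill = in_bin & (rng.random(len(spk)) < p)
                            spk = spk[~kill]
            if extra:
                spk = np.concatenate([spk] + extra)
            area_spikes.append(spk)
        spikes[area] = area_spikes

    # planted assemblies: shared 20 ms synchronous windows
    assembly_truth = []
    for adef in spec.assembly_defs:
        ev = _assembly_event_times(adef, trials, ripple_times, duration_s, rng)
        for t in ev:
            participate = rng.random(len(adef.members)) < adef.participation_p
            jitter = rng.uniform(0, 0.02, size=len(adef.members))
            for m, p, j in zip(adef.members, participate, jitter):
                if p:
                    spikes[adef.area][m] = np.append(spikes[adef.area][m], t + j)
        w = np.zeros(areas[adef.area])
        w[list(adef.members)] = 1.0 / np.sqrt(len(adef.members))
        assembly_truth.append({"area": adef.area, "members": list(adef.members),
                               "weights": w, "ripple_coupling_p": adef.ripple_coupling_p,
                               "n_events": len(ev), "event_times": ev})

    for area in spikes:
        spikes[area] = [np.sort(np.clip(s, 0, duration_s)) for s in spikes[area]]
    return spikes, unit_class, assembly_truth


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _pink_noise(n: int, fs: float, sd_uv: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^2-like background: integrated white noise, high-passed at 0.5 Hz."""
    x = np.cumsum(rng.standard_normal(n))
    sos = signal.butter(2, 0.5, "highpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    s = x.std()
    if s > 0:
        x = x * (sd_uv / s)
    return x


def _ripple_profile(n_channels: int, peak: int, width: float = 1.5) -> np.ndarray:
    """Gaussian laminar amplitude profile, normalized so the peak channel
    keeps unit amplitude after common-average referencing."""
    ch = np.arange(n_channels)
    g = np.exp(-0.5 * ((ch - peak) / width) ** 2)
    return g / (g[peak] - g.mean())


def _insert_burst(data: np.ndarray, fs: float, t0: float, amp: float,
                  freq: float, profile: np.ndarray, rng: np.random.Generator,
                  env_sd_s: float = 0.015) -> None:
    half = int(3 * env_sd_s * fs)
    tt = np.arange(-half, half + 1) / fs
    env = np.exp(-0.5 * (tt / env_sd_s) ** 2)
    burst = amp * env * np.cos(2 * np.pi * freq * tt + rng.uniform(0, 2 * np.pi))
    i0 = int(round(t0 * fs)) - half
    lo, hi = max(i0, 0), min(i0 + len(tt), data.shape[1])
    if hi <= lo:
        return
    seg = burst[lo - i0: hi - i0]
    data[:, lo:hi] += profile[:, None] * seg[None, :]


def generate_lfp(spec: SessionSpec, ripple_times: np.ndarray,
                 artifact_times: np.ndarray, trials: pd.DataFrame,
                 duration_s: float, rng: np.random.Generator) -> dict:
    """CA1 multichannel + PFC single-channel LFP (µV).

    CA1 channels carry 1/f^2 background noise plus ripple-band bursts at
    the planted ripple times, with a Gaussian depth profile peaking on the
    designated channel; artifact bursts exceed the high-cut amplitude.
    The PFC channel shares a band-limited (gamma) component with CA1
    during trial stimulus+trace windows, creating coherence.
    """
    if spec.ripple_amp_uv <= 0:
        raise ValueError("ripple_amp_uv must be > 0")
    fs = spec.fs_lfp_hz
    n = int(round(duration_s * fs))
    nch = spec.n_lfp_channels_ca1
    ca1 = np.empty((nch, n), dtype=np.float64)
    for c in range(nch):
        ca1[c] = _pink_noise(n, fs, spec.lfp_noise_uv, rng) \
            + 3.0 * rng.standard_normal(n)

    profile = _ripple_profile(nch, spec.ripple_peak_channel)
    for t in ripple_times:
        _insert_burst(ca1, fs, t, spec.ripple_amp_uv, spec.ripple_freq_hz,
                      profile, rng)
    for t in artifact_times:
        _insert_burst(ca1, fs, t, spec.artifact_amp_uv, spec.ripple_freq_hz,
                      profile, rng, env_sd_s=0.012)

    pfc = _pink_noise(n, fs, spec.lfp_noise_uv, rng) + 3.0 * rng.standard_normal(n)

    if spec.coherence_gain_uv > 0 and len(trials):
        sos = signal.butter(4, spec.coherence_band_hz, "bandpass", fs=fs, output="sos")
        shared = signal.sosfiltfilt(sos, rng.standard_normal(n))
        s = shared.std()
        if s > 0:
            shared /= s
        gate = np.zeros(n)
        for o in trials["onset_s"]:
            a, b = int(o * fs), int((o + REWARD_DELAY_S) * fs)
            gate[max(a, 0):min(b, n)] = 1.0
        # smooth 50 ms on/off ramps to avoid spectral splatter
        ramp = signal.windows.hann(int(0.1 * fs) | 1)
        gate = signal.fftconvolve(gate, ramp / ramp.sum(), mode="same")
        comp = spec.coherence_gain_uv * shared * gate
        ca1 += comp[None, :]
        pfc += comp

    return {"ca1": LFPBlock(ca1.astype(np.float32), fs),
            "pfc": LFPBlock(pfc[None, :].astype(np.float32), fs)}


def generate_artifact_times(spec: SessionSpec, ripple_times: np.ndarray,
                            licks: np.ndarray, duration_s: float,
                            rng: np.random.Generator) -> np.ndarray:
    out = []
    guard = 0.4
    tries = 0
    while len(out) < spec.n_artifacts and tries < 1000:
        tries += 1
        t = rng.uniform(1.0, duration_s - 1.0)
        near = (len(ripple_times) and np.min(np.abs(ripple_times - t)) < guard) or \
               (len(licks) and np.min(np.abs(licks - t)) < guard) or \
               any(abs(t - o) < guard for o in out)
        if not near:
            out.append(t)
    return np.sort(np.asarray(out))


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def generate_session(spec: SessionSpec):
    """Compose a full synthetic session. Deterministic given ``spec.seed``.

    Returns ``(SessionBundle, GroundTruth)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    trials = generate_trial_schedule(spec, rng)
    duration = session_duration(trials, spec)
    licks, bouts = generate_licks(trials, spec.stage, rng, duration_s=duration)
    ripples = generate_ripple_times(spec, trials, licks, duration, rng)
    artifacts = generate_artifact_times(spec, ripples, licks, duration, rng)
    spikes, unit_class, assembly_truth = generate_spike_trains(
        spec, trials, licks, bouts, ripples, duration, rng)
    lfp = (generate_lfp(spec, ripples, artifacts, trials, duration, rng)
           if spec.with_lfp else {})
    bundle = SessionBundle(
        trials=trials, licks=licks, spikes=spikes, lfp=lfp,
        duration_s=duration,
        meta={"stage": spec.stage, "areas": sorted(spikes),
              "spec_hash": spec.spec_hash(), "seed": spec.seed,
              "synthetic": True})
    truth = GroundTruth(
        unit_class={a: list(v) for a, v in unit_class.items()},
        assembly_membership=assembly_truth,
        ripple_times_s=ripples,
        artifact_times_s=artifacts,
        planted_comm_rank=spec.comm_rank,
        lick_bout_onsets_s=bouts,
        learned=(spec.stage == "post"))
    truth.validate()
    return bundle, truth


# -- convenience spec factories --------------------------------------------

def default_assemblies(n_ca1: int = 34, n_pfc: int = 54) -> list:
    """Three CA1 + two PFC assemblies of six members each; one assembly per
    area is ripple-coupled.  The coupled CA1 assembly is CS--biased (less
    active in CS+ trials, i.e. CS+ suppressed), emulating the preferential
    ripple reactivation of CS+-suppressed hippocampal assemblies."""
    defs = [
        AssemblyDef("ca1", tuple(range(0, 6)), ripple_coupling_p=0.5,
                    bias_cs="minus"),
        AssemblyDef("ca1", tuple(range(6, 12)), ripple_coupling_p=0.0,
                    bias_cs="plus"),
        AssemblyDef("ca1", tuple(range(12, 18)), ripple_coupling_p=0.0),
        AssemblyDef("pfc", tuple(range(0, 6)), ripple_coupling_p=0.5),
        AssemblyDef("pfc", tuple(range(6, 12)), ripple_coupling_p=0.0),
    ]
    limits = {"ca1": n_ca1, "pfc": n_pfc}
    return [d for d in defs if max(d.members) < limits[d.area]]


def null_spec(seed: int = 0, **kw) -> SessionSpec:
    """Effect-free session: no response classes, no assemblies, no shared
    drive.  Used for false-positive calibration."""
    zero = {c: 0.0 for c in RESPONSE_CLASSES if c != "unmodulated"}
    kw.setdefault("response_fractions", {"ca1": dict(zero), "pfc": dict(zero)})
    kw.setdefault("stage", "pre")
    kw.setdefault("comm_rank", 0)
    kw.setdefault("with_lfp", False)
    return SessionSpec(seed=seed, **kw)
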