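"""Binning, smoothing, z-scoring, PSTHs and the single-cell response taxonomy.

Spiking is binned at 25 ms, smoothed with a Gaussian-weighted moving
average (25 bins), and z-scored against the pre-onset baseline of the
trial-averaged PSTH.  Units are classified by window scores: sound-evoked
(0-0.35 s), trace (2-3 s), reward (0-0.5 s post reward) and lick
(-0.25 to +0.25 s around the first anticipatory lick), with inclusive
+/-1 SD thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .behavior import first_anticipatory_lick
from .synthetic import SessionBundle

BIN_WIDTH_S = 0.025
SMOOTH_BINS = 25
CS_WINDOW = (-1.0, 4.0)
BASELINE_WINDOW = (-1.0, 0.0)
EVOKED_WINDOW = (0.0, 0.35)
TRACE_WINDOW = (2.0, 3.0)
REWARD_WINDOW = (3.0, 3.5)       # 0-0.5 s post reward (reward at +3 s)
LICK_WINDOW = (-0.25, 0.25)


@dataclass
class BinnedPopulation:
    """trials x bins x units firing-rate tensor with binning provenance."""

    rates: np.ndarray               # Hz
    bin_centers: np.ndarray         # s, relative to alignment event
    bin_width_s: float
    window: tuple
    smoothing: str
    alignment_times: np.ndarray

    @property
    def n_trials(self):
        return self.rates.shape[0]

    @property
    def n_units(self):
        return self.rates.shape[2]


def gaussian_ma_kernel(n_bins: int = SMOOTH_BINS) -> np.ndarray:
    """Normalized Gaussian-weighted moving-average kernel (sigma = n/5)."""
    k = signal.windows.gaussian(n_bins, std=n_bins / 5.0)
    return k / k.sum()


def bin_spikes(spikes, alignment_times, window, bin_width: float) -> np.ndarray:
    """Raw spike counts, trials x bins x units.  Bins are half-open [a, b)."""
    alignment_times = np.asarray(alignment_times, dtype=float)
    n_bins = int(round((window[1] - window[0]) / bin_width))
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    counts = np.zeros((len(alignment_times), n_bins, len(spikes)))
    for u, spk in enumerate(spikes):
        spk = np.asarray(spk)
        for t, t0 in enumerate(alignment_times):
            idx = np.searchsorted(spk, t0 + edges, side="left")
            counts[t, :, u] = np.diff(idx)
    return counts


def bin_and_smooth(spikes, alignment_times, window=CS_WINDOW,
                   bin_width: float = BIN_WIDTH_S,
                   smooth_bins: int = SMOOTH_BINS,
                   duration_s: float = None) -> BinnedPopulation:
    """Per-trial binned rates (Hz) convolved with the Gaussian MA kernel.

    The kernel is normalized and the convolution uses symmetric reflection
    padding, so the total count per trial is preserved.  Alignment events
    whose window exceeds the session bounds are dropped with a warning.
    """
    alignment_times = np.asarray(alignment_times, dtype=float)
    if duration_s is not None:
        ok = (alignment_times + window[0] >= 0) & (alignment_times + window[1] <= duration_s)
        if not ok.all():
            warnings.warn(f"dropping {int((~ok).sum())} trials whose window "
                          "exceeds the session bounds")
        alignment_times = alignment_times[ok]
    counts = bin_spikes(spikes, alignment_times, window, bin_width)
    if smooth_bins and smooth_bins > 1:
        kernel = gaussian_ma_kernel(smooth_bins)
        counts = ndimage.convolve1d(counts, kernel, axis=1, mode="reflect")
        smoothing = f"gaussian_ma_{smooth_bins}bins"
    else:
        smoothing = "none"
    n_bins = counts.shape[1]
    centers = window[0] + bin_width * (np.arange(n_bins) + 0.5)
    return BinnedPopulation(rates=counts / bin_width, bin_centers=centers,
                            bin_width_s=bin_width, window=tuple(window),
                            smoothing=smoothing, alignment_times=alignment_times)


def trial_average(pop: BinnedPopulation) -> np.ndarray:
    """Trial-averaged PSTH, bins x units (Hz)."""
    return pop.rates.mean(axis=0)


def zscore_to_baseline(psth: np.ndarray, bin_centers: np.ndarray,
                       baseline_window=BASELINE_WINDOW):
    """Z-score each unit's PSTH against its baseline bins.

    ``psth`` is bins x units (trial-averaged).  Returns ``(z, excluded)``
    where ``excluded`` marks units with zero baseline SD (their z columns
    are NaN rather than +/-inf).
    """
    mask = (bin_centers >= baseline_window[0]) & (bin_centers < baseline_window[1])
    if not mask.any():
        raise ValueError("no bins inside the baseline window")
    mu = psth[mask].mean(axis=0)
    sd = psth[mask].std(axis=0)
    excluded = sd == 0
    sd_safe = np.where(excluded, np.nan, sd)
    z = (psth - mu) / sd_safe
    return z, excluded


def _window_mean(z: np.ndarray, centers: np.ndarray, window) -> np.ndarray:
    mask = (centers >= window[0]) & (centers < window[1])
    return z[mask].mean(axis=0)


def classify_response_windows(bundle: SessionBundle, area: str,
                              first_licks: pd.Series = None) -> pd.DataFrame:
    """Window scores and response flags for every unit of one area.

    trace_up / trace_down: mean trace-window z >= +1 / <= -1 in either CS
    type (inclusive thresholds).  evoked flag: mean 0-350 ms z >= 1 in
    either CS type.  lick_up / lick_down: mean raw rate +/-250 ms around
    the first anticipatory lick at least one baseline-SD above / below the
    pretrial (-1 s to onset) raw-rate baseline; undefined (NaN flags) when
    no CS+ trial has an anticipatory lick.
    """
    spikes = bundle.spikes[area]
    trials = bundle.trials
    if first_licks is None:
        first_licks = first_anticipatory_lick(bundle)

    rows = {"unit_id": np.arange(len(spikes)), "area": area}
    per_cs = {}
    for cs in ("plus", "minus"):
        onsets = trials.loc[trials.cs_type == cs, "onset_s"].to_numpy()
        if len(onsets) == 0:
            continue
        pop = bin_and_smooth(spikes, onsets, duration_s=bundle.duration_s)
        psth = trial_average(pop)
        z, excluded = zscore_to_baseline(psth, pop.bin_centers)
        per_cs[cs] = dict(pop=pop, psth=psth, z=z, excluded=excluded)
        rows[f"evoked_{cs}"] = _window_mean(z, pop.bin_centers, EVOKED_WINDOW)
        rows[f"trace_{cs}"] = _window_mean(z, pop.bin_centers, TRACE_WINDOW)
        if cs == "plus":
            rows["reward"] = _window_mean(z, pop.bin_centers, REWARD_WINDOW)
            # raw-rate baseline statistics for the lick criterion: mean and
            # SD across trials of the per-trial baseline-window rate
            # (trial-count independent, unlike the SD over averaged bins)
            raw = bin_and_smooth(spikes, onsets, smooth_bins=0,
                                 duration_s=bundle.duration_s)
            bmask = (raw.bin_centers >= BASELINE_WINDOW[0]) \
                & (raw.bin_centers < BASELINE_WINDOW[1])
            per_trial = raw.rates[:, bmask, :].mean(axis=1)   # trials x units
            rows["baseline_mean_hz"] = per_trial.mean(axis=0)
            rows["baseline_sd_hz"] = per_trial.std(axis=0)
            rows["excluded"] = excluded

    df = pd.DataFrame(rows)
    for col in ("evoked_plus", "evoked_minus", "trace_plus", "trace_minus",
                "reward", "baseline_mean_hz", "baseline_sd_hz"):
        if col not in df:
            df[col] = np.nan
    if "excluded" not in df:
        df["excluded"] = False

    trace_p = df["trace_plus"].to_numpy()
    trace_m = df["trace_minus"].to_numpy()
    with np.errstate(invalid="ignore"):
        df["trace_up"] = (trace_p >= 1.0) | (trace_m >= 1.0)
        df["trace_down"] = (trace_p <= -1.0) | (trace_m <= -1.0)
        df["evoked"] = (df["evoked_plus"].to_numpy() >= 1.0) \
            | (df["evoked_minus"].to_numpy() >= 1.0)

    # lick classification on raw rates around the first anticipatory lick;
    # undefined unless enough trials carry an anticipatory bout (a one-trial
    # average would make the +/-1 SD rule pure noise)
    lick_times = first_licks.dropna().to_numpy()
    if len(lick_times) >= 5:
        lick_pop = bin_and_smooth(spikes, lick_times, window=(-0.5, 0.5),
                                  smooth_bins=0, duration_s=bundle.duration_s)
        lick_psth = trial_average(lick_pop)
        lick_rate = _window_mean(lick_psth, lick_pop.bin_centers, LICK_WINDOW)
        df["lick_rate_hz"] = lick_rate
        delta = lick_rate - df["baseline_mean_hz"].to_numpy()
        sd = df["baseline_sd_hz"].to_numpy()
        with np.errstate(invalid="ignore"):
            df["lick_up"] = delta >= sd
            df["lick_down"] = delta <= -sd
        df.loc[df["baseline_sd_hz"] == 0, ["lick_up", "lick_down"]] = False
    else:
        df["lick_rate_hz"] = np.nan
        df["lick_up"] = np.nan      # undefined: no anticipatory licks
        df["lick_down"] = np.nan
    df["is_lick_cell"] = df["lick_up"].eq(True) | df["lick_down"].eq(True)
    return df


def classify_cells(bundle: SessionBundle) -> pd.DataFrame:
    """Classification table for all recorded areas."""
    first_licks = first_anticipatory_lick(bundle)
    parts = [classify_response_windows(bundle, area, first_licks)
             for area in bundle.areas]
    df = pd.concat(parts, ignore_index=True)
    df["stage"] = bundle.meta.get("stage", "unknown")
    return df


def group_window_scores(tables) -> dict:
    """Group statistics of window scores across sessions.

    ``tables`` is an iterable of classification tables (each with ``area``
    and ``stage`` columns).  Returns ``{"stats": ..., "comparisons": ...}``:
    per (area, stage) mean +/- SEM of each window score (groups with fewer
    than two units are excluded), plus rank-based two-sample comparisons
    (CS+ vs CS- within stage; pre vs post within score).
    """
    df = pd.concat(list(tables), ignore_index=True)
    score_cols = ["evoked_plus", "evoked_minus", "trace_plus", "trace_minus", "reward"]
    stats_rows, comp_rows = [], []
    for (area, stage), g in df.groupby(["area", "stage"]):
        for col in score_cols:
            vals = g[col].dropna().to_numpy()
            if len(vals) < 2:
                continue
            stats_rows.append({"area": area, "stage": stage, "score": col,
                               "mean": vals.mean(),
                               "sem": vals.std(ddof=1) / np.sqrt(len(vals)),
                               "n": len(vals)})
        for pair in (("evoked_plus", "evoked_minus"), ("trace_plus", "trace_minus")):
            both = g[[pair[0], pair[1]]].dropna()
            a = both[pair[0]].to_numpy()
            b = both[pair[1]].to_numpy()
            if len(a) >= 2:
                s, p = stats.ranksums(a, b)
                # paired within-unit contrast: mean-sensitive, so a minority
                # of strongly responding cells can carry the group effect
                sp = (stats.ttest_rel(a, b).pvalue if np.any(a != b) else 1.0)
                comp_rows.append({"area": area, "stage": stage,
                                  "comparison": f"{pair[0]}_vs_{pair[1]}",
                                  "statistic": s, "p_value": p,
                                  "paired_p_value": float(sp),
                                  "direction": np.sign(a.mean() - b.mean())})
    for area, g in df.groupby("area"):
        for col in score_cols:
            pre = g.loc[g.stage == "pre", col].dropna().to_numpy()
            post = g.loc[g.stage == "post", col].dropna().to_numpy()
            if len(pre) >= 2 and len(post) >= 2:
                s, p = stats.ranksums(post, pre)
                comp_rows.append({"area": area, "stage": "pre_vs_post",
                                  "comparison": col, "statistic": s,
                                  "p_value": p,
                                  "direction": np.sign(post.mean() - pre.mean())})
    return {"stats": pd.DataFrame(stats_rows),
            "comparisons": pd.DataFrame(comp_rows)}
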