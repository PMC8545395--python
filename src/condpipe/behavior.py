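"""Lick-based learning classification and anticipatory-lick detection.

A session counts as learned when the per-trial change in lick count
(trace-period count minus pre-onset baseline count) is significantly
higher on CS+ than on CS- trials (two-sample t-test, alpha = 0.05, with
the CS+ > CS- direction required).  The first anticipatory lick of a CS+
trial is the first lick after CS onset and before reward delivery that is
followed by at least three further licks within one second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CS_DUR_S, REWARD_DELAY_S, SessionBundle

TRACE_WINDOW = (CS_DUR_S, REWARD_DELAY_S)     # 2-3 s post onset
BASELINE_WINDOW = (-1.0, 0.0)


@dataclass
class LickAnalysis:
    lick_change: np.ndarray            # per trial
    cs_labels: np.ndarray
    learned: bool
    p_value: float
    first_anticipatory_lick_s: pd.Series   # indexed by CS+ trial index; NaN = absent


def _count_in(licks: np.ndarray, lo: float, hi: float) -> int:
    """Licks in the half-open interval [lo, hi)."""
    return int(np.searchsorted(licks, hi, side="left")
               - np.searchsorted(licks, lo, side="left"))


def lick_rate_change_per_trial(bundle: SessionBundle) -> np.ndarray:
    """Per-trial (trace-period lick count) - (baseline lick count).

    Windows are half-open [a, b) relative to CS onset: trace is
    [onset+2, onset+3), baseline is [onset-1, onset).
    """
    licks = np.sort(np.asarray(bundle.licks, dtype=float))
    out = np.empty(len(bundle.trials), dtype=float)
    for i, onset in enumerate(bundle.trials["onset_s"]):
        trace = _count_in(licks, onset + TRACE_WINDOW[0], onset + TRACE_WINDOW[1])
        base = _count_in(licks, onset + BASELINE_WINDOW[0], onset + BASELINE_WINDOW[1])
        out[i] = trace - base
    return out


def classify_session_learning(changes: np.ndarray, cs_labels: np.ndarray,
                              alpha: float = 0.05):
    """Two-sample t-test of CS+ vs CS- lick-rate changes.

    Returns ``(learned, p_value)``; learned requires both p < alpha and a
    CS+ mean above the CS- mean.  Degenerate zero-variance comparisons of
    identical constant groups yield p = 1.
    """
    changes = np.asarray(changes, dtype=float)
    cs_labels = np.asarray(cs_labels)
    plus = changes[cs_labels == "plus"]
    minus = changes[cs_labels == "minus"]
    if len(plus) < 2 or len(minus) < 2:
        raise ValueError("need >= 2 trials of each CS type for the learning t-test")
    t, p = stats.ttest_ind(plus, minus)
    if np.isnan(p):   # both groups constant
        p = 1.0 if plus.mean() == minus.mean() else 0.0
    learned = bool(p < alpha and plus.mean() > minus.mean())
    return learned, float(p)


def first_anticipatory_lick(bundle: SessionBundle,
                            min_followers: int = 3,
                            follower_window_s: float = 1.0) -> pd.Series:
    """First anticipatory lick per CS+ trial (NaN when absent).

    Candidate licks lie in [onset, reward); a candidate qualifies when at
    least ``min_followers`` further licks fall within ``follower_window_s``
    after it.  Follower licks may occur after reward delivery.
    """
    licks = np.sort(np.asarray(bundle.licks, dtype=float))
    trials = bundle.trials
    idx = trials.index[trials.cs_type == "plus"]
    out = pd.Series(np.nan, index=idx, dtype=float)
    for i in idx:
        onset = trials.loc[i, "onset_s"]
        reward = trials.loc[i, "reward_time_s"]
        if np.isnan(reward):
            reward = onset + REWARD_DELAY_S
        lo = np.searchsorted(licks, onset, side="left")
        hi = np.searchsorted(licks, reward, side="left")
        for j in range(lo, hi):
            t = licks[j]
            n_follow = np.searchsorted(licks, t + follower_window_s, side="right") - (j + 1)
            if n_follow >= min_followers:
                out.loc[i] = t
                break
    return out


def analyze_behavior(bundle: SessionBundle, alpha: float = 0.05) -> LickAnalysis:
    changes = lick_rate_change_per_trial(bundle)
    labels = bundle.trials["cs_type"].to_numpy()
    learned, p = classify_session_learning(changes, labels, alpha=alpha)
    fal = first_anticipatory_lick(bundle)
    return LickAnalysis(lick_change=changes, cs_labels=labels,
                        learned=learned, p_value=p,
                        first_anticipatory_lick_s=fal)
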