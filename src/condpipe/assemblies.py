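"""Cell-assembly detection (ICA with Marcenko-Pastur threshold) and
ripple-triggered reactivation analysis.

Spikes from every trial (-1 to 4 s around CS onset) are binned at 20 ms
and z-scored per unit; the number of assemblies is the number of
eigenvalues of the unit correlation matrix exceeding the analytic
Marcenko-Pastur upper edge ``(1 + sqrt(n_units / n_bins))**2``.
Independent-component extraction in the significant principal subspace
yields one unit-weight pattern per assembly (unit norm, largest-|weight|
entry positive).  Assembly expression at time t is the quadratic form
``z^T P z`` of z-scored binned activity with the pattern's outer-product
projector whose diagonal is zeroed, evaluated on sliding 20 ms bins with
10 ms overlap.  Reactivation is the mean z-scored activation in a 50 ms
window centered on each awake ripple, with the z baseline computed from
inter-trial samples excluding the ripple centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats
from sklearn.decomposition import FastICA

from .synthetic import SessionBundle, TRIAL_SPAN_S, TRIAL_PRE_S

ASSEMBLY_BIN_S = 0.020
ASSEMBLY_STEP_S = 0.010
ASSEMBLY_WINDOW = (-1.0, 4.0)
RIPPLE_CENTER_S = 0.050          # reactivation window width
STIM_BASELINE = (-1.0, 0.0)
PERIODS = {"baseline": (-1.0, 0.0), "stim": (0.0, 2.0),
           "trace": (2.0, 3.0), "reward": (3.0, 3.5)}


def mp_bound(n_units: int, n_bins: int) -> float:
    """Marcenko-Pastur upper eigenvalue edge (1 + sqrt(n/B))^2."""
    if n_bins <= n_units:
        raise ValueError("need more bins than units for the MP bound")
    return (1.0 + np.sqrt(n_units / n_bins)) ** 2


@dataclass
class AssemblyModel:
    patterns: np.ndarray            # n_assemblies x n_units, unit norm
    mp_lambda_max: float
    eigenvalues: np.ndarray
    unit_mean: np.ndarray           # training binning statistics (counts/bin)
    unit_sd: np.ndarray
    bin_width_s: float
    window: tuple
    area: str

    @property
    def n_assemblies(self):
        return self.patterns.shape[0]

    @property
    def n_units(self):
        return self.patterns.shape[1]


def _bin_trials(spikes, onsets, window, bin_width) -> np.ndarray:
    """Concatenated per-trial binned counts: (trials*bins) x units."""
    n_bins = int(round((window[1] - window[0]) / bin_width))
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    out = np.empty((len(onsets) * n_bins, len(spikes)))
    for u, spk in enumerate(spikes):
        for t, o in enumerate(onsets):
            idx = np.searchsorted(spk, o + edges, side="left")
            out[t * n_bins:(t + 1) * n_bins, u] = np.diff(idx)
    return out


def _sign_align(patterns: np.ndarray) -> np.ndarray:
    out = patterns.copy()
    for i, p in enumerate(out):
        if p[np.argmax(np.abs(p))] < 0:
            out[i] = -p
    return out


def extract_patterns(Z: np.ndarray, n_sig: int, eigvecs: np.ndarray,
                     seed: int = 0, n_restarts: int = 5) -> np.ndarray:
    """ICA patterns in the significant principal subspace.

    ``Z`` is (bins x units) z-scored activity, ``eigvecs`` the top
    ``n_sig`` correlation-matrix eigenvectors.  The extraction is
    restarted ``n_restarts`` times keeping the run with maximal summed
    source kurtosis.  Patterns are unit-norm, sign-aligned rows.
    """
    V = eigvecs[:, :n_sig]
    Y = Z @ V
    best, best_k = None, -np.inf
    for r in range(n_restarts):
        ica = FastICA(n_components=n_sig, random_state=seed * 1000 + r,
                      max_iter=1000, tol=1e-4, whiten="unit-variance")
        try:
            S = ica.fit_transform(Y)
        except Exception:
            continue
        k = np.sum(stats.kurtosis(S, axis=0))
        if k > best_k:
            best_k = k
            best = ica.mixing_
    if best is None:                # ICA failed: fall back to the PCs
        best = np.eye(n_sig)
    patterns = (V @ best).T
    norms = np.linalg.norm(patterns, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return _sign_align(patterns / norms)


def detect_assemblies(bundle: SessionBundle, area: str,
                      window=ASSEMBLY_WINDOW, bin_width: float = ASSEMBLY_BIN_S,
                      seed: int = 0, onsets=None) -> AssemblyModel:
    """Detect co-activation patterns in concatenated trial activity.

    ``onsets=None`` uses all trial onsets; passing explicit times allows
    the inter-trial-interval variant of the analysis.
    """
    spikes = bundle.spikes[area]
    if len(spikes) < 2:
        raise ValueError("need >= 2 units")
    if onsets is None:
        onsets = bundle.trials["onset_s"].to_numpy()
    if len(onsets) < 1:
        raise ValueError("need >= 1 trial")
    counts = _bin_trials(spikes, onsets, window, bin_width)
    mu = counts.mean(axis=0)
    sd = counts.std(axis=0)
    active = sd > 0
    Z = np.zeros_like(counts)
    Z[:, active] = (counts[:, active] - mu[active]) / sd[active]
    B, n = Z.shape
    corr = (Z.T @ Z) / B
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    lam_max = mp_bound(int(active.sum()), B)
    n_sig = int(np.sum(eigvals > lam_max))
    if n_sig == 0:
        patterns = np.empty((0, n))
    else:
        patterns = extract_patterns(Z, n_sig, eigvecs, seed=seed)
    return AssemblyModel(patterns=patterns, mp_lambda_max=lam_max,
                         eigenvalues=eigvals, unit_mean=mu, unit_sd=sd,
                         bin_width_s=bin_width, window=tuple(window), area=area)


# ---------------------------------------------------------------------------
# activation
# ---------------------------------------------------------------------------

def activation_strength(z: np.ndarray, pattern: np.ndarray) -> float:
    """Quadratic form z^T P z with P = w w^T and zeroed diagonal.

    Zero whenever z has at most one nonzero entry (single-unit activity
    cannot express an assembly).
    """
    z = np.asarray(z, dtype=float)
    w = np.asarray(pattern, dtype=float)
    proj = z @ w
    return float(proj * proj - np.sum((z * w) ** 2))


@dataclass
class ActivationTrace:
    times: np.ndarray               # bin centers (s)
    activation: np.ndarray          # n_assemblies x n_times
    bin_width_s: float
    step_s: float


def assembly_activation(model: AssemblyModel, spikes, t_start: float,
                        t_stop: float, step: float = ASSEMBLY_STEP_S) -> ActivationTrace:
    """Assembly expression on sliding bins (20 ms width, 10 ms step).

    Activity is z-scored with the model's training statistics;
    ``A_k(t) = z^T P_k z`` with the projector diagonal zeroed.
    """
    if len(spikes) != model.n_units:
        raise ValueError("unit count mismatch with model")
    if model.n_assemblies == 0:
        times = np.arange(t_start, t_stop - model.bin_width_s, step) + model.bin_width_s / 2
        return ActivationTrace(times, np.empty((0, len(times))),
                               model.bin_width_s, step)
    # counts on step-width sub-bins, summed pairwise for overlapping bins
    n_sub = int(np.floor((t_stop - t_start) / step))
    edges = t_start + step * np.arange(n_sub + 1)
    sub = np.empty((n_sub, model.n_units))
    for u, spk in enumerate(spikes):
        idx = np.searchsorted(spk, edges, side="left")
        sub[:, u] = np.diff(idx)
    k = int(round(model.bin_width_s / step))
    counts = sub[:n_sub - k + 1].copy()
    for j in range(1, k):
        counts += sub[j:n_sub - k + 1 + j]
    active = model.unit_sd > 0
    Z = np.zeros_like(counts)
    Z[:, active] = (counts[:, active] - model.unit_mean[active]) / model.unit_sd[active]
    times = edges[:n_sub - k + 1] + model.bin_width_s / 2
    P = model.patterns
    proj = Z @ P.T                                  # times x assemblies
    diag = (Z ** 2) @ (P.T ** 2)
    act = (proj ** 2 - diag).T
    return ActivationTrace(times=times, activation=act,
                           bin_width_s=model.bin_width_s, step_s=step)


def _iti_mask(times: np.ndarray, trials: pd.DataFrame) -> np.ndarray:
    mask = np.ones(len(times), dtype=bool)
    for o in trials["onset_s"]:
        mask &= ~((times >= o - TRIAL_PRE_S) & (times < o + TRIAL_SPAN_S))
    return mask


# ---------------------------------------------------------------------------
# ripple-triggered reactivation
# ---------------------------------------------------------------------------

@dataclass
class ReactivationSummary:
    per_ripple: np.ndarray          # n_assemblies x n_ripples (z)
    mean_reactivation: np.ndarray   # n_assemblies
    triggered: np.ndarray           # n_assemblies x n_offsets (z, smoothed)
    offsets: np.ndarray
    ripple_times: np.ndarray


def swr_triggered_reactivation(trace: ActivationTrace, ripple_times,
                               trials: pd.DataFrame, window: float = 1.0,
                               smooth_s: float = 0.1) -> ReactivationSummary:
    """Ripple-triggered assembly reactivation (ITI ripples).

    Activation is z-scored using inter-trial samples outside the 50 ms
    ripple-center windows; the per-ripple reactivation is the mean z in
    the centered 50 ms window; triggered averages are smoothed with a
    100 ms Gaussian window.
    """
    ripple_times = np.asarray(ripple_times, dtype=float)
    iti = _iti_mask(trace.times, trials)
    ripple_times = ripple_times[_iti_mask(ripple_times, trials)]
    n_off = int(round(window / trace.step_s))
    offsets = trace.step_s * np.arange(-n_off, n_off + 1)
    if len(ripple_times) == 0:
        empty = np.empty((trace.activation.shape[0], 0))
        return ReactivationSummary(empty, np.full(trace.activation.shape[0], np.nan),
                                   np.empty((trace.activation.shape[0], len(offsets))),
                                   offsets, ripple_times)
    half = RIPPLE_CENTER_S / 2
    near_ripple = np.zeros(len(trace.times), dtype=bool)
    for t in ripple_times:
        near_ripple |= np.abs(trace.times - t) <= half
    base = iti & ~near_ripple
    mu = trace.activation[:, base].mean(axis=1)
    sd = trace.activation[:, base].std(axis=1)
    sd[sd == 0] = 1.0
    z = (trace.activation - mu[:, None]) / sd[:, None]

    t0 = trace.times[0]
    idx = np.round((ripple_times[:, None] + offsets[None, :] - t0)
                   / trace.step_s).astype(int)
    idx = np.clip(idx, 0, len(trace.times) - 1)
    trig = z[:, idx]                                # assemblies x ripples x offsets
    center = np.abs(offsets) <= half
    per_ripple = trig[:, :, center].mean(axis=2)
    avg = trig.mean(axis=1)
    sigma_bins = (smooth_s / trace.step_s) / 5.0
    smoothed = ndimage.gaussian_filter1d(avg, sigma=sigma_bins, axis=1,
                                         mode="reflect")
    return ReactivationSummary(per_ripple=per_ripple,
                               mean_reactivation=per_ripple.mean(axis=1),
                               triggered=smoothed, offsets=offsets,
                               ripple_times=ripple_times)


# ---------------------------------------------------------------------------
# stimulus-aligned activation and modulation scores
# ---------------------------------------------------------------------------

def stimulus_triggered_activation(trace: ActivationTrace, trials: pd.DataFrame):
    """CS-aligned, z-scored assembly activation and per-period means.

    The z baseline is the pre-stimulus period (-1 to 0 s) of both CS
    types.  Returns per-CS aligned traces, per-trial period means, and
    CS+ vs CS- (signed-rank, across assemblies) plus vs-zero (t-test)
    comparisons for each period.
    """
    if not {"plus", "minus"} <= set(trials.cs_type):
        raise ValueError("both CS types must be present")
    n_off = int(round((ASSEMBLY_WINDOW[1] - ASSEMBLY_WINDOW[0]) / trace.step_s))
    offsets = ASSEMBLY_WINDOW[0] + trace.step_s * np.arange(n_off)
    t0 = trace.times[0]
    onsets_all = trials["onset_s"].to_numpy()
    idx = np.round((onsets_all[:, None] + offsets[None, :] - t0)
                   / trace.step_s).astype(int)
    idx = np.clip(idx, 0, len(trace.times) - 1)
    aligned = trace.activation[:, idx]              # assemblies x trials x offsets

    base_mask = (offsets >= STIM_BASELINE[0]) & (offsets < STIM_BASELINE[1])
    base = aligned[:, :, base_mask]
    mu = base.mean(axis=(1, 2))
    sd = base.std(axis=(1, 2))
    sd[sd == 0] = 1.0
    aligned_z = (aligned - mu[:, None, None]) / sd[:, None, None]

    cs = trials["cs_type"].to_numpy()
    out = {"offsets": offsets, "aligned": {}, "period_means": {},
           "comparisons": {}}
    for c in ("plus", "minus"):
        sel = cs == c
        out["aligned"][c] = aligned_z[:, sel].mean(axis=1)
        out["period_means"][c] = {
            name: aligned_z[:, sel][:, :, (offsets >= w[0]) & (offsets < w[1])]
            .mean(axis=(1, 2))
            for name, w in PERIODS.items()}
    for name in PERIODS:
        a = out["period_means"]["plus"][name]
        b = out["period_means"]["minus"][name]
        comp = {}
        if len(a) >= 2 and np.any(a != b):
            comp["signed_rank_p"] = float(stats.wilcoxon(a, b).pvalue)
        if len(a) >= 2 and a.std() > 0:
            comp["vs_zero_p_plus"] = float(stats.ttest_1samp(a, 0.0).pvalue)
        out["comparisons"][name] = comp
    return out


def per_trial_activation(trace: ActivationTrace, trials: pd.DataFrame,
                         period=(0.0, 3.0)) -> np.ndarray:
    """Mean activation per (assembly, trial) within a window rel. onset."""
    onsets = trials["onset_s"].to_numpy()
    out = np.empty((trace.activation.shape[0], len(onsets)))
    for t, o in enumerate(onsets):
        m = (trace.times >= o + period[0]) & (trace.times < o + period[1])
        out[:, t] = trace.activation[:, m].mean(axis=1) if m.any() else np.nan
    return out


def modulation_scores(trace: ActivationTrace, trials: pd.DataFrame,
                      period=(0.0, 3.0)):
    """Trial-type and trial-period modulation scores per assembly.

    Trial-type score: mean activation in CS+ trials minus CS- trials over
    the stimulus+trace period.  Trial-period score (CS- trials only):
    mean stimulus-period minus mean trace-period activation.
    """
    if not {"plus", "minus"} <= set(trials.cs_type):
        raise ValueError("both CS types must be present")
    per_trial = per_trial_activation(trace, trials, period)
    cs = trials["cs_type"].to_numpy()
    trial_type = per_trial[:, cs == "plus"].mean(axis=1) \
        - per_trial[:, cs == "minus"].mean(axis=1)
    minus_trials = trials[trials.cs_type == "minus"]
    stim = per_trial_activation(trace, minus_trials, PERIODS["stim"])
    tr = per_trial_activation(trace, minus_trials, PERIODS["trace"])
    trial_period = stim.mean(axis=1) - tr.mean(axis=1)
    return {"trial_type": trial_type, "trial_period": trial_period}


def select_extreme_assemblies(scores: np.ndarray):
    """Most negative (CS+ suppressed), most positive (CS- suppressed) and
    least-|score| (nonmodulated) assembly indices; flagged when fewer than
    three assemblies exist."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n == 0:
        return {"flagged": True}
    sel = {"cs_plus_suppressed": int(np.argmin(scores)),
           "cs_minus_suppressed": int(np.argmax(scores)),
           "nonmodulated": int(np.argmin(np.abs(scores))),
           "flagged": n < 3}
    return sel


def reactivation_vs_modulation(mean_reactivation, scores):
    """Pearson correlation between trial-type modulation score and mean
    ripple reactivation, pooled across assemblies."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(mean_reactivation, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 assemblies for the correlation")
    if x.std() == 0 or y.std() == 0:
        return {"r": np.nan, "p": np.nan, "flagged": True}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "flagged": False}


# ---------------------------------------------------------------------------
# within-session dynamics
# ---------------------------------------------------------------------------

def block_dynamics(summary: ReactivationSummary, trials: pd.DataFrame,
                   duration_s: float, n_blocks: int = 10):
    """Reactivation per equal-trial block for reactivation+/- groups.

    Blocks partition the trials into ``n_blocks`` contiguous groups with
    sizes differing by at most one; each ITI ripple is assigned to the
    block whose time span contains it.  Assemblies are grouped by the
    sign of their session-mean reactivation and the first-3 vs last-3
    block contrast is tested with a signed-rank test per group.
    """
    onsets = trials["onset_s"].to_numpy()
    if len(onsets) < n_blocks:
        raise ValueError(f"need >= {n_blocks} trials")
    splits = np.array_split(np.arange(len(onsets)), n_blocks)
    bounds = [0.0] + [onsets[s[0]] for s in splits[1:]] + [duration_s]
    block_of = np.digitize(summary.ripple_times, bounds) - 1
    block_of = np.clip(block_of, 0, n_blocks - 1)
    n_asm = summary.per_ripple.shape[0]
    per_block = np.full((n_asm, n_blocks), np.nan)
    for b in range(n_blocks):
        sel = block_of == b
        if sel.any():
            per_block[:, b] = summary.per_ripple[:, sel].mean(axis=1)
    groups = {"reactivation+": summary.mean_reactivation > 0,
              "reactivation-": summary.mean_reactivation < 0}
    tests = {}
    for name, g in groups.items():
        if g.sum() == 0:
            continue
        first = np.nanmean(per_block[g][:, :3], axis=1)
        last = np.nanmean(per_block[g][:, -3:], axis=1)
        ok = np.isfinite(first) & np.isfinite(last)
        entry = {"first3": first, "last3": last, "n": int(ok.sum())}
        if ok.sum() >= 2 and np.any(first[ok] != last[ok]):
            entry["signed_rank_p"] = float(stats.wilcoxon(first[ok], last[ok]).pvalue)
        tests[name] = entry
    return {"per_block": per_block, "block_bounds": bounds, "groups": groups,
            "tests": tests}


# ---------------------------------------------------------------------------
# significance and cross-area coactivation
# ---------------------------------------------------------------------------

def significant_reactivation_fraction(per_ripple_values):
    """Fraction of per-ripple reactivations above median + 2 SD, with the
    SD estimated robustly as 1.4826 * MAD.

    MAD = 0 falls back to the fraction strictly above the median (flagged).
    """
    v = np.asarray(per_ripple_values, dtype=float)
    if len(v) < 10:
        raise ValueError("need >= 10 ripples")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return float(np.mean(v > med)), True
    sd = 1.4826 * mad
    return float(np.mean(v > med + 2 * sd)), False


def quadrant_coactivation(ca1_per_ripple: np.ndarray,
                          pfc_per_ripple: np.ndarray):
    """Median-split joint reactivation of every CA1 x PFC assembly pair.

    %Q1: both areas above their medians; %Q2: CA1 above, PFC below.
    Returns the per-pair table and a paired signed-rank p over pairs.
    """
    ca1 = np.atleast_2d(np.asarray(ca1_per_ripple, dtype=float))
    pfc = np.atleast_2d(np.asarray(pfc_per_ripple, dtype=float))
    if ca1.shape[1] != pfc.shape[1]:
        raise ValueError("areas must share the ripple event list")
    if ca1.shape[1] < 10:
        raise ValueError("need >= 10 shared ripples")
    rows = []
    for i, x in enumerate(ca1):
        mx = np.median(x)
        hx = x > mx
        for j, y in enumerate(pfc):
            my = np.median(y)
            hy = y > my
            rows.append({"ca1_assembly": i, "pfc_assembly": j,
                         "q1_pct": 100.0 * np.mean(hx & hy),
                         "q2_pct": 100.0 * np.mean(hx & ~hy)})
    table = pd.DataFrame(rows)
    q1, q2 = table["q1_pct"].to_numpy(), table["q2_pct"].to_numpy()
    if len(q1) >= 2 and np.any(q1 != q2):
        p = float(stats.wilcoxon(q1, q2).pvalue)
    else:
        p = np.nan
    return {"pairs": table, "q1_mean_pct": float(q1.mean()),
            "q2_mean_pct": float(q2.mean()), "signed_rank_p": p}


# ---------------------------------------------------------------------------
# pattern-recovery utilities
# ---------------------------------------------------------------------------

def match_patterns(detected: np.ndarray, truth: np.ndarray):
    """Greedy bipartite matching of detected patterns to ground truth by
    |cosine similarity| (sign-aligned); ties broken by magnitude."""
    if len(detected) == 0 or len(truth) == 0:
        return []
    sim = np.abs(detected @ truth.T) / (
        np.linalg.norm(detected, axis=1)[:, None]
        * np.linalg.norm(truth, axis=1)[None, :])
    pairs = []
    used_d, used_t = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(-sim, axis=None), sim.shape))[0]
    for d, t in order:
        if d in used_d or t in used_t:
            continue
        pairs.append((int(d), int(t), float(sim[d, t])))
        used_d.add(d)
        used_t.add(t)
    return pairs
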