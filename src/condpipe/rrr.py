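"""Reduced-rank regression (RRR) between and within CA1 and PFC populations.

For each of ten random subsamples, each area's units are split into
disjoint source and target sets (all four sets equally sized).  Spike
counts in 100 ms bins within a task period (baseline, stim, trace,
reward) are mean-centered and regressed target-on-source with 10-fold
cross-validation across a full grid of ranks; the reduced-rank estimator
projects the OLS predictions onto the top principal components of the
fitted values.  The selected rank ("number of predictive dimensions") is
the smallest whose mean cross-validated R^2 lies within one SEM of the
best rank's.  A penalized full-rank regression over a swept penalty grid
serves as control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, Ridge
from sklearn.model_selection import KFold

from .synthetic import SessionBundle, TRIAL_PRE_S

PERIODS = {"baseline": (-1.0, 0.0), "stim": (0.0, 2.0),
           "trace": (2.0, 3.0), "reward": (3.0, 3.5)}
RRR_BIN_S = 0.1
PENALTY_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)


def subsample_quadruple(units_ca1, units_pfc, rng):
    """Random disjoint source/target split per area, all four sets of equal
    size m = min over areas of floor(N/2)."""
    units_ca1 = np.asarray(units_ca1)
    units_pfc = np.asarray(units_pfc)
    m = min(len(units_ca1) // 2, len(units_pfc) // 2)
    if m < 2:
        raise ValueError(f"subsample size {m} < 2: too few units")
    perm_c = rng.permutation(units_ca1)
    perm_p = rng.permutation(units_pfc)
    return {"ca1": {"source": np.sort(perm_c[:m]), "target": np.sort(perm_c[m:2 * m])},
            "pfc": {"source": np.sort(perm_p[:m]), "target": np.sort(perm_p[m:2 * m])}}


def period_activity(bundle: SessionBundle, area: str, period: str,
                    unit_ids=None, bin_s: float = RRR_BIN_S) -> np.ndarray:
    """Mean-centered spike counts (samples x units) in a task period.

    Counts in ``bin_s`` bins within the period window of every trial,
    concatenated across trials.
    """
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}")
    lo, hi = PERIODS[period]
    n_bins = int(round((hi - lo) / bin_s))
    if n_bins == 0:
        raise ValueError("empty period")
    onsets = bundle.trials["onset_s"].to_numpy()
    if len(onsets) == 0:
        raise ValueError("no trials")
    if unit_ids is None:
        unit_ids = np.arange(len(bundle.spikes[area]))
    edges = lo + bin_s * np.arange(n_bins + 1)
    X = np.empty((len(onsets) * n_bins, len(unit_ids)))
    for j, u in enumerate(unit_ids):
        spk = bundle.spikes[area][u]
        for t, o in enumerate(onsets):
            idx = np.searchsorted(spk, o + edges, side="left")
            X[t * n_bins:(t + 1) * n_bins, j] = np.diff(idx)
    return X - X.mean(axis=0)


def _ols_fit(X: np.ndarray, Y: np.ndarray):
    """OLS coefficients with ridge jitter on the Gram matrix if singular."""
    G = X.T @ X
    singular = np.linalg.matrix_rank(G) < G.shape[0]
    if singular:
        G = G + 1e-8 * np.eye(G.shape[0])
    B = np.linalg.solve(G, X.T @ Y)
    return B, singular


def rrr_cv_curve(X: np.ndarray, Y: np.ndarray, ranks=None, folds: int = 10,
                 seed: int = 0):
    """Cross-validated R^2 per rank.

    Per fold, OLS is fitted on the training split; predictions at rank r
    are the OLS predictions projected onto the top-r principal components
    of the training fitted values.  At full rank the projector is the
    identity and the estimator equals OLS.  Returns
    ``(ranks, r2_matrix[ranks x folds], singular_flag)``.
    """
    n, p = X.shape
    if n < folds:
        raise ValueError("need at least as many samples as folds")
    max_rank = min(p, Y.shape[1])
    if ranks is None:
        ranks = np.arange(1, max_rank + 1)
    ranks = np.asarray(ranks)
    if ranks.max() > max_rank:
        raise ValueError("rank exceeds min(source units, target units)")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    r2 = np.empty((len(ranks), folds))
    any_singular = False
    for f, (tr, te) in enumerate(kf.split(X)):
        Xtr, Ytr = X[tr], Y[tr]
        Xte, Yte = X[te], Y[te]
        mx, my = Xtr.mean(0), Ytr.mean(0)
        Xtr, Ytr = Xtr - mx, Ytr - my
        Xte, Yte = Xte - mx, Yte - my
        B, singular = _ols_fit(Xtr, Ytr)
        any_singular |= singular
        fitted = Xtr @ B
        _, _, Vt = np.linalg.svd(fitted, full_matrices=False)
        ss_tot = np.sum((Yte - Yte.mean(0)) ** 2)
        pred_full = Xte @ B
        for ri, r in enumerate(ranks):
            pred = pred_full @ Vt[:r].T @ Vt[:r] if r < Vt.shape[0] else pred_full
            r2[ri, f] = 1.0 - np.sum((Yte - pred) ** 2) / ss_tot
    return ranks, r2, any_singular


def fit_rrr(X: np.ndarray, Y: np.ndarray, rank: int, folds: int = 10,
            seed: int = 0) -> np.ndarray:
    """Per-fold held-out R^2 of the reduced-rank estimator at one rank."""
    _, r2, _ = rrr_cv_curve(X, Y, ranks=[rank], folds=folds, seed=seed)
    return r2[0]


def select_rank(mean_r2: np.ndarray, sem_r2: np.ndarray, ranks=None) -> int:
    """Smallest rank whose mean performance is within one SEM of the best."""
    mean_r2 = np.asarray(mean_r2, dtype=float)
    sem_r2 = np.asarray(sem_r2, dtype=float)
    if len(mean_r2) == 0:
        raise ValueError("no ranks evaluated")
    if ranks is None:
        ranks = np.arange(1, len(mean_r2) + 1)
    best = int(np.argmax(mean_r2))
    thr = mean_r2[best] - sem_r2[best]
    idx = int(np.argmax(mean_r2 >= thr))
    return int(np.asarray(ranks)[idx])


def full_rank_control(X: np.ndarray, Y: np.ndarray, folds: int = 10,
                      seed: int = 0, l1_ratio: float = 0.0,
                      penalties=PENALTY_GRID):
    """Penalized full-rank regression: penalty chosen by highest mean CV
    R^2; reports the held-out MSE of the winning model.

    ``l1_ratio=0`` gives pure L2 (ridge); ``l1_ratio>0`` switches to an
    elastic-style penalty with that L1 mixing weight.
    """
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    results = []
    for alpha in penalties:
        r2s, mses = [], []
        for tr, te in kf.split(X):
            if l1_ratio > 0:
                model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=5000)
            else:
                model = Ridge(alpha=alpha)
            model.fit(X[tr], Y[tr])
            pred = model.predict(X[te])
            resid = Y[te] - pred
            ss_tot = np.sum((Y[te] - Y[te].mean(0)) ** 2)
            r2s.append(1.0 - np.sum(resid ** 2) / ss_tot)
            mses.append(np.mean(resid ** 2))
        results.append((alpha, np.mean(r2s), np.mean(mses)))
    best = max(results, key=lambda t: t[1])
    return {"alpha": best[0], "cv_r2": best[1], "cv_mse": best[2]}


def crossarea_analysis(bundle: SessionBundle, n_subsamples: int = 10,
                       folds: int = 10, seed: int = 0,
                       periods=None, max_rank: int = None) -> pd.DataFrame:
    """RRR over {CA1->CA1, CA1->PFC, PFC->PFC, PFC->CA1} x task periods.

    Each subsample replicate draws a fresh disjoint quadruple of unit
    sets (independent RNG substream per replicate) and fits the rank
    curve plus the penalized full-rank control.  With a single recorded
    area only the within-area regressions are computed (flagged).
    """
    if periods is None:
        periods = list(PERIODS)
    areas = bundle.areas
    both = "ca1" in areas and "pfc" in areas
    pairs = ([("ca1", "ca1"), ("ca1", "pfc"), ("pfc", "pfc"), ("pfc", "ca1")]
             if both else [(a, a) for a in areas])
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_subsamples)]
    rows = []
    for rep, rng in enumerate(streams):
        if both:
            quad = subsample_quadruple(np.arange(bundle.n_units("ca1")),
                                       np.arange(bundle.n_units("pfc")), rng)
        else:
            a = areas[0]
            n = bundle.n_units(a)
            m = n // 2
            if m < 2:
                raise ValueError("too few units")
            perm = rng.permutation(n)
            quad = {a: {"source": np.sort(perm[:m]), "target": np.sort(perm[m:2 * m])}}
        for period in periods:
            acts = {}
            for area in quad:
                for role in ("source", "target"):
                    acts[(area, role)] = period_activity(
                        bundle, area, period, quad[area][role])
            for src, tgt in pairs:
                X = acts[(src, "source")]
                Y = acts[(tgt, "target")]
                m = X.shape[1]
                ranks = np.arange(1, (min(m, max_rank) if max_rank else m) + 1)
                ranks_out, r2, singular = rrr_cv_curve(X, Y, ranks=ranks,
                                                       folds=folds, seed=rep)
                mean_r2 = r2.mean(axis=1)
                sem_r2 = r2.std(axis=1, ddof=1) / np.sqrt(folds)
                sel = select_rank(mean_r2, sem_r2, ranks_out)
                ctrl = full_rank_control(X, Y, folds=folds, seed=rep)
                rows.append({
                    "replicate": rep, "source": src, "target": tgt,
                    "period": period, "selected_rank": sel,
                    "r2_selected": mean_r2[np.where(ranks_out == sel)[0][0]],
                    "r2_best": mean_r2.max(), "r2_full": mean_r2[-1],
                    "ridge_alpha": ctrl["alpha"], "ridge_cv_mse": ctrl["cv_mse"],
                    "singular": singular, "single_area": not both,
                })
    return pd.DataFrame(rows)


def aggregate_rrr(table: pd.DataFrame) -> pd.DataFrame:
    """Average performance and selected rank over subsample replicates."""
    return (table.groupby(["source", "target", "period"])
            .agg(r2_selected=("r2_selected", "mean"),
                 r2_full=("r2_full", "mean"),
                 selected_rank=("selected_rank", "mean"),
                 ridge_cv_mse=("ridge_cv_mse", "mean"),
                 n_replicates=("replicate", "nunique"))
            .reset_index())
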