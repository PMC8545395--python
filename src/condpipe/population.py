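"""Population rate-vector trajectories, CS+/CS- distance, PCA and decoding.

Non-lick units are binned at 25 ms and trial-averaged per CS condition.
The per-bin Euclidean distance between the CS+ and CS- trajectories
(z-scored to pre-stimulus baseline bins) quantifies how long trial-type
information persists; a linear maximum-margin classifier on trace-period
(2-3 s) firing rates decodes trial identity with 20-fold stratified
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import single_cell as sc
from .synthetic import SessionBundle


@dataclass
class PopulationTrajectory:
    matrices: dict                  # cs_type -> bins x units (Hz)
    bin_centers: np.ndarray
    unit_ids: np.ndarray
    area: str


def nonlick_unit_ids(classification: pd.DataFrame, area: str) -> np.ndarray:
    sub = classification[classification.area == area]
    return sub.loc[~sub["is_lick_cell"].astype(bool), "unit_id"].to_numpy()


def population_vectors(bundle: SessionBundle, classification: pd.DataFrame,
                       area: str) -> PopulationTrajectory:
    """Trial-averaged, smoothed condition matrices over non-lick units."""
    unit_ids = nonlick_unit_ids(classification, area)
    if len(unit_ids) < 2:
        raise ValueError("need >= 2 non-lick units for population analysis")
    spikes = [bundle.spikes[area][u] for u in unit_ids]
    mats = {}
    centers = None
    for cs in ("plus", "minus"):
        onsets = bundle.trials.loc[bundle.trials.cs_type == cs, "onset_s"].to_numpy()
        pop = sc.bin_and_smooth(spikes, onsets, duration_s=bundle.duration_s)
        mats[cs] = sc.trial_average(pop)
        centers = pop.bin_centers
    return PopulationTrajectory(matrices=mats, bin_centers=centers,
                                unit_ids=unit_ids, area=area)


def distance_trace(mat_a: np.ndarray, mat_b: np.ndarray,
                   bin_centers: np.ndarray,
                   baseline_window=sc.BASELINE_WINDOW):
    """Per-bin Euclidean distance between two condition matrices.

    Returns ``(z_or_raw, raw, zscored_flag)``.  The distance is z-scored
    with the mean/SD of the baseline bins; if the baseline SD is zero the
    raw distance is returned with ``zscored_flag=False``.
    """
    if mat_a.shape != mat_b.shape:
        raise ValueError("condition matrices must have matching shapes")
    raw = np.linalg.norm(mat_a - mat_b, axis=1)
    mask = (bin_centers >= baseline_window[0]) & (bin_centers < baseline_window[1])
    mu, sd = raw[mask].mean(), raw[mask].std()
    if sd == 0:
        return raw, raw, False
    return (raw - mu) / sd, raw, True


def pca_trajectory(matrices: dict, n_components: int = 3):
    """Joint PCA of the concatenated condition matrices.

    Both conditions are projected into the shared space.  Component signs
    are fixed so the largest-|loading| coefficient is positive.  If the
    data rank is below ``n_components``, fewer components are returned
    (``rank_deficient=True``).
    """
    keys = sorted(matrices)
    stacked = np.vstack([matrices[k] for k in keys])
    centered = stacked - stacked.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-10)
    n_comp = min(n_components, rank, stacked.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(stacked)
    for c in range(n_comp):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[c] *= -1
            coords[:, c] *= -1
    out = {}
    i = 0
    for k in keys:
        nb = matrices[k].shape[0]
        out[k] = coords[i:i + nb]
        i += nb
    return out, pca, rank < n_components


def trial_rates(bundle: SessionBundle, area: str, unit_ids,
                window=sc.TRACE_WINDOW) -> np.ndarray:
    """Per-trial mean firing rate (Hz) of the given units in a window."""
    onsets = bundle.trials["onset_s"].to_numpy()
    width = window[1] - window[0]
    rates = np.empty((len(onsets), len(unit_ids)))
    for j, u in enumerate(unit_ids):
        spk = bundle.spikes[area][u]
        lo = np.searchsorted(spk, onsets + window[0], side="left")
        hi = np.searchsorted(spk, onsets + window[1], side="left")
        rates[:, j] = (hi - lo) / width
    return rates


def _cv_accuracy(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> tuple:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(X[train], y[train])
        accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    return float(np.mean(accs)), np.asarray(accs)


def decode_trial_identity(bundle: SessionBundle, classification: pd.DataFrame,
                          area: str, folds: int = 20, n_permutations: int = 1000,
                          seed: int = 0, window=sc.TRACE_WINDOW):
    """Trial-identity (CS+/CS-) decoding from trace-period rates.

    Linear maximum-margin classifier (C = 1) on per-trial mean rates of
    non-lick units, stratified ``folds``-fold cross-validation.  The
    single-session p-value comes from a label-permutation null
    (``n_permutations`` shuffles, p = (1 + #{perm >= obs}) / (n + 1)).
    Set ``n_permutations=0`` to skip the permutation test.
    """
    y = (bundle.trials["cs_type"] == "plus").to_numpy().astype(int)
    if len(y) < folds:
        raise ValueError(f"need >= {folds} trials for {folds}-fold CV")
    if len(np.unique(y)) < 2:
        raise ValueError("both CS types must be present")
    if min(np.bincount(y)) < folds:
        raise ValueError("stratified partitioning impossible: a fold would "
                         "lack one class")
    unit_ids = nonlick_unit_ids(classification, area)
    X = trial_rates(bundle, area, unit_ids, window=window)
    acc, per_fold = _cv_accuracy(X, y, folds, seed)
    p = np.nan
    if n_permutations:
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            yp = rng.permutation(y)
            null[i], _ = _cv_accuracy(X, yp, folds, seed)
        p = (1 + np.sum(null >= acc)) / (n_permutations + 1)
    return {"accuracy": acc, "per_fold": per_fold, "p_value": float(p),
            "n_units": len(unit_ids)}
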