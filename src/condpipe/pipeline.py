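"""Pipeline orchestration: configuration, stage dependency order, reporting.

Stages run in dependency order (behavior -> cells -> population / rrr /
lfp -> assemblies) against a session-bundle directory; every stage writes
plain-text outputs (CSV/JSON) plus a run report echoing all parameters
and flagging non-defaults.  All randomness derives from the single
``seed`` entry of the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assemblies as asm
from . import behavior as beh
from . import lfp as lfpmod
from . import population as pop
from . import rrr as rrrmod
from . import single_cell as sc
from .io import load_bundle
from .synthetic import SessionBundle, TRIAL_SPAN_S

log = logging.getLogger("condpipe")

STAGE_ORDER = ["behavior", "cells", "popdist", "decode", "rrr", "ripples",
               "coherence", "assemblies"]
STAGE_DEPS = {
    "cells": ["behavior"],
    "popdist": ["cells"],
    "decode": ["cells"],
    "rrr": [],
    "ripples": [],
    "coherence": [],
    "assemblies": ["ripples"],
}

DEFAULT_CONFIG = {
    "seed": 0,
    "alpha": 0.05,
    "stages": STAGE_ORDER,
    "decode_folds": 20,
    "decode_permutations": 200,
    "rrr_subsamples": 10,
    "rrr_folds": 10,
    "ripple_low_cut_uv": 100.0,
    "ripple_high_cut_uv": 500.0,
    "coherence_permutations": 200,
    "assembly_bin_s": asm.ASSEMBLY_BIN_S,
    "assembly_step_s": asm.ASSEMBLY_STEP_S,
}


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    non_default: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=str)


def make_config(**overrides) -> dict:
    unknown = set(overrides) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(overrides)
    return cfg


def validate_bundle(path) -> list:
    """Check SessionBundle invariants; returns a list of violation strings
    (empty when well formed) without aborting on the first problem."""
    bundle = load_bundle(path)
    issues = []
    dur = bundle.duration_s
    if len(bundle.licks) and (bundle.licks.min() < 0 or bundle.licks.max() > dur):
        issues.append("lick time outside session duration")
    for area, units in bundle.spikes.items():
        for u, spk in enumerate(units):
            if len(spk) and (spk.min() < 0 or spk.max() > dur):
                issues.append(f"{area} unit {u}: spike time outside session")
                break
    tr = bundle.trials
    if len(tr):
        if tr["onset_s"].min() < 0 or (tr["onset_s"] + TRIAL_SPAN_S).max() > dur + 1e-6:
            issues.append("trial window outside session duration")
        if not tr["onset_s"].is_monotonic_increasing:
            issues.append("trial onsets not sorted")
        post = bundle.meta.get("stage") == "post"
        plus = tr[tr.cs_type == "plus"]
        if post and len(plus):
            if not np.allclose(plus["reward_time_s"], plus["onset_s"] + 3.0):
                issues.append("CS+ reward_time_s != onset + 3 s")
    for area, block in bundle.lfp.items():
        expected = int(round(dur * block.fs_hz))
        if abs(block.data.shape[1] - expected) > block.fs_hz:  # 1 s slack
            issues.append(f"{area} LFP sample count inconsistent with fs*duration")
    return issues


def _run_behavior(bundle, out, cfg, report):
    res = beh.analyze_behavior(bundle, alpha=cfg["alpha"])
    with open(out / "lick_analysis.json", "w") as f:
        json.dump({"learned": res.learned, "p_value": res.p_value,
                   "mean_change_plus": float(res.lick_change[res.cs_labels == "plus"].mean()),
                   "mean_change_minus": float(res.lick_change[res.cs_labels == "minus"].mean())},
                  f, indent=1)
    return {"learned": res.learned, "p_value": res.p_value}


def _run_cells(bundle, out, cfg, report):
    table = sc.classify_cells(bundle)
    table.to_csv(out / "cell_classification.csv", index=False)
    return {"n_units": len(table),
            "n_lick_cells": int(table["is_lick_cell"].sum())}


def _load_cells(out):
    return pd.read_csv(out / "cell_classification.csv")


def _run_popdist(bundle, out, cfg, report):
    cls = _load_cells(out)
    rows = []
    for area in bundle.areas:
        traj = pop.population_vectors(bundle, cls, area)
        z, raw, flag = pop.distance_trace(traj.matrices["plus"],
                                          traj.matrices["minus"],
                                          traj.bin_centers)
        rows.append(pd.DataFrame({"area": area, "time_s": traj.bin_centers,
                                  "distance_z": z, "distance_raw": raw}))
    pd.concat(rows).to_csv(out / "distance.csv", index=False)
    return {"areas": bundle.areas}


def _run_decode(bundle, out, cfg, report):
    cls = _load_cells(out)
    res = {}
    y = (bundle.trials["cs_type"] == "plus").to_numpy().astype(int)
    folds = min(cfg["decode_folds"], int(np.bincount(y).min()))
    if folds < cfg["decode_folds"]:
        report.warnings.append(f"decode: folds reduced to {folds} "
                               "(too few trials per class)")
    for area in bundle.areas:
        d = pop.decode_trial_identity(
            bundle, cls, area, folds=folds,
            n_permutations=cfg["decode_permutations"], seed=cfg["seed"])
        res[area] = {"accuracy": d["accuracy"], "p_value": d["p_value"],
                     "n_units": d["n_units"]}
    with open(out / "decoding.json", "w") as f:
        json.dump(res, f, indent=1)
    return res


def _run_rrr(bundle, out, cfg, report):
    if len(bundle.areas) < 2:
        report.warnings.append("rrr: single-area bundle, within-area only")
    table = rrrmod.crossarea_analysis(
        bundle, n_subsamples=cfg["rrr_subsamples"], folds=cfg["rrr_folds"],
        seed=cfg["seed"])
    table.to_csv(out / "rrr_results.csv", index=False)
    agg = rrrmod.aggregate_rrr(table)
    agg.to_csv(out / "rrr_aggregated.csv", index=False)
    return {"n_rows": len(table)}


def _run_ripples(bundle, out, cfg, report):
    if "ca1" not in bundle.lfp:
        raise RuntimeError("no CA1 LFP in bundle")
    ev = lfpmod.detect_ripples_from_bundle(
        bundle, cfg["ripple_low_cut_uv"], cfg["ripple_high_cut_uv"])
    ev.events.to_csv(out / "ripples.csv", index=False)
    rates = lfpmod.ripple_rate_dynamics(ev, bundle.trials, bundle.duration_s)
    with open(out / "ripple_rates.json", "w") as f:
        json.dump({"period_rates_hz": rates["period_rates_hz"],
                   "n_retained": rates["n_retained"],
                   "channel": ev.channel}, f, indent=1)
    return {"n_retained": int(ev.events.retained.sum()), "channel": ev.channel}


def _run_coherence(bundle, out, cfg, report):
    if not {"ca1", "pfc"} <= set(bundle.lfp):
        raise RuntimeError("coherence needs CA1 and PFC LFP")
    res = lfpmod.coherence_analysis(bundle, n_perm=cfg["coherence_permutations"],
                                    seed=cfg["seed"])
    rows = []
    for (cs, name), (f, coh) in res["coherence"].items():
        rows.append(pd.DataFrame({"cs_type": cs, "window": name,
                                  "freq_hz": f, "coherence": coh}))
    pd.concat(rows).to_csv(out / "coherence.csv", index=False)
    sig = {cs: int(t["sig"].sum()) for cs, t in res["tests"].items()}
    return {"channel": res["channel"], "n_sig_freqs": sig}


def _run_assemblies(bundle, out, cfg, report):
    ripples = pd.read_csv(out / "ripples.csv")
    ripple_times = ripples.loc[ripples.retained, "time_s"].to_numpy()
    pattern_rows, summary_rows = [], []
    per_area = {}
    for area in bundle.areas:
        model = asm.detect_assemblies(bundle, area, seed=cfg["seed"],
                                      bin_width=cfg["assembly_bin_s"])
        for k, p in enumerate(model.patterns):
            for u, w in enumerate(p):
                pattern_rows.append({"area": area, "assembly_id": k,
                                     "unit_id": u, "weight": w})
        if model.n_assemblies == 0:
            continue
        trace = asm.assembly_activation(model, bundle.spikes[area], 0.0,
                                        bundle.duration_s,
                                        step=cfg["assembly_step_s"])
        summary = asm.swr_triggered_reactivation(trace, ripple_times,
                                                 bundle.trials)
        scores = asm.modulation_scores(trace, bundle.trials)
        per_area[area] = summary
        for k in range(model.n_assemblies):
            frac, flagged = (asm.significant_reactivation_fraction(
                summary.per_ripple[k]) if summary.per_ripple.shape[1] >= 10
                else (np.nan, True))
            summary_rows.append({
                "area": area, "assembly_id": k,
                "mean_reactivation": summary.mean_reactivation[k],
                "trial_type_score": scores["trial_type"][k],
                "trial_period_score": scores["trial_period"][k],
                "significant_fraction": frac, "mad_zero": flagged})
    pd.DataFrame(pattern_rows).to_csv(out / "patterns.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(out / "reactivation_summary.csv", index=False)
    result = {"n_assemblies": {a: int(s.per_ripple.shape[0])
                               for a, s in per_area.items()}}
    if {"ca1", "pfc"} <= set(per_area) and len(ripple_times) >= 10 \
            and all(s.per_ripple.shape[0] for s in per_area.values()):
        quad = asm.quadrant_coactivation(per_area["ca1"].per_ripple,
                                         per_area["pfc"].per_ripple)
        quad["pairs"].to_csv(out / "quadrant_pairs.csv", index=False)
        result["quadrant"] = {"q1_mean_pct": quad["q1_mean_pct"],
                              "q2_mean_pct": quad["q2_mean_pct"],
                              "signed_rank_p": quad["signed_rank_p"]}
    return result


_RUNNERS = {"behavior": _run_behavior, "cells": _run_cells,
            "popdist": _run_popdist, "decode": _run_decode, "rrr": _run_rrr,
            "ripples": _run_ripples, "coherence": _run_coherence,
            "assemblies": _run_assemblies}


def run_pipeline(session_dir, out_dir, config: dict = None) -> RunReport:
    """Execute the requested stages in dependency order.

    Fails fast with a stage-attributed error; a stage whose dependency
    was not requested (and whose output is absent) raises a dependency
    error before anything runs.
    """
    cfg = make_config(**(config or {}))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    requested = [s for s in STAGE_ORDER if s in cfg["stages"]]
    unknown = set(cfg["stages"]) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outputs = {"behavior": "lick_analysis.json", "cells": "cell_classification.csv",
               "ripples": "ripples.csv"}
    for s in requested:
        for dep in STAGE_DEPS.get(s, []):
            if dep not in requested and not (out / outputs.get(dep, "")).exists():
                raise RuntimeError(
                    f"stage '{s}' requires '{dep}' (not requested and no "
                    f"prior output found)")
    report = RunReport(config=cfg,
                       non_default={k: v for k, v in cfg.items()
                                    if DEFAULT_CONFIG.get(k) != v})
    bundle = load_bundle(session_dir)
    for s in requested:
        log.info("stage %s: starting (params: %s)", s,
                 {k: v for k, v in cfg.items() if k.startswith(s[:4])})
        try:
            report.stages[s] = {"status": "ok",
                                "result": _RUNNERS[s](bundle, out, cfg, report)}
        except Exception as e:
            report.stages[s] = {"status": "error", "error": f"{type(e).__name__}: {e}"}
            with open(out / "run_report.json", "w") as f:
                f.write(report.to_json())
            raise RuntimeError(f"stage '{s}' failed: {e}") from e
        log.info("stage %s: ok", s)
    with open(out / "run_report.json", "w") as f:
        f.write(report.to_json())
    return report
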