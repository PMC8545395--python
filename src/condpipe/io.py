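"""Session-bundle disk format.

A bundle directory contains::

    trials.csv          onset_s, cs_type, reward_time_s
    licks.csv           time_s
    spikes.csv          area, unit_id, time_s
    lfp_<area>.bin      float32 little-endian, channel-major
    lfp_<area>.json     fs_hz, n_channels, uv_per_unit
    meta.json
    ground_truth.json   (synthetic bundles only)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GroundTruth, LFPBlock, SessionBundle


def save_bundle(bundle: SessionBundle, path, truth: GroundTruth = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.trials.to_csv(path / "trials.csv", index=False)
    pd.DataFrame({"time_s": bundle.licks}).to_csv(path / "licks.csv", index=False)

    rows = []
    for area, units in bundle.spikes.items():
        for uid, spk in enumerate(units):
            rows.append(pd.DataFrame(
                {"area": area, "unit_id": uid, "time_s": spk}))
    spikes = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=["area", "unit_id", "time_s"]))
    spikes.to_csv(path / "spikes.csv", index=False)

    for area, block in bundle.lfp.items():
        arr = np.ascontiguousarray(block.data.astype("<f4"))
        arr.tofile(path / f"lfp_{area}.bin")
        with open(path / f"lfp_{area}.json", "w") as f:
            json.dump({"fs_hz": block.fs_hz, "n_channels": arr.shape[0],
                       "n_samples": arr.shape[1], "uv_per_unit": 1.0}, f)

    meta = dict(bundle.meta)
    meta["duration_s"] = bundle.duration_s
    meta["n_units"] = {a: len(u) for a, u in bundle.spikes.items()}
    with open(path / "meta.json", "w") as f:
        json.dump(meta, f, indent=1)

    if truth is not None:
        with open(path / "ground_truth.json", "w") as f:
            json.dump({
                "unit_class": truth.unit_class,
                "assembly_membership": [
                    {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in a.items()} for a in truth.assembly_membership],
                "ripple_times_s": truth.ripple_times_s.tolist(),
                "artifact_times_s": truth.artifact_times_s.tolist(),
                "planted_comm_rank": truth.planted_comm_rank,
                "lick_bout_onsets_s": truth.lick_bout_onsets_s.tolist(),
                "learned": truth.learned,
            }, f)


def load_bundle(path) -> SessionBundle:
    path = Path(path)
    trials = pd.read_csv(path / "trials.csv")
    if len(trials) == 0:
        trials = pd.DataFrame(columns=["onset_s", "cs_type", "reward_time_s"])
    licks = pd.read_csv(path / "licks.csv")["time_s"].to_numpy(dtype=float)

    spikes_df = pd.read_csv(path / "spikes.csv")
    with open(path / "meta.json") as f:
        meta = json.load(f)
    spikes = {}
    for area, n in meta.get("n_units", {}).items():
        sub = spikes_df[spikes_df.area == area]
        units = [np.sort(sub[sub.unit_id == uid]["time_s"].to_numpy(dtype=float))
                 for uid in range(n)]
        spikes[area] = units

    lfp = {}
    for jpath in sorted(path.glob("lfp_*.json")):
        area = jpath.stem[len("lfp_"):]
        with open(jpath) as f:
            hdr = json.load(f)
        data = np.fromfile(path / f"lfp_{area}.bin", dtype="<f4")
        data = data.reshape(hdr["n_channels"], hdr["n_samples"])
        lfp[area] = LFPBlock(data * hdr.get("uv_per_unit", 1.0), hdr["fs_hz"])

    duration = meta.pop("duration_s")
    meta.pop("n_units", None)
    return SessionBundle(trials=trials, licks=licks, spikes=spikes,
                         lfp=lfp, duration_s=duration, meta=meta)


def load_ground_truth(path) -> GroundTruth:
    with open(Path(path) / "ground_truth.json") as f:
        d = json.load(f)
    for a in d["assembly_membership"]:
        a["weights"] = np.asarray(a["weights"])
        if "event_times" in a:
            a["event_times"] = np.asarray(a["event_times"])
    return GroundTruth(
        unit_class=d["unit_class"],
        assembly_membership=d["assembly_membership"],
        ripple_times_s=np.asarray(d["ripple_times_s"]),
        artifact_times_s=np.asarray(d["artifact_times_s"]),
        planted_comm_rank=d["planted_comm_rank"],
        lick_bout_onsets_s=np.asarray(d["lick_bout_onsets_s"]),
        learned=d["learned"])
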