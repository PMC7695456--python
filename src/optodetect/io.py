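"""Session-bundle persistence.

A bundle directory contains:

- ``trials.csv``: trial_index, trial_type ('catch' or zone count), onset_s,
  lick_times (semicolon-joined seconds), autoreward_s (empty if none)
- ``targets.csv``: trial_type, x_um, y_um, z_um
- ``traces.h5``: datasets f_roi, f_neuropil (neurons x volumes),
  centroids_um (neurons x 3), volume_times_s
- ``ground_truth.json`` (simulated sessions only)
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import CATCH, TrialRecord

__all__ = [
    "write_trials_csv",
    "read_trials_csv",
    "write_targets_csv",
    "read_targets_csv",
    "write_traces_h5",
    "read_traces_h5",
    "write_session",
    "read_session",
]


def _type_to_str(trial_type: int) -> str:
    return "catch" if trial_type == CATCH else str(int(trial_type))


def _type_from_str(s) -> int:
    return CATCH if str(s) == "catch" else int(s)


def write_trials_csv(trials: list[TrialRecord], path):
    rows = []
    for t in trials:
        rows.append(
            {
                "trial_index": t.trial_index,
                "trial_type": _type_to_str(t.trial_type),
                "onset_s": t.onset_s,
                "lick_times": ";".join(f"{x:.6f}" for x in np.asarray(t.lick_times_s)),
                "autoreward_s": "" if t.autoreward_s is None else t.autoreward_s,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trials_csv(path) -> list[TrialRecord]:
    df = pd.read_csv(path, dtype={"lick_times": str, "autoreward_s": str}, keep_default_na=False)
    trials = []
    for _, row in df.iterrows():
        licks = (
            np.array([float(x) for x in row["lick_times"].split(";")])
            if row["lick_times"]
            else np.empty(0)
        )
        auto = row.get("autoreward_s", "")
        trials.append(
            TrialRecord(
                trial_index=int(row["trial_index"]),
                trial_type=_type_from_str(row["trial_type"]),
                onset_s=float(row["onset_s"]),
                lick_times_s=licks,
                autoreward_s=float(auto) if auto not in ("", None) else None,
            )
        )
    return trials


def write_targets_csv(zone_coords_by_type: dict[int, np.ndarray], path):
    rows = []
    for trial_type, coords in zone_coords_by_type.items():
        for x, y, z in np.asarray(coords, dtype=float):
            rows.append({"trial_type": _type_to_str(trial_type), "x_um": x, "y_um": y, "z_um": z})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_targets_csv(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    out = {}
    for tt, grp in df.groupby("trial_type"):
        out[_type_from_str(tt)] = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    return out


def write_traces_h5(path, f_roi, f_neuropil, centroids_um, volume_times_s):
    with h5py.File(path, "w") as f:
        f.create_dataset("f_roi", data=np.asarray(f_roi, dtype=np.float32))
        f.create_dataset("f_neuropil", data=np.asarray(f_neuropil, dtype=np.float32))
        f.create_dataset("centroids_um", data=np.asarray(centroids_um, dtype=np.float64))
        f.create_dataset("volume_times_s", data=np.asarray(volume_times_s, dtype=np.float64))


def read_traces_h5(path) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        return {k: f[k][()].astype(float) for k in ("f_roi", "f_neuropil", "centroids_um", "volume_times_s")}


def _ground_truth_json(session) -> dict:
    gt = session.ground_truth
    return {
        "psych_truth": asdict(gt.psych_truth),
        "zone_coords_um": gt.zone_coords_um.tolist(),
        "target_neuron_of_zone": gt.target_neuron_of_zone.tolist(),
        "per_trial_activated_zones": [z.tolist() for z in gt.per_trial_activated_zones],
        "n_activated": gt.n_activated.tolist(),
        "lick_coupling": gt.lick_coupling.tolist(),
        "per_trial_suppressed": [z.tolist() for z in (gt.per_trial_suppressed or [])],
        "suppression_slope": gt.suppression_slope,
        "suppression_base": gt.suppression_base,
        "neuropil_coeff_true": gt.neuropil_coeff_true,
    }


def write_session(session, out_dir):
    """Write a simulated session bundle (trials, targets, traces, ground truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trials_csv(session.trials, out / "trials.csv")
    zones = session.ground_truth.zone_coords_um
    by_type = {tt: zones[:tt] for tt in session.config.go_types}
    write_targets_csv(by_type, out / "targets.csv")
    write_traces_h5(
        out / "traces.h5",
        session.f_roi,
        session.f_neuropil,
        session.centroids_um,
        session.volume_times_s,
    )
    (out / "ground_truth.json").write_text(json.dumps(_ground_truth_json(session), indent=1))
    return out


def read_session(bundle_dir) -> dict:
    """Read a session bundle back as a plain dict of components."""
    d = Path(bundle_dir)
    out = {
        "trials": read_trials_csv(d / "trials.csv"),
        "targets": read_targets_csv(d / "targets.csv"),
        **read_traces_h5(d / "traces.h5"),
    }
    gt = d / "ground_truth.json"
    if gt.exists():
        out["ground_truth"] = json.loads(gt.read_text())
    return out
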