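"""Reading and writing datasets, paradigms and ground truth.

The on-disk dataset layout (all plain text) is::

    <dir>/config.json                  simulation config
    <dir>/ground_truth.json            per-voxel HRF + neural-model truth
    <dir>/paradigm_localizer.csv/.json
    <dir>/paradigm_adaptation{i}.csv/.json
    <dir>/localizer.csv                rows = volumes, columns = voxels
    <dir>/adaptation_run{i}.csv

A 4D NIfTI export (x, y, z, t) is available for interoperability with
standard neuroimaging tools.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Condition, Event, Paradigm, TimeCourse
from .hrf import PARAM_NAMES, HRFParams
from .synthetic import (
    NeuralModel,
    SimulatedVoxel,
    SimulationConfig,
    SyntheticDataset,
)

__all__ = [
    "write_paradigm",
    "read_paradigm",
    "write_dataset",
    "read_dataset",
    "write_nifti",
]


def _event_row(ev: Event) -> dict:
    if isinstance(ev.condition, Condition):
        rt, dur = ev.condition.response_type, ev.condition.test_duration_s
    else:
        rt, dur = ev.condition, ""
    return {"onset_s": ev.onset_s, "duration_s": ev.duration_s,
            "response_type": rt, "test_duration_s": dur}


def write_paradigm(paradigm: Paradigm, path: str | Path) -> None:
    """Write a paradigm as CSV (``.csv``) or JSON (anything else)."""
    path = Path(path)
    rows = [_event_row(ev) for ev in paradigm.events]
    if path.suffix == ".csv":
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        payload = {"kind": paradigm.kind, "run_length_s": paradigm.run_length_s,
                   "tr_s": paradigm.tr_s,
                   "adaptation_onset_s": paradigm.adaptation_onset_s,
                   "events": rows}
        path.write_text(json.dumps(payload, indent=2) + "\n")


def _event_from_row(row: dict) -> Event:
    rt = row["response_type"]
    if rt in ("increment", "decrement"):
        cond: Condition | str = Condition(rt, float(row["test_duration_s"]))
    else:
        cond = rt
    return Event(onset_s=float(row["onset_s"]), duration_s=float(row["duration_s"]),
                 condition=cond)


def read_paradigm(path: str | Path, *, kind: str | None = None,
                  run_length_s: float | None = None, tr_s: float = 1.0) -> Paradigm:
    """Read a paradigm written by :func:`write_paradigm`.

    CSV files carry only the event table, so ``kind`` and
    ``run_length_s`` must be supplied; JSON files are self-describing.
    """
    path = Path(path)
    if path.suffix == ".csv":
        if kind is None or run_length_s is None:
            raise ValueError("kind and run_length_s are required for CSV paradigms")
        df = pd.read_csv(path)
        events = tuple(_event_from_row(r) for r in df.to_dict("records"))
        adaptation_onset = 30.0 if kind == "adaptation" else None
        return Paradigm(events=events, run_length_s=run_length_s, tr_s=tr_s,
                        kind=kind, adaptation_onset_s=adaptation_onset)  # type: ignore[arg-type]
    payload = json.loads(path.read_text())
    events = tuple(_event_from_row(r) for r in payload["events"])
    return Paradigm(events=events, run_length_s=payload["run_length_s"],
                    tr_s=payload["tr_s"], kind=payload["kind"],
                    adaptation_onset_s=payload.get("adaptation_onset_s"))


def _neural_payload(nm: NeuralModel) -> dict:
    return {
        "base_gain": nm.base_gain,
        "duration_gain": {rt: {str(d): g for d, g in m.items()}
                          for rt, m in nm.duration_gain.items()},
        "onset_offset_transient": list(nm.onset_offset_transient),
        "habituation_tau_s": None if np.isinf(nm.habituation_tau_s)
        else nm.habituation_tau_s,
        "adaptation_baseline": list(nm.adaptation_baseline),
        "plateau_fraction": nm.plateau_fraction,
        "decrement_gain": nm.decrement_gain,
    }


def _neural_from_payload(p: dict) -> NeuralModel:
    return NeuralModel(
        base_gain=p["base_gain"],
        duration_gain={rt: {float(d): g for d, g in m.items()}
                       for rt, m in p["duration_gain"].items()},
        onset_offset_transient=tuple(p["onset_offset_transient"]),
        habituation_tau_s=np.inf if p["habituation_tau_s"] is None
        else p["habituation_tau_s"],
        adaptation_baseline=tuple(p["adaptation_baseline"]),
        plateau_fraction=p["plateau_fraction"],
        decrement_gain=p["decrement_gain"],
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write a simulated dataset as CSV matrices + JSON sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(dataset.config)
    cfg["drift_components"] = [list(c) for c in cfg["drift_components"]]
    (out / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")

    write_paradigm(dataset.localizer_paradigm, out / "paradigm_localizer.csv")
    write_paradigm(dataset.localizer_paradigm, out / "paradigm_localizer.json")
    for i, par in enumerate(dataset.adaptation_paradigms):
        write_paradigm(par, out / f"paradigm_adaptation{i}.csv")
        write_paradigm(par, out / f"paradigm_adaptation{i}.json")

    truth = []
    for vox in dataset.voxels:
        truth.append({
            "voxel_id": vox.voxel_id, "coords": list(vox.coords),
            "active": vox.active,
            "hrf": {n: getattr(vox.hrf, n) for n in PARAM_NAMES},
            "neural": _neural_payload(vox.neural),
        })
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")

    cols = [f"voxel{v.voxel_id}" for v in dataset.voxels]
    loc = np.column_stack([v.localizer.values for v in dataset.voxels])
    pd.DataFrame(loc, columns=cols).to_csv(out / "localizer.csv", index=False)
    for i in range(len(dataset.adaptation_paradigms)):
        mat = np.column_stack([v.adaptation_runs[i].values for v in dataset.voxels])
        pd.DataFrame(mat, columns=cols).to_csv(out / f"adaptation_run{i}.csv",
                                               index=False)


def read_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Reconstruct a dataset written by :func:`write_dataset`."""
    d = Path(in_dir)
    cfg = json.loads((d / "config.json").read_text())
    cfg["drift_components"] = tuple(tuple(c) for c in cfg["drift_components"])
    config = SimulationConfig(**cfg)
    localizer_par = read_paradigm(d / "paradigm_localizer.json")
    adaptation_pars = []
    i = 0
    while (d / f"paradigm_adaptation{i}.json").exists():
        adaptation_pars.append(read_paradigm(d / f"paradigm_adaptation{i}.json"))
        i += 1
    truth = json.loads((d / "ground_truth.json").read_text())
    loc = pd.read_csv(d / "localizer.csv", float_precision="round_trip")
    runs = [pd.read_csv(d / f"adaptation_run{j}.csv", float_precision="round_trip")
            for j in range(len(adaptation_pars))]
    voxels = []
    for entry in truth:
        vid = entry["voxel_id"]
        col = f"voxel{vid}"
        hrf = HRFParams(**entry["hrf"], sign=1, bounds_mode="restricted")
        voxels.append(SimulatedVoxel(
            voxel_id=vid, coords=tuple(entry["coords"]), hrf=hrf,
            neural=_neural_from_payload(entry["neural"]), active=entry["active"],
            localizer=TimeCourse(loc[col].to_numpy(), localizer_par.tr_s,
                                 unit="raw", origin=f"voxel{vid}/localizer"),
            adaptation_runs=tuple(
                TimeCourse(run[col].to_numpy(), p.tr_s, unit="raw",
                           origin=f"voxel{vid}/adaptation{j}")
                for j, (run, p) in enumerate(zip(runs, adaptation_pars))
            ),
        ))
    return SyntheticDataset(tuple(voxels), localizer_par, tuple(adaptation_pars),
                            config)


def write_nifti(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Export runs as 4D NIfTI volumes (x, y, z, t); off-grid voxels are zero."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coords = np.array([v.coords for v in dataset.voxels])
    shape = tuple(coords.max(axis=0) + 1)

    def to_4d(series: Sequence[np.ndarray]) -> np.ndarray:
        n_t = len(series[0])
        vol = np.zeros(shape + (n_t,), dtype=np.float32)
        for v, s in zip(dataset.voxels, series):
            vol[v.coords[0], v.coords[1], v.coords[2], :] = s
        return vol

    affine = np.eye(4)
    nib.save(nib.Nifti1Image(to_4d([v.localizer.values for v in dataset.voxels]),
                             affine), out / "localizer.nii")
    for i in range(len(dataset.adaptation_paradigms)):
        nib.save(nib.Nifti1Image(
            to_4d([v.adaptation_runs[i].values for v in dataset.voxels]), affine),
            out / f"adaptation_run{i}.nii")
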