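"""Lossless dataset containers: HDF5 (groups /kspace, /navigators, /reacq,
/truth, /schedule) with an NPZ fallback carrying the same names."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .synthetic import (AcquisitionSchedule, DriftSpec, KSpaceDataset,
                        MotionEvent, MotionEventSpec, TruthInfo)

_SCHEDULE_ATTRS = ("matrix_size", "acquired_ky", "center_line", "tr_s",
                   "echo_spacing_ms", "n_echoes", "nav_echo_index")


def _schedule_to_attrs(sched: AcquisitionSchedule) -> dict:
    return {
        "matrix_size": list(sched.matrix_size),
        "acquired_ky": sched.acquired_ky.tolist(),
        "center_line": sched.center_line,
        "tr_s": sched.tr_s,
        "echo_spacing_ms": sched.echo_spacing_ms,
        "n_echoes": sched.n_imaging_echoes,
        "nav_echo_index": sched.navigator_echo_index,
        "partial_fourier": sched.partial_fourier,
        "n_slices": sched.n_slices,
        "n_reacq_trs": sched.n_reacq_trs,
    }


def _schedule_from_attrs(a: dict) -> AcquisitionSchedule:
    return AcquisitionSchedule(
        matrix_size=tuple(int(v) for v in a["matrix_size"]),
        partial_fourier=float(a["partial_fourier"]),
        n_slices=int(a["n_slices"]),
        tr_s=float(a["tr_s"]),
        echo_spacing_ms=float(a["echo_spacing_ms"]),
        n_imaging_echoes=int(a["n_echoes"]),
        navigator_echo_index=int(a["nav_echo_index"]),
        n_reacq_trs=int(a["n_reacq_trs"]),
    )


def _events_to_json(spec: MotionEventSpec) -> str:
    return json.dumps({
        "events": [{"tr_start": e.tr_start, "tr_end": e.tr_end,
                    "amplitude_drop_fraction": e.amplitude_drop_fraction,
                    "phase_jitter_sd": e.phase_jitter_sd,
                    "throat_shift_px": e.throat_shift_px}
                   for e in spec.events],
        "drift": {"amplitude_fraction": spec.drift.amplitude_fraction,
                  "shape": spec.drift.shape},
    })


def _events_from_json(s: str) -> MotionEventSpec:
    d = json.loads(s)
    return MotionEventSpec(
        events=tuple(MotionEvent(**e) for e in d["events"]),
        drift=DriftSpec(**d["drift"]))


def write_dataset(dataset: KSpaceDataset, path: str | Path) -> None:
    """Write a dataset to HDF5 (or NPZ when the suffix is .npz)."""
    path = Path(path)
    if path.suffix == ".npz":
        _write_npz(dataset, path)
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace/data", data=dataset.data)
        f.create_dataset("navigators/data", data=dataset.navigators)
        for key, val in _schedule_to_attrs(dataset.schedule).items():
            f.require_group("schedule").attrs[key] = val
        if dataset.reacq_data is not None:
            g = f.require_group("reacq")
            g.create_dataset("data", data=dataset.reacq_data)
            g.create_dataset("navigators", data=dataset.reacq_navigators)
            g.create_dataset("tr_indices", data=dataset.reacq_tr_indices)
        if dataset.truth is not None:
            g = f.require_group("truth")
            g.create_dataset("clean_data", data=dataset.truth.clean_data)
            g.create_dataset("corrupted_tr_mask",
                             data=dataset.truth.corrupted_tr_mask)
            g.attrs["events"] = _events_to_json(dataset.truth.events)


def read_dataset(path: str | Path) -> KSpaceDataset:
    """Read a dataset container, validating that required groups exist."""
    path = Path(path)
    if path.suffix == ".npz":
        return _read_npz(path)
    with h5py.File(path, "r") as f:
        missing = [g for g in ("kspace", "navigators", "schedule")
                   if g not in f]
        if missing:
            raise ValueError(f"malformed container {path}: missing "
                             f"group(s) {missing}")
        sched = _schedule_from_attrs(dict(f["schedule"].attrs))
        ds = KSpaceDataset(data=f["kspace/data"][()],
                           navigators=f["navigators/data"][()],
                           schedule=sched)
        if "reacq" in f:
            ds.reacq_data = f["reacq/data"][()]
            ds.reacq_navigators = f["reacq/navigators"][()]
            ds.reacq_tr_indices = f["reacq/tr_indices"][()]
        if "truth" in f:
            ds.truth = TruthInfo(
                clean_data=f["truth/clean_data"][()],
                corrupted_tr_mask=f["truth/corrupted_tr_mask"][()].astype(bool),
                events=_events_from_json(f["truth"].attrs["events"]))
        return ds


def _write_npz(dataset: KSpaceDataset, path: Path) -> None:
    arrays = {
        "kspace": dataset.data,
        "navigators": dataset.navigators,
        "schedule": json.dumps(_schedule_to_attrs(dataset.schedule)),
    }
    if dataset.reacq_data is not None:
        arrays["reacq_data"] = dataset.reacq_data
        arrays["reacq_navigators"] = dataset.reacq_navigators
        arrays["reacq_tr_indices"] = dataset.reacq_tr_indices
    if dataset.truth is not None:
        arrays["truth_clean_data"] = dataset.truth.clean_data
        arrays["truth_corrupted_tr_mask"] = dataset.truth.corrupted_tr_mask
        arrays["truth_events"] = _events_to_json(dataset.truth.events)
    np.savez(path, **arrays)


def _read_npz(path: Path) -> KSpaceDataset:
    with np.load(path, allow_pickle=False) as f:
        missing = [k for k in ("kspace", "navigators", "schedule")
                   if k not in f]
        if missing:
            raise ValueError(f"malformed container {path}: missing "
                             f"entries {missing}")
        sched = _schedule_from_attrs(json.loads(str(f["schedule"])))
        ds = KSpaceDataset(data=f["kspace"], navigators=f["navigators"],
                           schedule=sched)
        if "reacq_data" in f:
            ds.reacq_data = f["reacq_data"]
            ds.reacq_navigators = f["reacq_navigators"]
            ds.reacq_tr_indices = f["reacq_tr_indices"]
        if "truth_clean_data" in f:
            ds.truth = TruthInfo(
                clean_data=f["truth_clean_data"],
                corrupted_tr_mask=f["truth_corrupted_tr_mask"].astype(bool),
                events=_events_from_json(str(f["truth_events"])))
        return ds
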