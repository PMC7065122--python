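"""End-to-end four-arm experiment: still / swl / reacq / moco.

One experiment simulates, from a single phantom + coil instance, a
motion-free acquisition (still) and a swallow-corrupted acquisition with
end-of-scan reacquisition TRs (swl).  The corrupted data are reconstructed
uncorrected (swl), with reacquisition replacement only (reacq), and with
central-line replacement plus GRAPPA estimation (moco); quality metrics are
reported for all four arms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import metrics as qmetrics
from .io import write_dataset
from .recon import ReconConfig, reconstruct
from .scoring import score_dataset
from .synthetic import (AcquisitionSchedule, DriftSpec, KSpaceDataset,
                        MotionEvent, MotionEventSpec, make_coil_profiles,
                        make_phantom, simulate_mese_kspace,
                        truth_corrupted_mask)

DEFAULT_EVENTS = (
    {"tr_start": 45, "tr_end": 45, "amplitude_drop_fraction": 0.25,
     "phase_jitter_sd": 0.4, "throat_shift_px": 3.0},
    {"tr_start": 62, "tr_end": 63, "amplitude_drop_fraction": 0.20,
     "phase_jitter_sd": 0.4, "throat_shift_px": 2.5},
    {"tr_start": 78, "tr_end": 78, "amplitude_drop_fraction": 0.15,
     "phase_jitter_sd": 0.3, "throat_shift_px": 2.0},
    {"tr_start": 96, "tr_end": 97, "amplitude_drop_fraction": 0.20,
     "phase_jitter_sd": 0.4, "throat_shift_px": 3.0},
    {"tr_start": 110, "tr_end": 110, "amplitude_drop_fraction": 0.12,
     "phase_jitter_sd": 0.3, "throat_shift_px": 1.5},
)


@dataclass
class ExperimentConfig:
    """Serializable description of one four-arm experiment."""

    matrix_size: tuple[int, int] = (192, 192)
    partial_fourier: float = 5.0 / 8.0
    n_slices: int = 5
    n_imaging_echoes: int = 14
    tr_s: float = 2.0
    echo_spacing_ms: float = 9.1
    ncoils: int = 10
    phantom_seed: int = 0
    coil_seed: int = 1
    noise_sd: float = 0.01
    n_reacq: int = 16
    reacq_shift_px: float = 2.0
    events: tuple[dict, ...] = DEFAULT_EVENTS
    drift_amplitude_fraction: float = 0.05
    drift_shape: str = "smooth"
    drift_window: int = 10
    hampel_window: int = 25
    n_sd: float = 3.0
    n_central: int = 7
    cap: int = 12
    calib_halfwidth: int = 12
    pocs_iterations: int = 10
    pocs_tol: float = 1e-6

    def schedule(self, n_reacq: int | None = None) -> AcquisitionSchedule:
        return AcquisitionSchedule(
            matrix_size=tuple(self.matrix_size),
            partial_fourier=self.partial_fourier,
            n_slices=self.n_slices, tr_s=self.tr_s,
            echo_spacing_ms=self.echo_spacing_ms,
            n_imaging_echoes=self.n_imaging_echoes,
            navigator_echo_index=self.n_imaging_echoes + 1,
            n_reacq_trs=self.n_reacq if n_reacq is None else n_reacq)

    def motion(self) -> MotionEventSpec:
        return MotionEventSpec(
            events=tuple(MotionEvent(**e) for e in self.events),
            drift=DriftSpec(amplitude_fraction=self.drift_amplitude_fraction,
                            shape=self.drift_shape))

    def recon_config(self) -> ReconConfig:
        return ReconConfig(pocs_iterations=self.pocs_iterations,
                           pocs_tol=self.pocs_tol, n_central=self.n_central,
                           cap=self.cap, calib_halfwidth=self.calib_halfwidth,
                           drift_window=self.drift_window,
                           hampel_window=self.hampel_window, n_sd=self.n_sd)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"invalid config field(s): {sorted(bad)}")
        if "matrix_size" in raw:
            raw["matrix_size"] = tuple(raw["matrix_size"])
        if "events" in raw:
            raw["events"] = tuple(raw["events"])
        return cls(**raw)


def simulate_pair(config: ExperimentConfig, seed: int = 0
                  ) -> tuple[KSpaceDataset, KSpaceDataset, Any]:
    """Simulate the still and motion-corrupted datasets of one experiment
    from the same phantom/coils; returns (still, swl, phantom)."""
    phantom = make_phantom(tuple(config.matrix_size),
                           rng_seed=config.phantom_seed)
    coils = make_coil_profiles(phantom, ncoils=config.ncoils,
                               rng_seed=config.coil_seed)
    ss = np.random.SeedSequence(seed)
    seed_still, seed_swl = (int(s.generate_state(1)[0]) for s in ss.spawn(2))
    still = simulate_mese_kspace(phantom, coils, config.schedule(n_reacq=0),
                                 motion=None, noise_sd=config.noise_sd,
                                 rng_seed=seed_still)
    swl = simulate_mese_kspace(phantom, coils, config.schedule(),
                               motion=config.motion(),
                               noise_sd=config.noise_sd, rng_seed=seed_swl,
                               reacq_shift_px=config.reacq_shift_px)
    return still, swl, phantom


def run_experiment(config: ExperimentConfig, seed: int = 0,
                   outdir: str | Path | None = None,
                   fit_t2_maps: bool = True) -> dict:
    """Run the four-arm experiment and return the metrics report."""
    still_ds, swl_ds, phantom = simulate_pair(config, seed=seed)
    rcfg = config.recon_config()
    qc = score_dataset(swl_ds, drift_window=config.drift_window,
                       hampel_window=config.hampel_window, n_sd=config.n_sd)

    stacks = {
        "still": reconstruct(still_ds, "still", config=rcfg),
        "swl": reconstruct(swl_ds, "swl", qc=qc, config=rcfg),
        "reacq": reconstruct(swl_ds, "reacq", qc=qc, config=rcfg),
        "moco": reconstruct(swl_ds, "moco", qc=qc, config=rcfg),
    }

    rois = qmetrics.auto_rois(phantom)
    sl = config.n_slices // 2
    swl_imgs = {name: st.images[sl, 0] for name, st in stacks.items()}
    ref_bg = qmetrics.background_median(swl_imgs["swl"], rois)
    ghost = {name: qmetrics.ghost_level(img, rois, ref_bg)
             for name, img in swl_imgs.items()}
    reductions = {name: qmetrics.ghosting_reduction(ghost[name], ghost["swl"])
                  for name in ("reacq", "moco")}
    cnr = {name: qmetrics.cnr(img, rois.wall_roi, rois.lumen_roi,
                              rois.noise_roi)
           for name, img in swl_imgs.items()}
    iepa = {name: qmetrics.iepa(
        qmetrics.wall_edge_profiles(img, phantom))
        for name, img in swl_imgs.items()}

    truth_mask = truth_corrupted_mask(swl_ds)[0]
    detected = qc.corrupted_mask
    tp = int((detected & truth_mask).sum())
    fp = int((detected & ~truth_mask).sum())

    report: dict[str, Any] = {
        "seed": seed,
        "config": dataclasses.asdict(config),
        "detection": {
            "n_truth_corrupted": int(truth_mask.sum()),
            "n_detected": int(detected.sum()),
            "true_positives": tp,
            "false_positives": fp,
            "sensitivity": tp / max(int(truth_mask.sum()), 1),
        },
        "ghost_level": ghost,
        "ghosting_reduction_percent": reductions,
        "cnr": cnr,
        "iepa": iepa,
        "provenance": {name: st.provenance for name, st in stacks.items()},
    }

    if fit_t2_maps:
        te = still_ds.schedule.echo_times_ms
        t2_median = {}
        for name, st in stacks.items():
            fit = qmetrics.fit_t2(st.images[sl], te, mask=rois.wall_roi)
            sel = fit.valid_mask & ~fit.near_bound_mask
            t2_median[name] = float(np.median(fit.t2_map[sel]))
        report["t2_median_wall_ms"] = t2_median

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_dataset(swl_ds, outdir / "swl.h5")
        write_dataset(still_ds, outdir / "still.h5")
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
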