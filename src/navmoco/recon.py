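"""Image reconstruction: POCS partial-Fourier completion, coil combination,
and the four comparison variants (still / swl / reacq / moco).

POCS iterates between enforcing the image phase estimated from the
symmetric low-frequency band and restoring the acquired k-space samples;
acquired samples are preserved exactly in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._fft import ifft2c
from .grappa import (LinePattern, apply_plan, build_estimation_plan,
                     calibrate_for_dataset)
from .reacquisition import merge_reacq_all, replace_central_lines
from .scoring import QualityTrace, reacq_tr_scores, score_dataset
from .synthetic import KSpaceDataset

VARIANTS = ("still", "swl", "reacq", "moco")


@dataclass
class EchoImageStack:
    images: np.ndarray  # (n_slices, n_echoes, ny, nx) real, >= 0
    provenance: dict[str, Any] = field(default_factory=dict)


def pocs_partial_fourier(kspace: np.ndarray, acquired_ky: np.ndarray,
                         center_line: int, n_iter: int = 20,
                         tol: float = 1e-6,
                         return_residuals: bool = False):
    """POCS completion of partial-Fourier k-space.

    ``kspace`` is full-grid (..., ny, nx) with zeros on unacquired rows;
    ``acquired_ky`` holds 1-based acquired row indices, which must include a
    symmetric band around ``center_line``.  The image-phase projection uses
    the phase of the low-frequency image from that band (raised-cosine
    windowed); the data-consistency projection restores acquired samples
    exactly, so they are preserved in the output.
    """
    import scipy.fft as sfft

    k = np.asarray(kspace)
    if not np.iscomplexobj(k):
        k = k.astype(complex)
    ny = k.shape[-2]
    rows = np.asarray(acquired_ky, dtype=int) - 1
    c = center_line - 1
    above = rows[rows > c].size
    below = rows[rows < c].size
    half = min(above, below)
    if half < 1:
        raise ValueError("acquired region has no symmetric band around the "
                         "center line; POCS phase estimate impossible")

    window = np.zeros(ny)
    band = np.arange(c - half, c + half + 1)
    window[band] = 0.5 * (1.0 + np.cos(np.pi * (band - c) / (half + 1)))
    phase = np.exp(1j * np.angle(ifft2c(k * window[:, None])))
    phase = phase.astype(k.dtype, copy=False)

    mask = np.zeros(ny, dtype=bool)
    mask[rows] = True
    mask_col = mask[:, None]

    # iterate in unshifted FFT coordinates to avoid fftshift copies
    axes = (-2, -1)
    ks = sfft.ifftshift(k, axes=axes)
    phase_s = sfft.ifftshift(phase, axes=axes)
    mask_s = sfft.ifftshift(mask_col, axes=(0,))

    out = ks.copy()
    residuals = []
    for _ in range(n_iter):
        img = sfft.ifft2(out, axes=axes, norm="ortho")
        np.multiply(img, np.conj(phase_s), out=img)
        img = img.real * phase_s
        k_new = sfft.fft2(img, axes=axes, norm="ortho", overwrite_x=True)
        np.copyto(k_new, ks, where=mask_s)
        num = np.linalg.norm(k_new - out)
        den = max(float(np.linalg.norm(out)), 1e-300)
        residuals.append(num / den)
        out = k_new
        if residuals[-1] < tol:
            break
    # exact (not merely converged) restoration of acquired samples
    np.copyto(out, ks, where=mask_s)
    out = sfft.fftshift(out, axes=axes)
    if return_residuals:
        return out, residuals
    return out


def coil_combine(images_per_coil: np.ndarray, method: str = "rss",
                 coil_axis: int = 0) -> np.ndarray:
    """Combine per-coil complex images into one magnitude image."""
    if method != "rss":
        raise ValueError(f"unknown combination method {method!r}")
    return np.sqrt((np.abs(images_per_coil) ** 2).sum(axis=coil_axis))


@dataclass
class ReconConfig:
    pocs_iterations: int = 20
    pocs_tol: float = 1e-6
    n_central: int = 7
    cap: int = 12
    calib_halfwidth: int = 12
    drift_window: int = 10
    hampel_window: int = 25
    n_sd: float = 3.0


def _images_from_dataset(dataset: KSpaceDataset,
                         config: ReconConfig) -> np.ndarray:
    sched = dataset.schedule
    nsl, ne = dataset.data.shape[:2]
    images = np.empty((nsl, ne, sched.ny, sched.nx))
    for sl in range(nsl):
        # batch POCS over echoes and coils of one slice; single precision
        # is ample for magnitude images and halves memory traffic
        k = np.stack([dataset.full_grid(sl, e) for e in range(ne)])
        k = k.astype(np.complex64)
        k = pocs_partial_fourier(k, sched.acquired_ky, sched.center_line,
                                 n_iter=config.pocs_iterations,
                                 tol=config.pocs_tol)
        imgs = ifft2c(k)
        images[sl] = coil_combine(imgs, coil_axis=1)
    return images


def reconstruct(dataset: KSpaceDataset, variant: str = "swl",
                qc: QualityTrace | None = None,
                config: ReconConfig | None = None) -> EchoImageStack:
    """Reconstruct per-echo magnitude images for one comparison variant.

    still / swl: no correction; reacq: every corrupted line replaced by its
    reacquisition under the higher-score rule; moco: central-line
    replacement, then worst-first 1/2-AMCL GRAPPA estimation of the
    remaining corrupted lines, then POCS and coil combination.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of "
                         f"{VARIANTS}")
    config = config or ReconConfig()
    prov: dict[str, Any] = {"variant": variant,
                            "pocs_iterations": config.pocs_iterations}

    ds = dataset
    if variant in ("reacq", "moco"):
        if qc is None:
            qc = score_dataset(dataset, drift_window=config.drift_window,
                               hampel_window=config.hampel_window,
                               n_sd=config.n_sd)
        r_scores = reacq_tr_scores(dataset)
        if variant == "reacq":
            ds, log = merge_reacq_all(dataset, qc, r_scores)
            prov["replaced_trs"] = log.replaced_trs
            prov["warnings"] = log.warnings
        else:
            ds, log = replace_central_lines(dataset, qc, r_scores,
                                            n_central=config.n_central)
            plan = build_estimation_plan(log.updated_mask, log.updated_scores,
                                         cap=config.cap)
            kernels = calibrate_for_dataset(
                ds, calib_halfwidth=config.calib_halfwidth)
            ds, executed = apply_plan(ds, plan, kernels)
            prov["replaced_trs"] = log.replaced_trs
            prov["estimated_lines"] = executed.all_lines()
            prov["skipped_lines"] = executed.skipped_lines
            prov["warnings"] = log.warnings

    images = _images_from_dataset(ds, config)
    return EchoImageStack(images=images, provenance=prov)


def moco_pattern(dataset: KSpaceDataset, qc: QualityTrace | None = None,
                 config: ReconConfig | None = None, sl: int = 0
                 ) -> LinePattern:
    """The corrupted-line pattern and kernels that the moco variant would
    apply, for g-factor analysis."""
    config = config or ReconConfig()
    if qc is None:
        qc = score_dataset(dataset, drift_window=config.drift_window,
                           hampel_window=config.hampel_window,
                           n_sd=config.n_sd)
    ds, log = replace_central_lines(dataset, qc, reacq_tr_scores(dataset),
                                    n_central=config.n_central)
    plan = build_estimation_plan(log.updated_mask, log.updated_scores,
                                 cap=config.cap)
    kernels = calibrate_for_dataset(ds, calib_halfwidth=config.calib_halfwidth)
    return LinePattern.from_plan(plan, kernels, dataset.schedule, sl=sl)
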