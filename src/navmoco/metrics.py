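"""Image quality metrics: ghosting level/reduction, wall-lumen CNR, edge
sharpness (profile acutance) and voxel-wise T2 fitting.

The ghost level of a reconstruction is the median intensity in a ghost ROI
minus the median intensity of the background ROI of the *original*
(uncorrected) reconstruction; 100% ghosting reduction therefore means the
ghost ROI has dropped to the background level.  Ghosting propagates along
the phase-encode (y) direction, so the auto-generated ghost ROI sits in the
background band above/below the mobile structure, and the background ROI in
columns outside that band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .synthetic import (LABEL_BACKGROUND, LABEL_LUMEN, LABEL_THROAT,
                        LABEL_WALL, PhantomModel)


@dataclass
class RoiSet:
    ghost_roi: np.ndarray       # boolean masks (ny, nx)
    background_roi: np.ndarray
    wall_roi: np.ndarray
    lumen_roi: np.ndarray
    noise_roi: np.ndarray
    provenance: str = "generated-from-phantom"


def auto_rois(phantom: PhantomModel) -> RoiSet:
    """Derive the metric ROIs from the phantom labels.

    The ghost ROI covers background rows sharing columns with the mobile
    throat structure (the phase-encode ghosting band); the background and
    noise ROIs sit in columns clear of any object."""
    labels = phantom.tissue_labels
    ny, nx = labels.shape
    obj = labels != LABEL_BACKGROUND
    margin = max(2, ny // 48)
    obj_dil = ndimage.binary_dilation(obj, iterations=margin)

    throat_cols = np.flatnonzero((labels == LABEL_THROAT).any(axis=0))
    ghost = np.zeros_like(obj)
    ghost[:, throat_cols] = True
    ghost &= ~obj_dil

    clear_cols = np.flatnonzero(~obj_dil.any(axis=0))
    background = np.zeros_like(obj)
    background[:, clear_cols] = True
    background &= ~obj_dil
    background[:, throat_cols] = False

    noise = background.copy()

    return RoiSet(ghost_roi=ghost, background_roi=background,
                  wall_roi=labels == LABEL_WALL,
                  lumen_roi=labels == LABEL_LUMEN,
                  noise_roi=noise)


def ghost_level(image: np.ndarray, rois: RoiSet,
                reference_background_median: float) -> float:
    """Median ghost-ROI intensity minus the background median of the
    original (uncorrected) reconstruction."""
    if not rois.ghost_roi.any():
        raise ValueError("empty ghost ROI")
    return float(np.median(image[rois.ghost_roi])
                 - reference_background_median)


def background_median(image: np.ndarray, rois: RoiSet) -> float:
    if not rois.background_roi.any():
        raise ValueError("empty background ROI")
    return float(np.median(image[rois.background_roi]))


def ghosting_reduction(ghost_level_corrected: float,
                       ghost_level_swl: float) -> float:
    """Percent reduction of ghosting relative to the uncorrected image;
    100% means ghosting at the background-noise level."""
    if ghost_level_swl <= 0:
        raise ValueError("uncorrected ghost level must be > 0")
    return 100.0 * (1.0 - ghost_level_corrected / ghost_level_swl)


def cnr(image: np.ndarray, wall_roi: np.ndarray, lumen_roi: np.ndarray,
        noise_roi: np.ndarray) -> float:
    """Wall/lumen contrast-to-noise ratio: (mean wall - mean lumen) / noise
    std."""
    for roi, name in ((wall_roi, "wall"), (lumen_roi, "lumen"),
                      (noise_roi, "noise")):
        if not np.asarray(roi).any():
            raise ValueError(f"empty {name} ROI")
    sd = float(np.std(image[noise_roi]))
    if sd == 0:
        raise ValueError("zero noise standard deviation")
    return float((image[wall_roi].mean() - image[lumen_roi].mean()) / sd)


def iepa(image_or_profiles, edge_normals: list[np.ndarray] | None = None
         ) -> float:
    """Image edge profile acutance.

    Mean over edge profiles of the mean squared successive intensity
    difference normalized by the squared profile dynamic range; in (0, 1],
    higher is sharper.  Accepts either a list of 1D profiles, or an image
    plus pre-sampled profiles in ``edge_normals``.
    """
    profiles = (image_or_profiles if edge_normals is None
                else edge_normals)
    values = []
    for prof in profiles:
        p = np.asarray(prof, dtype=float)
        if p.size < 5:
            raise ValueError("each edge profile needs at least 5 samples")
        rng = p.max() - p.min()
        if rng == 0:
            continue  # flat profile carries no edge information
        diffs = np.diff(p)
        values.append(np.mean(diffs ** 2) / rng ** 2)
    if not values:
        raise ValueError("all profiles are flat; acutance undefined")
    return float(np.mean(values))


def wall_edge_profiles(image: np.ndarray, phantom: PhantomModel,
                       n_profiles: int = 8, length: int = 9,
                       step: float = 1.0) -> list[np.ndarray]:
    """Sample intensity profiles across the lumen/wall boundary (the
    high-contrast vessel edge), along outward radial normals from each
    vessel center."""
    labels = phantom.tissue_labels
    wall = labels == LABEL_WALL
    lumen = labels == LABEL_LUMEN
    vessels, n_v = ndimage.label(lumen | wall)
    profiles = []
    for v in range(1, n_v + 1):
        vy, vx = ndimage.center_of_mass(vessels == v)
        rr = np.sqrt(((np.argwhere((vessels == v) & lumen)
                       - [vy, vx]) ** 2).sum(axis=1))
        r_out = rr.max()
        for i in range(n_profiles):
            theta = 2 * np.pi * i / n_profiles
            t = (np.arange(length) - length // 2) * step
            ys = vy + (r_out + t) * np.sin(theta)
            xs = vx + (r_out + t) * np.cos(theta)
            prof = ndimage.map_coordinates(image, [ys, xs], order=1,
                                           mode="nearest")
            profiles.append(prof)
    return profiles


@dataclass
class T2FitResult:
    t2_map: np.ndarray
    s0_map: np.ndarray
    fit_residual: np.ndarray
    valid_mask: np.ndarray
    near_bound_mask: np.ndarray


T2_UPPER_BOUND_MS = 1e7
T2_NEAR_BOUND_MS = 1e4


def _monoexp(te, s0, t2):
    return s0 * np.exp(-te / t2)


def fit_t2(echo_images: np.ndarray, te_list_ms, mask: np.ndarray | None = None,
           s0_threshold: float = 0.0) -> T2FitResult:
    """Voxel-wise mono-exponential T2 fit of magnitude echo images.

    ``echo_images`` is (n_echoes, ny, nx); nonlinear least squares
    initialized from a log-linear regression.  Pixels that fail to converge,
    have all-zero signal, or have fitted S0 below ``s0_threshold`` are
    excluded via ``valid_mask``; fits hitting T2 > 1e4 ms are flagged
    near-bound (kept valid).
    """
    te = np.asarray(te_list_ms, dtype=float)
    if te.size < 3:
        raise ValueError("need at least 3 echoes")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")
    imgs = np.asarray(echo_images, dtype=float)
    ny, nx = imgs.shape[1:]
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)

    t2_map = np.zeros((ny, nx))
    s0_map = np.zeros((ny, nx))
    resid = np.zeros((ny, nx))
    valid = np.zeros((ny, nx), dtype=bool)
    near_bound = np.zeros((ny, nx), dtype=bool)

    ys, xs = np.nonzero(mask)
    for y, x in zip(ys, xs):
        sig = imgs[:, y, x]
        if not np.any(sig > 0):
            continue
        pos = sig > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(te[pos], np.log(sig[pos]), 1)
            t2_0 = -1.0 / slope if slope < 0 else T2_NEAR_BOUND_MS
            s0_0 = float(np.exp(intercept))
        else:
            t2_0, s0_0 = 50.0, float(sig.max())
        t2_0 = float(np.clip(t2_0, 1.0, T2_UPPER_BOUND_MS))
        try:
            popt, _ = optimize.curve_fit(
                _monoexp, te, sig, p0=(s0_0, t2_0),
                bounds=([0.0, 0.1], [np.inf, T2_UPPER_BOUND_MS]),
                maxfev=200)
        except (RuntimeError, ValueError):
            continue
        s0, t2 = popt
        if s0 < s0_threshold:
            continue
        t2_map[y, x] = t2
        s0_map[y, x] = s0
        resid[y, x] = float(np.linalg.norm(_monoexp(te, *popt) - sig))
        valid[y, x] = True
        near_bound[y, x] = t2 > T2_NEAR_BOUND_MS
    return T2FitResult(t2_map=t2_map, s0_map=s0_map, fit_residual=resid,
                       valid_mask=valid, near_bound_mask=near_bound)
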