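"""Synthetic multi-coil MESE k-space with navigators, motion and reacquisition.

Generates a digital neck-like phantom (muscle ellipse, dark-lumen vessel
walls, a mobile "throat" structure), smooth complex coil sensitivity maps,
and a segmented multi-echo spin-echo (MESE) acquisition: one ky line per TR
for every slice, 14 imaging echoes plus a trailing unencoded (ky=0)
navigator echo per echo train.

Corruption model: each motion event applies, to every echo of the affected
TRs (navigator included), a global amplitude drop, an optional random
per-(slice, TR) phase offset, and an in-plane displacement of the throat
structure along the phase-encode (y) direction.  A slow multiplicative
drift spans the whole scan.  Reacquisition TRs are simulated at the
end-of-scan state (final drift level, optional residual throat offset).

Full ground truth (clean k-space, corrupted-line mask, event list) is
attached to the returned dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._fft import fft2c

# tissue label values used in PhantomModel.tissue_labels
LABEL_BACKGROUND = 0
LABEL_MUSCLE = 1
LABEL_WALL = 2
LABEL_LUMEN = 3
LABEL_THROAT = 4


# --------------------------------------------------------------------------
# schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSchedule:
    """Sampling schedule and timing of the segmented MESE acquisition.

    ky lines are 1-based indices on the full ``ny`` grid; with partial
    Fourier the acquired lines are ``1 .. n_acquired`` and the DC line is
    ``ny // 2 + 1`` (line 97 for a 192 matrix).  One ky line is acquired
    per TR for all slices, so TR index and acquisition-order line index
    coincide.
    """

    matrix_size: tuple[int, int] = (192, 192)
    partial_fourier: float = 5.0 / 8.0
    n_slices: int = 5
    tr_s: float = 2.0
    echo_spacing_ms: float = 9.1
    n_imaging_echoes: int = 14
    navigator_echo_index: int = 15
    n_reacq_trs: int = 0
    slice_order: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        ny, nx = self.matrix_size
        if ny % 2 or nx % 2:
            raise ValueError("matrix_size must be even along both axes")
        if not (0.5 < self.partial_fourier <= 1.0):
            raise ValueError("partial_fourier must be in (0.5, 1]")
        if self.n_acquired < self.center_line:
            raise ValueError("partial Fourier fraction excludes the ky=0 line")
        if self.navigator_echo_index < 1:
            raise ValueError("navigator_echo_index must be >= 1")
        if self.n_reacq_trs < 0:
            raise ValueError("n_reacq_trs must be >= 0")

    # -- geometry -----------------------------------------------------------
    @property
    def ny(self) -> int:
        return self.matrix_size[0]

    @property
    def nx(self) -> int:
        return self.matrix_size[1]

    @property
    def n_acquired(self) -> int:
        return int(round(self.partial_fourier * self.ny))

    @property
    def acquired_ky(self) -> np.ndarray:
        """1-based ky grid indices in acquisition (TR) order."""
        return np.arange(1, self.n_acquired + 1)

    @property
    def center_line(self) -> int:
        """1-based index of the ky=0 (DC) line: ny // 2 + 1."""
        return self.ny // 2 + 1

    @property
    def n_trs(self) -> int:
        return self.n_acquired

    @property
    def symmetric_halfwidth(self) -> int:
        """Half-width of the symmetric band around the center line."""
        return self.n_acquired - self.center_line

    # -- timing -------------------------------------------------------------
    @property
    def echo_times_ms(self) -> np.ndarray:
        return self.echo_spacing_ms * np.arange(1, self.n_imaging_echoes + 1)

    @property
    def navigator_te_ms(self) -> float:
        return self.navigator_echo_index * self.echo_spacing_ms

    def slice_block_duration_ms(self, n_echoes: int | None = None) -> float:
        """Duration of one slice acquisition block with ``n_echoes`` echoes."""
        if n_echoes is None:
            n_echoes = self.navigator_echo_index
        return n_echoes * self.echo_spacing_ms

    def navigator_overhead_ms(self) -> float:
        """Slice-block duration increase caused by the appended navigator."""
        return (self.slice_block_duration_ms(self.navigator_echo_index)
                - self.slice_block_duration_ms(self.n_imaging_echoes))

    def reacq_duration_s(self, n_reacq: int | None = None) -> float:
        """Scan-time cost of appending ``n_reacq`` reacquisition TRs."""
        if n_reacq is None:
            n_reacq = self.n_reacq_trs
        return n_reacq * self.tr_s


# --------------------------------------------------------------------------
# phantom and coils
# --------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Tissue parameters of the generated phantom (proton density is in
    arbitrary units, T2 in ms)."""

    pd_muscle: float = 1.0
    pd_wall: float = 1.3
    pd_lumen: float = 0.0
    pd_throat: float = 0.9
    t2_muscle_ms: float = 35.0
    t2_wall_ms: float = 50.0
    t2_lumen_ms: float = 200.0
    t2_throat_ms: float = 30.0
    t2_background_ms: float = 1.0
    position_jitter: float = 0.01  # seeded jitter of structures, fraction of n
    texture_sd: float = 0.08       # proton-density texture inside the object
    texture_corr_px: float = 2.0


@dataclass
class PhantomModel:
    proton_density: np.ndarray
    t2_map: np.ndarray
    tissue_labels: np.ndarray
    grid_shape: tuple[int, int]
    config: PhantomConfig = field(default_factory=PhantomConfig)


@dataclass
class CoilProfiles:
    sensitivities: np.ndarray  # (ncoils, ny, nx) complex
    ncoils: int


def _disk(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float,
          ry: float, rx: float) -> np.ndarray:
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def make_phantom(grid_shape: tuple[int, int] = (192, 192), rng_seed: int = 0,
                 config: PhantomConfig | None = None) -> PhantomModel:
    """Generate the neck-like test phantom.

    Contains a bulk muscle ellipse, two vessel-wall annuli with dark lumens
    (dark-lumen surrogate for black-blood preparation), and a labeled mobile
    throat structure.  Deterministic for a fixed seed.
    """
    ny, nx = grid_shape
    if ny < 64 or nx < 64:
        raise ValueError("grid_shape must be at least (64, 64) to contain "
                         "the vessel geometry")
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(rng_seed)
    n = float(min(ny, nx))
    jit = cfg.position_jitter * n

    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    labels = np.zeros(grid_shape, dtype=np.int32)

    # bulk neck: leaves clear background margins for ghost/background ROIs
    neck_cy, neck_cx = 0.50 * ny, 0.50 * nx
    neck = _disk(yy, xx, neck_cy, neck_cx, 0.33 * ny, 0.36 * nx)
    labels[neck] = LABEL_MUSCLE

    # two carotid-like vessels, left and right of the midline
    r_out = max(0.055 * n, 5.0)
    r_in = max(0.030 * n, 2.5)
    for side in (-1.0, 1.0):
        vy = neck_cy + 0.06 * ny + rng.uniform(-jit, jit)
        vx = neck_cx + side * 0.18 * nx + rng.uniform(-jit, jit)
        outer = _disk(yy, xx, vy, vx, r_out, r_out)
        inner = _disk(yy, xx, vy, vx, r_in, r_in)
        labels[outer] = LABEL_WALL
        labels[inner] = LABEL_LUMEN

    # mobile throat structure (anterior midline)
    ty = 0.38 * ny + rng.uniform(-jit, jit)
    tx = 0.50 * nx + rng.uniform(-jit, jit)
    throat = _disk(yy, xx, ty, tx, 0.065 * ny, 0.085 * nx)
    labels[throat] = LABEL_THROAT

    pd = np.zeros(grid_shape)
    t2 = np.full(grid_shape, cfg.t2_background_ms)
    for lab, pdv, t2v in (
        (LABEL_MUSCLE, cfg.pd_muscle, cfg.t2_muscle_ms),
        (LABEL_WALL, cfg.pd_wall, cfg.t2_wall_ms),
        (LABEL_LUMEN, cfg.pd_lumen, cfg.t2_lumen_ms),
        (LABEL_THROAT, cfg.pd_throat, cfg.t2_throat_ms),
    ):
        pd[labels == lab] = pdv
        t2[labels == lab] = t2v

    if cfg.texture_sd > 0:
        # mild smooth texture so k-space is not purely low-pass
        from scipy.ndimage import gaussian_filter

        tex = gaussian_filter(rng.standard_normal(grid_shape),
                              cfg.texture_corr_px)
        tex *= cfg.texture_sd / max(tex.std(), 1e-12)
        pd *= np.clip(1.0 + tex, 0.0, None)

    return PhantomModel(proton_density=pd, t2_map=t2, tissue_labels=labels,
                        grid_shape=(ny, nx), config=cfg)


def make_coil_profiles(phantom: PhantomModel, ncoils: int = 10,
                       rng_seed: int = 0, uniform: bool = False) -> CoilProfiles:
    """Smooth complex coil sensitivity maps.

    Gaussian magnitude lobes placed around the object perimeter with a
    smooth (low spatial frequency) phase; root-sum-of-squares sensitivity is
    strictly positive everywhere.  ``uniform=True`` returns all-ones maps.
    """
    if ncoils < 1:
        raise ValueError("ncoils must be >= 1")
    ny, nx = phantom.grid_shape
    if uniform:
        sens = np.ones((ncoils, ny, nx), dtype=complex)
        return CoilProfiles(sensitivities=sens, ncoils=ncoils)

    rng = np.random.default_rng(rng_seed)
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    cy, cx = ny / 2.0, nx / 2.0
    radius = 0.55 * min(ny, nx)
    sigma = 0.35 * min(ny, nx)
    sens = np.empty((ncoils, ny, nx), dtype=complex)
    for c in range(ncoils):
        theta = 2.0 * np.pi * c / ncoils + rng.uniform(-0.1, 0.1)
        py = cy + radius * np.sin(theta)
        px = cx + radius * np.cos(theta)
        mag = np.exp(-((yy - py) ** 2 + (xx - px) ** 2) / (2.0 * sigma ** 2))
        # smooth phase: constant + gentle linear ramp (<= 2 cycles per FOV)
        phi0 = rng.uniform(-np.pi, np.pi)
        gy, gx = rng.uniform(-2.0, 2.0, size=2)
        phase = phi0 + 2.0 * np.pi * (gy * yy / ny + gx * xx / nx) * 0.5
        sens[c] = mag * np.exp(1j * phase)
    return CoilProfiles(sensitivities=sens, ncoils=ncoils)


# --------------------------------------------------------------------------
# motion specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionEvent:
    """One swallow-like corruption event spanning TRs ``tr_start..tr_end``
    (1-based, inclusive)."""

    tr_start: int
    tr_end: int
    amplitude_drop_fraction: float
    phase_jitter_sd: float = 0.0
    throat_shift_px: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude_drop_fraction <= 1.0):
            raise ValueError("amplitude_drop_fraction must be in [0, 1]")
        if self.tr_end < self.tr_start or self.tr_start < 1:
            raise ValueError("invalid event TR range")


@dataclass(frozen=True)
class DriftSpec:
    """Slow multiplicative signal drift over the scan."""

    amplitude_fraction: float = 0.0  # total fractional drop over the scan
    shape: str = "linear"  # "linear" | "smooth"


@dataclass(frozen=True)
class MotionEventSpec:
    events: tuple[MotionEvent, ...] = ()
    drift: DriftSpec = field(default_factory=DriftSpec)

    def corrupted_tr_mask(self, n_trs: int) -> np.ndarray:
        """Boolean mask over TRs (length ``n_trs``), True inside events."""
        mask = np.zeros(n_trs, dtype=bool)
        for ev in self.events:
            if ev.tr_end > n_trs:
                raise ValueError(
                    f"event TRs {ev.tr_start}..{ev.tr_end} exceed scan "
                    f"length {n_trs}")
            mask[ev.tr_start - 1:ev.tr_end] = True
        return mask


# --------------------------------------------------------------------------
# dataset container
# --------------------------------------------------------------------------

@dataclass
class TruthInfo:
    clean_data: np.ndarray          # same layout as KSpaceDataset.data
    corrupted_tr_mask: np.ndarray   # (n_trs,) bool
    events: MotionEventSpec


@dataclass
class KSpaceDataset:
    """Segmented multi-coil multi-echo k-space plus navigators.

    data: (n_slices, n_imaging_echoes, n_trs, nx, ncoils) complex; line
    index equals TR index equals 1-based acquired ky index - 1.
    navigators: (n_slices, n_trs, nx, ncoils); reacq_* hold the same layouts
    for the reacquisition TRs, with ``reacq_tr_indices`` naming the original
    TR (1-based) each reacquisition repeats.
    """

    data: np.ndarray
    navigators: np.ndarray
    schedule: AcquisitionSchedule
    reacq_data: np.ndarray | None = None
    reacq_navigators: np.ndarray | None = None
    reacq_tr_indices: np.ndarray | None = None
    truth: TruthInfo | None = None

    @property
    def ncoils(self) -> int:
        return self.data.shape[-1]

    def copy(self) -> "KSpaceDataset":
        return dataclasses.replace(
            self,
            data=self.data.copy(),
            navigators=self.navigators.copy(),
            reacq_data=None if self.reacq_data is None else self.reacq_data.copy(),
            reacq_navigators=(None if self.reacq_navigators is None
                              else self.reacq_navigators.copy()),
            reacq_tr_indices=(None if self.reacq_tr_indices is None
                              else self.reacq_tr_indices.copy()),
        )

    def full_grid(self, sl: int, echo: int, data: np.ndarray | None = None
                  ) -> np.ndarray:
        """Zero-filled full-grid k-space (ncoils, ny, nx) for one slice/echo."""
        sched = self.schedule
        src = self.data if data is None else data
        out = np.zeros((self.ncoils, sched.ny, sched.nx), dtype=complex)
        rows = sched.acquired_ky - 1
        out[:, rows, :] = np.moveaxis(src[sl, echo], -1, 0)
        return out


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def _drift_factor(drift: DriftSpec, n_trs: int) -> np.ndarray:
    t = np.arange(n_trs) / max(n_trs - 1, 1)
    if drift.shape == "linear":
        s = t
    elif drift.shape == "smooth":
        s = 0.5 * (1.0 - np.cos(np.pi * t))
    else:
        raise ValueError(f"unknown drift shape: {drift.shape!r}")
    return 1.0 - drift.amplitude_fraction * s


def _slice_scales(n_slices: int) -> np.ndarray:
    # deterministic mild variation across slices
    idx = np.arange(n_slices)
    return 1.0 - 0.04 * np.abs(idx - (n_slices - 1) / 2.0)


def _echo_kspaces(phantom: PhantomModel, coils: CoilProfiles,
                  te_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-echo per-coil k-space of the static part and the throat part."""
    pd, t2, labels = (phantom.proton_density, phantom.t2_map,
                      phantom.tissue_labels)
    throat = labels == LABEL_THROAT
    decay = np.exp(-te_ms[:, None, None] / t2[None])  # (ne, ny, nx)
    static_imgs = (pd * ~throat)[None] * decay
    throat_imgs = (pd * throat)[None] * decay
    sens = coils.sensitivities  # (nc, ny, nx)
    k_static = fft2c(static_imgs[:, None] * sens[None])  # (ne, nc, ny, nx)
    k_throat = fft2c(throat_imgs[:, None] * sens[None])
    return k_static, k_throat


def _per_tr_state(motion: MotionEventSpec, n_trs: int
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-TR amplitude factor, phase-jitter sd, and throat shift."""
    amp = _drift_factor(motion.drift, n_trs)
    jitter_sd = np.zeros(n_trs)
    shift = np.zeros(n_trs)
    motion.corrupted_tr_mask(n_trs)  # validates TR ranges
    for ev in motion.events:
        sel = slice(ev.tr_start - 1, ev.tr_end)
        amp[sel] *= (1.0 - ev.amplitude_drop_fraction)
        jitter_sd[sel] = ev.phase_jitter_sd
        shift[sel] = ev.throat_shift_px
    return amp, jitter_sd, shift


def _complex_noise(rng: np.random.Generator, shape: tuple[int, ...],
                   sd: float) -> np.ndarray:
    """Circular complex Gaussian noise; ``sd`` is the std of the real and
    imaginary parts individually."""
    if sd == 0.0:
        return np.zeros(shape, dtype=complex)
    return sd * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))


def simulate_mese_kspace(phantom: PhantomModel, coils: CoilProfiles,
                         schedule: AcquisitionSchedule,
                         motion: MotionEventSpec | None = None,
                         noise_sd: float = 0.0, rng_seed: int = 0,
                         reacq_shift_px: float = 0.5,
                         reacq_weighting: np.ndarray | None = None,
                         ) -> KSpaceDataset:
    """Simulate the segmented MESE acquisition with navigators.

    Each TR acquires one ky line of all slices at the TR's object state
    (drift x event amplitude, per-(slice, TR) phase jitter, throat
    displacement), the navigator being the ky=0 line of the appended echo.
    Reacquisition TRs (``schedule.n_reacq_trs``) repeat the lowest-scoring
    TRs at end-of-scan state: final drift level, no event, residual throat
    offset ``reacq_shift_px``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    motion = motion or MotionEventSpec()
    sched = schedule
    rng = np.random.default_rng(rng_seed)
    nsl, ne, n_trs = sched.n_slices, sched.n_imaging_echoes, sched.n_trs
    ny, nx = sched.ny, sched.nx
    nc = coils.ncoils

    te_all = np.append(sched.echo_times_ms, sched.navigator_te_ms)
    k_static, k_throat = _echo_kspaces(phantom, coils, te_all)

    rows = sched.acquired_ky - 1                      # 0-based grid rows
    f_ky = (rows - ny // 2) / float(ny)               # cycles / pixel shift
    amp, jitter_sd, shift = _per_tr_state(motion, n_trs)
    ramp = np.exp(-2j * np.pi * f_ky * shift)         # (n_trs,)

    phases = rng.standard_normal((nsl, n_trs)) * jitter_sd[None, :]
    scales = _slice_scales(nsl)
    fac = scales[:, None] * amp[None, :] * np.exp(1j * phases)  # (nsl, n_trs)

    lines = (k_static[:ne, :, rows, :]
             + ramp[None, None, :, None] * k_throat[:ne, :, rows, :])
    data = np.einsum("st,ectx->setxc", fac, lines)
    data += _complex_noise(rng, data.shape, noise_sd)

    c_row = ny // 2  # ky = 0: throat shift along y leaves this line's ramp = 1
    nav_line = k_static[ne, :, c_row, :] + k_throat[ne, :, c_row, :]  # (nc, nx)
    navigators = np.einsum("st,cx->stxc", fac, nav_line)
    navigators += _complex_noise(rng, navigators.shape, noise_sd)

    clean = np.einsum("s,ectx->setxc", scales,
                      k_static[:ne, :, rows, :] + k_throat[:ne, :, rows, :])
    truth = TruthInfo(clean_data=clean,
                      corrupted_tr_mask=motion.corrupted_tr_mask(n_trs),
                      events=motion)

    reacq_data = reacq_navs = reacq_idx = None
    if sched.n_reacq_trs > 0:
        from .reacquisition import select_reacq_trs

        tr_scores = np.abs(navigators).sum(axis=(0, 2, 3))
        plan = select_reacq_trs(tr_scores, sched.n_reacq_trs,
                                ky_of_tr=sched.acquired_ky,
                                center_line=sched.center_line,
                                weighting=reacq_weighting)
        reacq_idx = np.asarray(plan.tr_indices, dtype=int)
        r_rows = rows[reacq_idx - 1]
        amp_r = amp[-1] if motion.drift.amplitude_fraction else 1.0
        ramp_r = np.exp(-2j * np.pi * (r_rows - ny // 2) / float(ny)
                        * reacq_shift_px)
        r_lines = (k_static[:ne, :, r_rows, :]
                   + ramp_r[None, None, :, None] * k_throat[:ne, :, r_rows, :])
        reacq_data = np.einsum("s,ectx->setxc", scales * amp_r, r_lines)
        reacq_data += _complex_noise(rng, reacq_data.shape, noise_sd)
        r_nav = np.broadcast_to(nav_line[:, None, :],
                                (nc, len(reacq_idx), nx))
        reacq_navs = np.einsum("s,ctx->stxc", scales * amp_r, r_nav)
        reacq_navs = reacq_navs + _complex_noise(rng, reacq_navs.shape,
                                                 noise_sd)

    return KSpaceDataset(data=data, navigators=navigators, schedule=sched,
                         reacq_data=reacq_data, reacq_navigators=reacq_navs,
                         reacq_tr_indices=reacq_idx, truth=truth)


def simulate_navigators(phantom: PhantomModel, coils: CoilProfiles,
                        schedule: AcquisitionSchedule,
                        motion: MotionEventSpec | None = None,
                        noise_sd: float = 0.0, rng_seed: int = 0) -> np.ndarray:
    """Fast path: simulate only the navigator readouts.

    Returns (n_slices, n_trs, nx, ncoils); same state model as
    :func:`simulate_mese_kspace` but skips the imaging echoes, for
    detector-performance studies over many seeded scans.
    """
    motion = motion or MotionEventSpec()
    sched = schedule
    rng = np.random.default_rng(rng_seed)
    nsl, n_trs = sched.n_slices, sched.n_trs
    te = np.asarray([sched.navigator_te_ms])
    k_static, k_throat = _echo_kspaces(phantom, coils, te)
    c_row = sched.ny // 2
    nav_line = k_static[0, :, c_row, :] + k_throat[0, :, c_row, :]

    amp, jitter_sd, _ = _per_tr_state(motion, n_trs)
    phases = rng.standard_normal((nsl, n_trs)) * jitter_sd[None, :]
    fac = _slice_scales(nsl)[:, None] * amp[None, :] * np.exp(1j * phases)
    navigators = np.einsum("st,cx->stxc", fac, nav_line)
    navigators += _complex_noise(rng, navigators.shape, noise_sd)
    return navigators


def truth_corrupted_mask(dataset: KSpaceDataset) -> np.ndarray:
    """Ground-truth per-(slice, ky) corruption mask, True for lines acquired
    during event TRs (identical across slices by construction)."""
    if dataset.truth is None:
        raise ValueError("dataset has no ground truth attached")
    tr_mask = dataset.truth.corrupted_tr_mask
    return np.broadcast_to(tr_mask[None, :],
                           (dataset.schedule.n_slices, tr_mask.size)).copy()
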