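"""Navigator quality scores, drift adjustment and corruption detection.

The slice score of one echo train is the magnitude of the navigator readout
summed over readout points and coils; the per-TR quality score sums the
slice scores of all slices in the TR block.  Slow drift is removed by
subtracting a sliding local median, and corrupted TRs are flagged as
one-sided (low) outliers against a Hampel criterion: more than ``n_sd``
scaled-MAD units below the local median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import KSpaceDataset

MAD_SCALE = 1.4826  # scaled MAD -> sigma for Gaussian data


@dataclass
class QualityTrace:
    """Per-slice and per-TR navigator quality scores and corruption flags."""

    slice_scores: np.ndarray          # (n_slices, n_trs)
    tr_scores: np.ndarray             # (n_trs,)
    adjusted_tr_scores: np.ndarray    # (n_trs,)
    corrupted_mask: np.ndarray        # (n_trs,) bool
    slice_corrupted_mask: np.ndarray | None = None  # (n_slices, n_trs) bool
    weighting: np.ndarray | None = None

    @property
    def n_trs(self) -> int:
        return self.tr_scores.size


def slice_score(navigator_readout: np.ndarray) -> float:
    """Sum of magnitude over all readout samples and channels."""
    nav = np.asarray(navigator_readout)
    if nav.size == 0:
        raise ValueError("empty navigator readout")
    return float(np.abs(nav).sum())


def tr_quality_score(slice_scores_for_tr, n_slices: int | None = None) -> float:
    """Quality score of one TR block: sum of its slice scores."""
    s = np.asarray(slice_scores_for_tr, dtype=float)
    if n_slices is not None and s.size != n_slices:
        raise ValueError(f"expected {n_slices} slice scores, got {s.size}")
    return float(s.sum())


def _sliding_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding median with truncated (shrinking) edge windows.

    For even ``window`` the centered span is ``[i - (w-1)//2, i + w//2]``.
    """
    n = x.size
    lo_half = (window - 1) // 2
    hi_half = window // 2
    med = np.empty(n)
    for i in range(n):
        lo = max(0, i - lo_half)
        hi = min(n, i + hi_half + 1)
        med[i] = np.median(x[lo:hi])
    return med


def adjust_drift(scores, window: int = 10) -> np.ndarray:
    """Subtract the local sliding-window median from the score sequence."""
    x = np.asarray(scores, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if x.size < window:
        raise ValueError(f"need at least {window} scores, got {x.size}")
    return x - _sliding_median(x, window)


def detect_corrupted(adjusted_scores, window: int = 25,
                     n_sd: float = 3.0) -> np.ndarray:
    """One-sided Hampel outlier detection on drift-adjusted scores.

    Index ``i`` is flagged iff its score is lower than the local median by
    more than ``n_sd`` times the scaled MAD (1.4826 x MAD) of the centered
    ``window``; edge windows are truncated.  Only low scores are flagged.
    """
    x = np.asarray(adjusted_scores, dtype=float)
    if window < 3:
        raise ValueError("window must be >= 3")
    n = x.size
    lo_half = (window - 1) // 2
    hi_half = window // 2
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - lo_half)
        hi = min(n, i + hi_half + 1)
        w = x[lo:hi]
        med = np.median(w)
        sigma = MAD_SCALE * np.median(np.abs(w - med))
        flags[i] = x[i] < med - n_sd * sigma
    return flags


def gaussian_weighting(ny: int, center_line: int,
                       fwhm_lines: float = 48.0) -> np.ndarray:
    """Unimodal ky weighting peaking at the center line (peak value 1).

    Indexed by 1-based ky grid line; used to make raw-score deficits near
    the k-space center rank as worse quality.
    """
    ky = np.arange(1, ny + 1, dtype=float)
    sigma = fwhm_lines / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((ky - center_line) / sigma) ** 2)


def triangular_weighting(ny: int, center_line: int,
                         halfwidth_lines: float = 48.0,
                         floor: float = 0.05) -> np.ndarray:
    """Triangular ky weighting peaking at the center line, clipped at
    ``floor`` so weights stay positive."""
    ky = np.arange(1, ny + 1, dtype=float)
    w = 1.0 - np.abs(ky - center_line) / halfwidth_lines
    return np.maximum(w, floor)


def center_weighted_score(tr_score: float, ky: int,
                          weighting: np.ndarray | None) -> float:
    """Quality score divided by the ky weight, amplifying deficits near the
    k-space center so central TRs rank lower (worse) for equal raw score."""
    if weighting is None:
        return float(tr_score)
    w = weighting[ky - 1]
    if w <= 0:
        raise ValueError(f"nonpositive weight {w} at ky={ky}")
    return float(tr_score) / float(w)


def score_dataset(dataset: KSpaceDataset, drift_window: int = 10,
                  hampel_window: int = 25, n_sd: float = 3.0,
                  per_slice: bool = False,
                  weighting: np.ndarray | None = None) -> QualityTrace:
    """Compute the full quality trace of a dataset's navigators."""
    nav = dataset.navigators  # (n_slices, n_trs, nx, nc)
    slice_scores = np.abs(nav).sum(axis=(2, 3))
    tr_scores = slice_scores.sum(axis=0)
    adjusted = adjust_drift(tr_scores, window=drift_window)
    mask = detect_corrupted(adjusted, window=hampel_window, n_sd=n_sd)
    slice_mask = None
    if per_slice:
        slice_mask = np.stack([
            detect_corrupted(adjust_drift(s, window=drift_window),
                             window=hampel_window, n_sd=n_sd)
            for s in slice_scores
        ])
    return QualityTrace(slice_scores=slice_scores, tr_scores=tr_scores,
                        adjusted_tr_scores=adjusted, corrupted_mask=mask,
                        slice_corrupted_mask=slice_mask, weighting=weighting)


def reacq_tr_scores(dataset: KSpaceDataset) -> np.ndarray:
    """Quality scores of the reacquisition TRs from their navigators."""
    if dataset.reacq_navigators is None:
        raise ValueError("dataset has no reacquisition navigators")
    return np.abs(dataset.reacq_navigators).sum(axis=(0, 2, 3))
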