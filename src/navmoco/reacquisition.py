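"""Reacquisition scheduling and merging of reacquired k-space lines.

TRs with the lowest (optionally center-weighted) quality scores are selected
for reacquisition at the end of the scan.  Merging replaces a corrupted line
with its reacquisition only if the reacquired line's quality score is higher
than the original one; the "central" mode restricts replacement to the lines
at the center of k-space that protect the parallel-imaging calibration
region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scoring import QualityTrace, center_weighted_score
from .synthetic import KSpaceDataset


@dataclass(frozen=True)
class ReacqPlan:
    tr_indices: tuple[int, ...]  # 1-based TR indices, worst first
    n_reacq: int


@dataclass
class MergeLog:
    """Record of a merge operation."""

    replaced_trs: list[int] = field(default_factory=list)  # 1-based
    updated_scores: np.ndarray | None = None
    updated_mask: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)


def select_reacq_trs(tr_scores, n_reacq: int,
                     ky_of_tr: np.ndarray | None = None,
                     center_line: int | None = None,
                     weighting: np.ndarray | None = None) -> ReacqPlan:
    """Select the ``n_reacq`` TRs with the lowest (weighted) quality scores.

    Ties are broken by proximity of the TR's ky line to the center line,
    then by lower TR index.
    """
    scores = np.asarray(tr_scores, dtype=float)
    n = scores.size
    if not (0 <= n_reacq <= n):
        raise ValueError(f"n_reacq={n_reacq} outside [0, {n}]")
    if ky_of_tr is None:
        ky_of_tr = np.arange(1, n + 1)
    ky_of_tr = np.asarray(ky_of_tr, dtype=int)
    if center_line is None:
        center_line = int(np.max(ky_of_tr) // 2 + 1)
    if weighting is not None:
        ranked = np.array([center_weighted_score(s, ky, weighting)
                           for s, ky in zip(scores, ky_of_tr)])
    else:
        ranked = scores
    order = sorted(range(n), key=lambda i: (ranked[i],
                                            abs(int(ky_of_tr[i]) - center_line),
                                            i))
    chosen = tuple(int(i) + 1 for i in order[:n_reacq])
    return ReacqPlan(tr_indices=chosen, n_reacq=n_reacq)


def _merge(dataset: KSpaceDataset, corrupted_mask: np.ndarray,
           orig_scores: np.ndarray, reacq_scores: np.ndarray,
           candidate_trs: np.ndarray) -> tuple[KSpaceDataset, MergeLog]:
    if dataset.reacq_data is None or dataset.reacq_tr_indices is None:
        raise ValueError("dataset has no reacquisition block")
    out = dataset.copy()
    log = MergeLog(updated_scores=np.asarray(orig_scores, dtype=float).copy(),
                   updated_mask=np.asarray(corrupted_mask, bool).copy())
    reacq_idx = np.asarray(dataset.reacq_tr_indices, dtype=int)
    reacq_scores = np.asarray(reacq_scores, dtype=float)

    for tr in np.flatnonzero(np.asarray(corrupted_mask, bool)) + 1:
        if tr not in candidate_trs:
            continue
        slots = np.flatnonzero(reacq_idx == tr)
        if slots.size == 0:
            log.warnings.append(
                f"corrupted TR {tr} has no reacquisition available")
            continue
        best = slots[np.argmax(reacq_scores[slots])]
        if reacq_scores[best] > log.updated_scores[tr - 1]:
            out.data[:, :, tr - 1] = dataset.reacq_data[:, :, best]
            out.navigators[:, tr - 1] = dataset.reacq_navigators[:, best]
            log.updated_scores[tr - 1] = reacq_scores[best]
            log.updated_mask[tr - 1] = False
            log.replaced_trs.append(int(tr))
    return out, log


def replace_central_lines(dataset: KSpaceDataset, qc: QualityTrace,
                          reacq_scores, n_central: int = 7
                          ) -> tuple[KSpaceDataset, MergeLog]:
    """Replace corrupted lines among the ``n_central`` lines centered on the
    ky=0 line with reacquisitions, when the reacquired score is higher.

    Protects the parallel-imaging calibration region; corrupted central
    lines without a usable reacquisition are recorded as warnings and left
    for the estimation/merge policy.
    """
    sched = dataset.schedule
    half = n_central // 2
    central = np.arange(sched.center_line - half, sched.center_line + half + 1)
    central = central[(central >= 1) & (central <= sched.n_acquired)]
    return _merge(dataset, qc.corrupted_mask, qc.tr_scores, reacq_scores,
                  candidate_trs=central)


def merge_reacq_all(dataset: KSpaceDataset, qc: QualityTrace,
                    reacq_scores) -> tuple[KSpaceDataset, MergeLog]:
    """Replace every corrupted line with its reacquisition under the
    higher-score rule (the pure-reacquisition comparator)."""
    all_trs = np.arange(1, dataset.schedule.n_trs + 1)
    return _merge(dataset, qc.corrupted_mask, qc.tr_scores, reacq_scores,
                  candidate_trs=all_trs)
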