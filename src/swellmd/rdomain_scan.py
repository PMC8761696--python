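"""Sliding-window assignment of an unresolved 17-residue segment.

Candidate windows of the regulatory-domain sequence are enumerated one
residue at a time, walking backwards from an anchor residue. Each window is
split into a leading disordered coil and a trailing 9-residue helix, scored
by the trailing-window mean backbone-CA RMSD of the segment against a
reference structure (fitting on the rest of the protein), and ranked
ascending; rank 1 is the most stable candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import md_geometry
from .md_geometry import AtomSelection, StructureModel, Trajectory

__all__ = [
    "AssignmentWindow",
    "StabilityRecord",
    "CoverageError",
    "enumerate_windows",
    "map_secondary_structure",
    "rank_by_stability",
    "score_assignment",
]

HELIX_LEN = 9  # trailing helix length within each window


class CoverageError(ValueError):
    """The supplied sequence does not cover the scanned residue range."""


@dataclass(frozen=True)
class AssignmentWindow:
    """One candidate placement of the unresolved segment.

    Residue numbers are 1-based and inclusive; ``sequence`` holds the
    one-letter codes at those positions.
    """

    start_res: int
    end_res: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end_res - self.start_res + 1 != len(self.sequence):
            raise ValueError("sequence length must match the residue span")

    @property
    def n_residues(self) -> int:
        return self.end_res - self.start_res + 1

    @property
    def coil_span(self) -> tuple[int, int] | None:
        coil, _ = map_secondary_structure(self)
        return coil

    @property
    def helix_span(self) -> tuple[int, int]:
        _, helix = map_secondary_structure(self)
        return helix


@dataclass
class StabilityRecord:
    window: AssignmentWindow
    mean_backbone_rmsd: float  # Angstrom
    rank: int  # 1 = most stable


def enumerate_windows(
    sequence: str,
    seq_start_res: int = 1,
    window_len: int = 17,
    anchor_end_res: int = 842,
    n_windows: int = 24,
) -> list[AssignmentWindow]:
    """Enumerate candidate windows ending at anchor_end_res, anchor_end_res-1, ...

    ``sequence`` is indexed so that its first letter sits at residue
    ``seq_start_res``; it must cover every residue the scan touches
    (``anchor_end_res - window_len - n_windows + 2`` through
    ``anchor_end_res``).
    """
    if window_len < 1 or n_windows < 1:
        raise ValueError("window_len and n_windows must be >= 1")
    lowest = anchor_end_res - window_len - n_windows + 2
    seq_end_res = seq_start_res + len(sequence) - 1
    if seq_start_res > lowest or seq_end_res < anchor_end_res:
        raise CoverageError(
            f"sequence covers {seq_start_res}-{seq_end_res}; scan needs "
            f"{lowest}-{anchor_end_res}"
        )
    windows = []
    for k in range(n_windows):
        end = anchor_end_res - k
        start = end - window_len + 1
        sub = sequence[start - seq_start_res : end - seq_start_res + 1]
        windows.append(AssignmentWindow(start_res=start, end_res=end, sequence=sub))
    return windows


def map_secondary_structure(
    window: AssignmentWindow,
) -> tuple[tuple[int, int] | None, tuple[int, int]]:
    """Split a window into (coil_span, helix_span): coil first, helix = last 9.

    Returns residue-number spans, inclusive; the coil span is ``None`` for a
    window of exactly 9 residues.
    """
    if window.n_residues < HELIX_LEN:
        raise ValueError(f"window must have >= {HELIX_LEN} residues")
    helix = (window.end_res - HELIX_LEN + 1, window.end_res)
    if window.n_residues == HELIX_LEN:
        return None, helix
    coil = (window.start_res, helix[0] - 1)
    return coil, helix


def rank_by_stability(
    records: list[tuple[AssignmentWindow, float]],
) -> list[StabilityRecord]:
    """Sort candidates ascending by RMSD (ties: smaller start_res first)."""
    if not records:
        raise ValueError("no records to rank")
    for _, rmsd in records:
        if not np.isfinite(rmsd):
            raise ValueError("rmsd values must be finite")
    ordered = sorted(records, key=lambda wr: (wr[1], wr[0].start_res))
    return [
        StabilityRecord(window=w, mean_backbone_rmsd=float(r), rank=i + 1)
        for i, (w, r) in enumerate(ordered)
    ]


def score_assignment(
    traj: Trajectory,
    reference: StructureModel,
    segment_span: tuple[int, int],
    window=None,
) -> float:
    """Mean segment-CA RMSD to the reference over a trailing frame window.

    The fit uses the CA atoms of every residue outside the segment, so the
    score reflects the segment's own motion, not global drift. ``window`` is
    a (start, stop) frame range; default = the trailing half of the frames.
    """
    lo, hi = segment_span
    seg_sel = AtomSelection(
        residue_ranges=((lo, hi),), atom_names=frozenset({"CA"})
    )
    all_res = reference.residue_ids
    rest_ranges = _complement_ranges(all_res, lo, hi)
    if not rest_ranges:
        raise md_geometry.SelectionError("segment spans the whole structure")
    fit_sel = AtomSelection(
        residue_ranges=tuple(rest_ranges), atom_names=frozenset({"CA"})
    )
    series = md_geometry.rmsd_series(
        traj, reference, selection=seg_sel, fit=True, fit_selection=fit_sel
    )
    if window is None:
        window = (traj.n_frames // 2, traj.n_frames)
        if window[0] >= window[1]:
            window = (0, traj.n_frames)
    w0, w1 = window
    if not (0 <= w0 < w1 <= traj.n_frames):
        raise md_geometry.WindowError(f"window {window} outside frames")
    return float(series[w0:w1].mean())


def _complement_ranges(resids: np.ndarray, lo: int, hi: int) -> list[tuple[int, int]]:
    """Inclusive ranges covering all residue ids outside [lo, hi]."""
    outside = np.sort(resids[(resids < lo) | (resids > hi)])
    ranges: list[tuple[int, int]] = []
    for r in outside:
        if ranges and r == ranges[-1][1] + 1:
            ranges[-1] = (ranges[-1][0], int(r))
        else:
            ranges.append((int(r), int(r)))
    return ranges
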