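"""Structure and trajectory geometry: superposition, RMSD/RMSF profiles,
minimum-distance series, salt-bridge contacts and C-alpha separations.

Coordinates are in Angstrom throughout. Residue numbering is 1-based and
residue spans are inclusive on both ends (e.g. ``630-856`` covers 227
residues). Periodic boundary conditions are not applied; input coordinates
are assumed whole/unwrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "StructureModel",
    "Trajectory",
    "AtomSelection",
    "ProfileSeries",
    "DistanceSeries",
    "SelectionError",
    "FitError",
    "WindowError",
    "parse_selection",
    "span_residue_count",
    "superpose",
    "rmsd_series",
    "residue_rmsd",
    "rmsf",
    "min_distance_series",
    "saltbridge_contact_fraction",
    "min_calpha_distance",
    "read_pdb",
    "write_pdb",
    "BASIC_SIDECHAIN_N",
    "ACIDIC_SIDECHAIN_O",
]

#: Side-chain nitrogen atoms that can carry a positive charge (Lys, Arg, His).
BASIC_SIDECHAIN_N = frozenset({"NZ", "NH1", "NH2", "NE", "ND1", "NE2"})
#: Side-chain carboxylate oxygens (Asp, Glu).
ACIDIC_SIDECHAIN_O = frozenset({"OD1", "OD2", "OE1", "OE2"})


class SelectionError(ValueError):
    """A selection resolved to no atoms or to an invalid atom set."""


class FitError(ValueError):
    """Superposition is impossible (too few atoms or degenerate geometry)."""


class WindowError(ValueError):
    """A frame-averaging window falls outside the trajectory."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class StructureModel:
    """A set of atoms with names, residue numbering and coordinates (Angstrom)."""

    atom_names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    elements: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype="U4")
        self.chains = np.asarray(self.chains, dtype="U4")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.elements is None:
            self.elements = np.array([n[:1] for n in self.atom_names], dtype="U2")
        n = len(self.atom_names)
        if not (len(self.resids) == len(self.resnames) == len(self.chains) == n):
            raise ValueError("atom annotation arrays must share one length")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be ({n}, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue numbers in order of first appearance."""
        _, idx = np.unique(self.resids, return_index=True)
        return self.resids[np.sort(idx)]

    def select(self, selection: "AtomSelection | str") -> np.ndarray:
        if isinstance(selection, str):
            selection = parse_selection(selection)
        return selection.resolve(self)

    def subset(self, indices: np.ndarray) -> "StructureModel":
        return StructureModel(
            atom_names=self.atom_names[indices],
            resids=self.resids[indices],
            resnames=self.resnames[indices],
            chains=self.chains[indices],
            coords=self.coords[indices],
            elements=self.elements[indices],
        )

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class Trajectory:
    """Per-frame coordinate sets over a fixed topology."""

    topology: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    frame_times: np.ndarray | None = None  # ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                "frames must be (n_frames, n_atoms, 3) matching the topology"
            )
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames, dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != self.n_frames:
                raise ValueError("frame_times length must equal n_frames")
            if np.any(np.diff(self.frame_times) < 0):
                raise ValueError("frame_times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class AtomSelection:
    """Atom filter by chain, inclusive residue range(s) and atom-name set.

    ``residue_ranges`` are (low, high) pairs, both ends included; ``None``
    fields do not constrain. Resolving against a topology with zero matches
    raises :class:`SelectionError`.
    """

    chains: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: frozenset[str] | None = None

    def mask(self, structure: StructureModel) -> np.ndarray:
        m = np.ones(structure.n_atoms, dtype=bool)
        if self.chains is not None:
            m &= np.isin(structure.chains, list(self.chains))
        if self.residue_ranges is not None:
            rm = np.zeros(structure.n_atoms, dtype=bool)
            for lo, hi in self.residue_ranges:
                rm |= (structure.resids >= lo) & (structure.resids <= hi)
            m &= rm
        if self.atom_names is not None:
            m &= np.isin(structure.atom_names, list(self.atom_names))
        return m

    def resolve(self, structure: StructureModel) -> np.ndarray:
        idx = np.flatnonzero(self.mask(structure))
        if idx.size == 0:
            raise SelectionError(f"selection {self} matches no atoms")
        return idx


def parse_selection(text: str) -> AtomSelection:
    """Parse the selection mini-language.

    Clauses joined by ``and``: ``chain A``, ``resid 10-20`` (comma lists and
    single ids allowed, ranges inclusive), ``name CA,CB``.
    """
    chains: set[str] | None = None
    ranges: list[tuple[int, int]] | None = None
    names: set[str] | None = None
    for clause in text.split(" and "):
        parts = clause.strip().split(None, 1)
        if len(parts) != 2:
            raise SelectionError(f"cannot parse selection clause {clause!r}")
        key, value = parts
        if key == "chain":
            chains = (chains or set()) | set(value.replace(",", " ").split())
        elif key == "name":
            names = (names or set()) | set(value.replace(",", " ").split())
        elif key == "resid":
            ranges = ranges or []
            for item in value.replace(",", " ").split():
                if "-" in item[1:]:
                    lo, hi = item.split("-", 1)
                    ranges.append((int(lo), int(hi)))
                else:
                    ranges.append((int(item), int(item)))
        else:
            raise SelectionError(f"unknown selection keyword {key!r}")
    return AtomSelection(
        chains=frozenset(chains) if chains else None,
        residue_ranges=tuple(ranges) if ranges else None,
        atom_names=frozenset(names) if names else None,
    )


def span_residue_count(start_res: int, end_res: int) -> int:
    """Number of residues in an inclusive 1-based span (``630-856`` -> 227)."""
    if end_res < start_res:
        raise ValueError("end_res must be >= start_res")
    return end_res - start_res + 1


@dataclass
class ProfileSeries:
    """Per-residue profile (RMSD or RMSF), Angstrom."""

    residue_ids: np.ndarray
    values: np.ndarray
    statistic: str  # "RMSD" | "RMSF"
    window: tuple[int, int]  # frame range, half-open

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("profile values must be non-negative")


@dataclass
class DistanceSeries:
    """Per-frame minimum distance between two selections, Angstrom."""

    values: np.ndarray
    summary_window: tuple[int, int]
    summary_mean: float = field(init=False)
    summary_sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = self.summary_window
        if not (0 <= lo < hi <= len(self.values)):
            raise WindowError(f"summary window {self.summary_window} outside frames")
        tail = self.values[lo:hi]
        self.summary_mean = float(tail.mean())
        self.summary_sd = float(tail.std(ddof=1)) if len(tail) > 1 else 0.0


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimising |R m + t - r|^2.

    Proper rotation only (no reflection). Raises FitError on degenerate input.
    """
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise FitError("superposition needs >= 3 paired atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    # collinear (or coincident) point sets leave the rotation underdetermined
    spread_m = np.linalg.svd(mobile - mc, compute_uv=False)
    if spread_m[0] < 1e-10 or spread_m[1] < 1e-8 * spread_m[0]:
        raise FitError("degenerate (collinear) fit selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = rc - rot @ mc
    return rot, trans


def superpose(
    mobile_coords: np.ndarray,
    reference_coords: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The transform is fitted on ``fit_selection`` (indices into both coordinate
    arrays; default all atoms) and applied to every mobile atom. Returns the
    transformed coordinates and the post-fit RMSD over the fit selection.
    """
    mobile_coords = np.asarray(mobile_coords, dtype=float)
    reference_coords = np.asarray(reference_coords, dtype=float)
    if fit_selection is None:
        fit_selection = np.arange(len(mobile_coords))
    fit_selection = np.asarray(fit_selection, dtype=int)
    rot, trans = _kabsch(mobile_coords[fit_selection], reference_coords[fit_selection])
    moved = mobile_coords @ rot.T + trans
    diff = moved[fit_selection] - reference_coords[fit_selection]
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return moved, rmsd


def _resolve(structure: StructureModel, selection) -> np.ndarray:
    if selection is None:
        selection = AtomSelection(atom_names=frozenset({"CA"}))
    if isinstance(selection, (str, AtomSelection)):
        return structure.select(selection)
    return np.asarray(selection, dtype=int)


def _fitted_frames(
    traj: Trajectory,
    reference: StructureModel,
    fit_idx: np.ndarray | None,
) -> np.ndarray:
    """Frames after optional per-frame rigid superposition onto the reference."""
    if fit_idx is None:
        return traj.frames
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        out[f], _ = superpose(traj.frames[f], reference.coords, fit_idx)
    return out


def rmsd_series(
    traj: Trajectory,
    reference: StructureModel,
    selection=None,
    fit: bool = True,
    fit_selection=None,
) -> np.ndarray:
    """Per-frame RMSD(t) = sqrt(mean_i |x_i(t) - x_i_ref|^2) over a selection.

    With ``fit=True`` each frame is first rigidly superposed onto the
    reference using ``fit_selection`` (default: the analysis selection).
    """
    idx = _resolve(traj.topology, selection)
    ref_idx = _resolve(reference, selection)
    if len(idx) != len(ref_idx):
        raise SelectionError("selection resolves to different atom counts")
    fit_idx = None
    if fit:
        fit_idx = idx if fit_selection is None else _resolve(traj.topology, fit_selection)
    frames = _fitted_frames(traj, reference, fit_idx)
    diff = frames[:, idx, :] - reference.coords[ref_idx][None, :, :]
    return np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))


def _check_window(traj: Trajectory, window) -> tuple[int, int]:
    if window is None:
        return 0, traj.n_frames
    lo, hi = window
    if not (0 <= lo < hi <= traj.n_frames):
        raise WindowError(f"window {window} outside 0..{traj.n_frames}")
    return int(lo), int(hi)


def _per_residue_deviation(
    traj: Trajectory,
    reference: StructureModel,
    selection,
    fit: bool,
    fit_selection,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fitted per-frame coordinates of a one-atom-per-residue selection."""
    idx = _resolve(traj.topology, selection)
    resids = traj.topology.resids[idx]
    if len(np.unique(resids)) != len(resids):
        raise SelectionError("selection must resolve to one atom per residue")
    fit_idx = None
    if fit:
        fit_idx = idx if fit_selection is None else _resolve(traj.topology, fit_selection)
    frames = _fitted_frames(traj, reference, fit_idx)
    return frames[:, idx, :], reference.coords[idx], resids


def residue_rmsd(
    traj: Trajectory,
    reference: StructureModel,
    selection=None,
    window=None,
    fit: bool = True,
    fit_selection=None,
) -> ProfileSeries:
    """Residue-wise RMSD to the reference, averaged over a frame window.

    For each residue i: sqrt(mean_t |x_i(t) - x_i_ref|^2) over the window,
    after per-frame global superposition on the fit selection.
    """
    lo, hi = _check_window(traj, window)
    coords, ref, resids = _per_residue_deviation(traj, reference, selection, fit, fit_selection)
    diff = coords[lo:hi] - ref[None, :, :]
    vals = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=0))
    return ProfileSeries(resids, vals, "RMSD", (lo, hi))


def rmsf(
    traj: Trajectory,
    reference: StructureModel,
    selection=None,
    window=None,
    mode: str = "reference",
    fit: bool = True,
    fit_selection=None,
) -> ProfileSeries:
    """Residue-wise root-mean-square fluctuation over a frame window.

    mode "reference": sqrt(<|x_i - x_i_ref|^2>) — deviation from the fixed
    reference position. mode "mean": deviation from the time-mean position.
    The two differ by any static offset of a residue from the reference.
    """
    if mode not in ("reference", "mean"):
        raise ValueError(f"unknown rmsf mode {mode!r}")
    lo, hi = _check_window(traj, window)
    coords, ref, resids = _per_residue_deviation(traj, reference, selection, fit, fit_selection)
    coords = coords[lo:hi]
    center = ref[None, :, :] if mode == "reference" else coords.mean(axis=0, keepdims=True)
    diff = coords - center
    vals = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=0))
    return ProfileSeries(resids, vals, "RMSF", (lo, hi))


# ---------------------------------------------------------------------------
# distances and contacts
# ---------------------------------------------------------------------------


def min_distance_series(
    traj: Trajectory,
    selection_a,
    selection_b,
    summary_window=None,
) -> DistanceSeries:
    """Per-frame minimum distance over all cross pairs of two disjoint selections."""
    ia = _resolve(traj.topology, selection_a)
    ib = _resolve(traj.topology, selection_b)
    if np.intersect1d(ia, ib).size:
        raise SelectionError("selections must be disjoint")
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        vals[f] = cdist(traj.frames[f, ia], traj.frames[f, ib]).min()
    if summary_window is None:
        summary_window = (traj.n_frames // 2, traj.n_frames)
        if summary_window[0] >= summary_window[1]:
            summary_window = (0, traj.n_frames)
    return DistanceSeries(vals, tuple(summary_window))


def saltbridge_contact_fraction(
    traj: Trajectory,
    basic_residue: int,
    acidic_residue: int,
    cutoff: float = 4.0,
    basic_atom_names: Iterable[str] = BASIC_SIDECHAIN_N,
    acidic_atom_names: Iterable[str] = ACIDIC_SIDECHAIN_O,
) -> float:
    """Fraction of frames where the minimum side-chain N-O distance is < cutoff.

    The inequality is strict: a frame sitting exactly at the cutoff does not
    count as a contact.
    """
    top = traj.topology
    sel_n = AtomSelection(
        residue_ranges=((basic_residue, basic_residue),),
        atom_names=frozenset(basic_atom_names),
    )
    sel_o = AtomSelection(
        residue_ranges=((acidic_residue, acidic_residue),),
        atom_names=frozenset(acidic_atom_names),
    )
    try:
        ia = sel_n.resolve(top)
    except SelectionError:
        raise SelectionError(f"residue {basic_residue} has no side-chain N atoms")
    try:
        ib = sel_o.resolve(top)
    except SelectionError:
        raise SelectionError(f"residue {acidic_residue} has no side-chain O atoms")
    mins = np.array(
        [cdist(traj.frames[f, ia], traj.frames[f, ib]).min() for f in range(traj.n_frames)]
    )
    return float(np.mean(mins < cutoff))


def min_calpha_distance(
    structure: StructureModel,
    residue: int,
    residue_span: tuple[int, int],
) -> float:
    """Minimum CA-CA distance between one residue and an inclusive residue span."""
    ca = AtomSelection(atom_names=frozenset({"CA"}))
    sel_r = AtomSelection(
        residue_ranges=((residue, residue),), atom_names=frozenset({"CA"})
    )
    lo, hi = residue_span
    sel_span = AtomSelection(
        residue_ranges=((lo, hi),), atom_names=frozenset({"CA"})
    )
    ir = sel_r.resolve(structure)
    ispan = sel_span.resolve(structure)
    return float(cdist(structure.coords[ir], structure.coords[ispan]).min())


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _from_atom_array(arr) -> StructureModel:
    return StructureModel(
        atom_names=arr.atom_name,
        resids=arr.res_id,
        resnames=arr.res_name,
        chains=arr.chain_id,
        coords=arr.coord,
        elements=arr.element,
    )


def read_pdb(path) -> StructureModel | Trajectory:
    """Read a PDB file; multi-model files come back as a Trajectory."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    first = stack[0] if stack.stack_depth() > 1 else stack[0]
    model = _from_atom_array(first)
    if stack.stack_depth() == 1:
        return model
    return Trajectory(topology=model, frames=stack.coord)


def _to_atom_array(structure: StructureModel):
    import biotite.structure as struc

    arr = struc.AtomArray(structure.n_atoms)
    arr.atom_name = structure.atom_names
    arr.res_id = structure.resids
    arr.res_name = structure.resnames
    arr.chain_id = structure.chains
    arr.element = structure.elements
    arr.coord = structure.coords
    arr.hetero = np.zeros(structure.n_atoms, dtype=bool)
    return arr


def write_pdb(path, obj: StructureModel | Trajectory) -> None:
    """Write a structure (single model) or trajectory (multi-model) PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    if isinstance(obj, Trajectory):
        arr = _to_atom_array(obj.topology)
        stack = struc.stack([arr] * obj.n_frames)
        stack.coord = obj.frames
        pdb.set_structure(stack)
    else:
        pdb.set_structure(_to_atom_array(obj))
    pdb.write(str(path))
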