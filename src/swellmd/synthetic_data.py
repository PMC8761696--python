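"""Synthetic wells and coordinate trajectories with known ground truth.

Image wells mimic brightfield organoid cultures: round objects with a dark
rim and a bright lumen on a mid-gray background, growing linearly in area
over the time lapse, plus small dark debris and additive Gaussian noise.
Trajectories apply a per-frame rigid transform and per-residue isotropic
Gaussian displacements to a reference structure.

All randomness comes from ``numpy.random.default_rng`` (PCG64) with the seed
recorded in the spec, so identical specs produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .md_geometry import StructureModel, Trajectory
from .segmentation import ImageStack

__all__ = [
    "SyntheticWellSpec",
    "GroundTruth",
    "FluctuationSpec",
    "PlacementError",
    "generate_organoid_stack",
    "generate_reference_structure",
    "generate_trajectory",
    "write_stack_tiff",
    "write_ground_truth_csv",
]


class PlacementError(RuntimeError):
    """Could not place the requested organoids without overlap."""


@dataclass
class SyntheticWellSpec:
    """Parameters of one synthetic well time lapse.

    ``growth_rate`` is the fractional area increase per hour, applied
    linearly: area(t) = area(0) * (1 + growth_rate * t_hours). ``n_organoids``
    of ``None`` draws uniformly from 25-30.
    """

    image_shape: tuple[int, int] = (768, 768)
    n_frames: int = 7
    frame_interval: float = 10.0  # minutes
    n_organoids: int | None = None
    initial_radius: tuple[float, float] = (22.0, 28.0)
    growth_rate: float = 1.0  # fractional area increase per hour
    rim_width: float = 4.0
    rim_intensity: float = 0.15
    lumen_intensity: float = 0.9
    background_intensity: float = 0.6
    noise_sigma: float = 0.01
    edge_softness: float = 0.8  # px; defocus-like smoothing of drawn edges
    placement_margin: float = 8.0  # px clearance between final-frame rims
    n_debris: int = 8
    debris_radius: tuple[float, float] = (1.5, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("rim_intensity", "lumen_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.rim_intensity >= self.background_intensity:
            raise ValueError("rim must be darker than background")
        if self.rim_intensity >= self.lumen_intensity:
            raise ValueError("rim must be darker than lumen")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.initial_radius[0] > self.initial_radius[1]:
            raise ValueError("initial_radius range must be (low, high)")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=list, indent=2)


@dataclass
class GroundTruth:
    """What was actually drawn: masks, per-organoid areas and debris."""

    masks: np.ndarray  # (n_frames, H, W) bool, organoids only (no debris)
    per_organoid_area: np.ndarray  # (n_frames, n_organoids) px^2
    true_normalized_series: np.ndarray  # % of t=0 total area
    debris_mask: np.ndarray  # (H, W) bool, static
    centers: np.ndarray  # (n_organoids, 2) row/col
    radii_t0: np.ndarray  # (n_organoids,) px


@dataclass
class FluctuationSpec:
    """Programmed per-residue fluctuations and optional rigid-body drift."""

    n_frames: int
    per_residue_sigma: np.ndarray  # Angstrom, one entry per residue
    rigid_translation_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rigid_rotation_per_frame: float = 0.0  # degrees
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.per_residue_sigma = np.asarray(self.per_residue_sigma, dtype=float)
        if np.any(self.per_residue_sigma < 0):
            raise ValueError("sigmas must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


def _place_organoids(
    rng: np.random.Generator,
    spec: SyntheticWellSpec,
    n: int,
    max_attempts_per_organoid: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping centers; radii are final-frame radii."""
    h, w = spec.image_shape
    hours_total = spec.times[-1] / 60.0
    growth_factor = np.sqrt(1.0 + spec.growth_rate * hours_total)
    centers: list[np.ndarray] = []
    radii0: list[float] = []
    margin = spec.placement_margin
    attempts = 0
    budget = max_attempts_per_organoid * n
    while len(centers) < n:
        if attempts >= budget:
            raise PlacementError(
                f"placed only {len(centers)}/{n} organoids after {budget} attempts"
            )
        attempts += 1
        r0 = rng.uniform(*spec.initial_radius)
        rf = r0 * growth_factor
        edge = rf + spec.rim_width + margin
        if 2 * edge >= min(h, w):
            continue
        c = rng.uniform([edge, edge], [h - edge, w - edge])
        ok = True
        for cj, r0j in zip(centers, radii0):
            if np.linalg.norm(c - cj) < rf + r0j * growth_factor + margin:
                ok = False
                break
        if ok:
            centers.append(c)
            radii0.append(r0)
    return np.array(centers), np.array(radii0)


def _disk(dist: np.ndarray, radius: float) -> np.ndarray:
    return dist <= radius


def generate_organoid_stack(
    spec: SyntheticWellSpec,
) -> tuple[ImageStack, GroundTruth]:
    """Draw the well time lapse and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    n = spec.n_organoids if spec.n_organoids is not None else int(rng.integers(25, 31))
    centers, radii0 = _place_organoids(rng, spec, n)

    rows, cols = np.indices((h, w), dtype=float)
    # static debris: small dark dots scattered outside organoid footprints
    hours_total = spec.times[-1] / 60.0
    growth_factor = np.sqrt(1.0 + spec.growth_rate * hours_total)
    debris_mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_debris):
        for _attempt in range(200):
            rd = rng.uniform(*spec.debris_radius)
            cd = rng.uniform([rd, rd], [h - rd, w - rd])
            clear = all(
                np.linalg.norm(cd - c) > r0 * growth_factor + spec.rim_width + rd + 3
                for c, r0 in zip(centers, radii0)
            )
            if clear:
                dist = np.hypot(rows - cd[0], cols - cd[1])
                debris_mask |= _disk(dist, rd)
                break

    frames = np.empty((spec.n_frames, h, w), dtype=float)
    masks = np.zeros((spec.n_frames, h, w), dtype=bool)
    per_area = np.zeros((spec.n_frames, n), dtype=float)
    dists = np.stack([np.hypot(rows - c[0], cols - c[1]) for c in centers])

    for f, t in enumerate(spec.times):
        scale = np.sqrt(1.0 + spec.growth_rate * t / 60.0)
        img = np.full((h, w), spec.background_intensity, dtype=float)
        img[debris_mask] = spec.rim_intensity
        for i in range(n):
            r = radii0[i] * scale
            body = _disk(dists[i], r)
            lumen = _disk(dists[i], max(r - spec.rim_width, 0.0))
            img[body] = spec.rim_intensity
            img[lumen] = spec.lumen_intensity
            masks[f] |= body
            per_area[f, i] = float(body.sum())
        if spec.edge_softness > 0:
            from scipy.ndimage import gaussian_filter

            img = gaussian_filter(img, spec.edge_softness, mode="reflect")
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=(h, w))
            np.clip(img, 0.0, 1.0, out=img)
        frames[f] = img

    masks &= ~debris_mask[None, :, :]
    totals = masks.reshape(spec.n_frames, -1).sum(axis=1).astype(float)
    normalized = 100.0 * totals / totals[0]
    normalized[0] = 100.0
    truth = GroundTruth(
        masks=masks,
        per_organoid_area=per_area,
        true_normalized_series=normalized,
        debris_mask=debris_mask,
        centers=centers,
        radii_t0=radii0,
    )
    return ImageStack(frames=frames, timestamps=spec.times), truth


# ---------------------------------------------------------------------------
# structures and trajectories
# ---------------------------------------------------------------------------


def generate_reference_structure(
    n_residues: int,
    spacing: float = 3.8,
    first_resid: int = 1,
    with_sidechain_sites: bool = False,
    chain: str = "A",
    geometry: str = "helix",
) -> StructureModel:
    """Chain with one CA per residue at the given consecutive spacing.

    ``geometry="helix"`` (default) winds the chain so CAs are non-collinear
    and rigid fitting is well-posed; ``"line"`` places them on the x axis.
    Consecutive CA-CA distance equals ``spacing`` exactly in both. With
    ``with_sidechain_sites`` each residue also carries an NZ and an OE1 dummy
    atom offset from the CA, so salt-bridge selections resolve.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if geometry not in ("helix", "line"):
        raise ValueError("geometry must be 'helix' or 'line'")
    if geometry == "helix":
        # radius and per-residue twist loosely alpha-helical; rise chosen so
        # the consecutive chord length is exactly `spacing`
        radius, phi = 0.55 * spacing, np.deg2rad(100.0)
        chord_xy = 2.0 * radius * np.sin(phi / 2.0)
        if chord_xy >= spacing:
            radius = 0.9 * spacing / (2.0 * np.sin(phi / 2.0))
            chord_xy = 2.0 * radius * np.sin(phi / 2.0)
        rise = float(np.sqrt(spacing**2 - chord_xy**2))
    names, resids, resnames, chains, coords, elements = [], [], [], [], [], []
    for i in range(n_residues):
        resid = first_resid + i
        if geometry == "helix":
            ca = np.array(
                [radius * np.cos(i * phi), radius * np.sin(i * phi), i * rise]
            )
        else:
            ca = np.array([i * spacing, 0.0, 0.0])
        names.append("CA")
        resids.append(resid)
        resnames.append("UNK")
        chains.append(chain)
        coords.append(ca)
        elements.append("C")
        if with_sidechain_sites:
            names += ["NZ", "OE1"]
            resids += [resid, resid]
            resnames += ["UNK", "UNK"]
            chains += [chain, chain]
            coords += [ca + (0.0, 1.5, 0.8), ca + (0.0, -1.5, 0.8)]
            elements += ["N", "O"]
    return StructureModel(
        atom_names=np.array(names),
        resids=np.array(resids),
        resnames=np.array(resnames),
        chains=np.array(chains),
        coords=np.array(coords),
        elements=np.array(elements),
    )


def _rotation_matrix(axis: np.ndarray, degrees: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be non-zero")
    return Rotation.from_rotvec(np.deg2rad(degrees) * axis / norm).as_matrix()


def generate_trajectory(
    reference: StructureModel, spec: FluctuationSpec
) -> Trajectory:
    """Frames = rigid transform^f of the reference plus seeded Gaussian noise.

    Frame 0 carries transform^0 (identity); the rigid rotation is taken about
    the reference centroid. Noise is isotropic per coordinate with the
    per-residue sigma broadcast to every atom of that residue.
    """
    if reference.n_atoms == 0:
        raise ValueError("reference must be non-empty")
    residue_ids = reference.residue_ids
    if len(spec.per_residue_sigma) != len(residue_ids):
        raise ValueError(
            f"sigma vector length {len(spec.per_residue_sigma)} != residue count "
            f"{len(residue_ids)}"
        )
    sigma_of = dict(zip(residue_ids.tolist(), spec.per_residue_sigma))
    atom_sigma = np.array([sigma_of[r] for r in reference.resids])[:, None]

    rng = np.random.default_rng(spec.seed)
    centroid = reference.coords.mean(axis=0)
    rot_step = _rotation_matrix(spec.rotation_axis, spec.rigid_rotation_per_frame)
    trans_step = np.asarray(spec.rigid_translation_per_frame, dtype=float)

    has_rigid = spec.rigid_rotation_per_frame != 0.0 or np.any(trans_step != 0.0)
    frames = np.empty((spec.n_frames, reference.n_atoms, 3))
    coords = reference.coords.copy()
    for f in range(spec.n_frames):
        noise = rng.normal(0.0, 1.0, size=coords.shape) * atom_sigma
        frames[f] = coords + noise
        if has_rigid:
            coords = (coords - centroid) @ rot_step.T + centroid + trans_step
    return Trajectory(topology=reference, frames=frames)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_stack_tiff(path, stack: ImageStack) -> None:
    """Write a multi-frame 16-bit grayscale TIFF."""
    import tifffile

    data = np.clip(stack.frames, 0.0, 1.0)
    tifffile.imwrite(str(path), (data * 65535).astype(np.uint16))


def write_ground_truth_csv(path, truth: GroundTruth) -> None:
    """Tidy CSV: frame, organoid_id, area_px2."""
    import pandas as pd

    n_frames, n_org = truth.per_organoid_area.shape
    rows = [
        {"frame": f, "organoid_id": i, "area_px2": truth.per_organoid_area[f, i]}
        for f in range(n_frames)
        for i in range(n_org)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
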