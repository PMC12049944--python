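"""Desk-scale exhaustive rigid-body accessible-interaction-space scan.

A scanning structure is rotated through a fixed quasi-uniform rotation set
and translated over a regular lattice around a fixed structure.  A pose is
*accessible* when it neither clashes with the fixed structure (voxel-overlap
count ≤ a threshold) nor floats free of it (its nearest approach, measured
on a distance-transform grid, must be within the interaction shell).  For
every accessible pose the distance restraints are evaluated; aggregating the
per-restraint satisfaction fractions over the whole accessible space and
z-scoring them across restraints flags the restraints no plausible pose can
satisfy — the likely false positives.

All accessibility tests are grid-based (half-voxel quantization), which is
the standard trade made by exhaustive scanners; restraint distances are
exact Euclidean distances.  The scan is deterministic for a fixed rotation
set and lattice.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidGeometryError, RestraintError
from .rotations import RotationSet, rotation_set
from .structures import StructureView, load_structure

__all__ = [
    "ScanConfig",
    "ScanResult",
    "Restraint",
    "Pose",
    "Grid",
    "voxelize",
    "accessible_interaction_space",
    "flag_false_positives",
    "score_fixed_pose",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan resolution and accessibility thresholds."""

    voxel_spacing: float = 2.0
    rotation_set_size: int = 576
    translation_step: float = 2.0
    clash_overlap_max: int = 0
    interaction_shell: float = 6.0
    #: additional hard-sphere clearance (Å): a pose clashes when any scanning
    #: atom comes closer than this to the fixed occupancy (0 disables).
    collision_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.voxel_spacing <= 0 or self.translation_step <= 0:
            raise InvalidGeometryError("spacings must be positive")
        if self.rotation_set_size < 1:
            raise InvalidGeometryError("need at least one rotation")
        if self.interaction_shell <= 0:
            raise InvalidGeometryError("interaction_shell must be positive")
        if self.clash_overlap_max < 0:
            raise InvalidGeometryError("clash_overlap_max must be ≥ 0")
        if self.collision_radius < 0:
            raise InvalidGeometryError("collision_radius must be ≥ 0")


@dataclass(frozen=True)
class Restraint:
    """A maximum-distance restraint between the fixed and scanning structures."""

    fixed_protein: str
    fixed_residue: int
    scanning_protein: str
    scanning_residue: int
    max_span: float
    label: str = ""

    @property
    def name(self) -> str:
        return self.label or (
            f"{self.fixed_protein}:{self.fixed_residue}-"
            f"{self.scanning_protein}:{self.scanning_residue}"
        )


@dataclass(frozen=True)
class Pose:
    """Rigid placement: rotate about the scanning centroid, put centroid at
    ``translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray, centroid: np.ndarray) -> np.ndarray:
        return (coords - centroid) @ self.rotation.T + self.translation

    @staticmethod
    def identity(centroid: np.ndarray) -> "Pose":
        return Pose(rotation=np.eye(3), translation=np.asarray(centroid, dtype=float))


@dataclass
class Grid:
    """Boolean occupancy grid with world-coordinate bookkeeping."""

    origin: np.ndarray
    spacing: float
    occupied: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupied.shape

    def world_to_index(self, coords: np.ndarray) -> np.ndarray:
        return np.floor((np.asarray(coords, dtype=float) - self.origin) / self.spacing).astype(int)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Voxel centers; round-trips atom positions to within spacing/2 per axis."""
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.spacing

    def lookup(self, coords: np.ndarray, fill: float, values: np.ndarray) -> np.ndarray:
        """Gather ``values`` at the voxels of ``coords``; off-grid → ``fill``."""
        idx = self.world_to_index(coords)
        inb = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=-1)
        flat = np.where(inb[..., None], idx, 0)
        out = values[flat[..., 0], flat[..., 1], flat[..., 2]].astype(float)
        return np.where(inb, out, fill)


def voxelize(
    structure,
    spacing: float = 2.0,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    atom_rule: str = "CA",
) -> Grid:
    """Map atom/bead centers onto a boolean occupancy grid.

    ``bounds`` (lower, upper world coordinates) lets callers embed the
    structure in a larger grid; by default the grid snugly covers the atoms.
    """
    if spacing <= 0:
        raise InvalidGeometryError("spacing must be positive")
    coords = _as_coords(structure, atom_rule)
    if coords.size == 0:
        raise InvalidGeometryError("structure has no atoms")
    lo = coords.min(axis=0) if bounds is None else np.asarray(bounds[0], dtype=float)
    hi = coords.max(axis=0) if bounds is None else np.asarray(bounds[1], dtype=float)
    origin = lo - 0.5 * spacing
    shape = np.maximum(np.ceil((hi - origin) / spacing).astype(int) + 1, 1)
    occupied = np.zeros(tuple(shape), dtype=bool)
    idx = np.floor((coords - origin) / spacing).astype(int)
    keep = np.all((idx >= 0) & (idx < shape), axis=1)
    idx = idx[keep]
    occupied[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return Grid(origin=origin, spacing=spacing, occupied=occupied)


def _as_coords(structure, atom_rule: str = "CA") -> np.ndarray:
    if isinstance(structure, np.ndarray):
        return np.asarray(structure, dtype=float).reshape(-1, 3)
    return load_structure(structure).all_coords(atom_rule)


@dataclass
class ScanResult:
    """Aggregate statistics of one accessible-interaction-space scan."""

    accessible_pose_count: int
    total_pose_count: int
    complexes_consistent_with_n: dict[int, int]
    restraints: list[Restraint]
    satisfied_counts: np.ndarray
    rotation_max_gap: float
    config: ScanConfig

    @property
    def satisfaction_fraction(self) -> np.ndarray:
        if self.accessible_pose_count == 0:
            return np.zeros(len(self.restraints))
        return self.satisfied_counts / self.accessible_pose_count

    @property
    def z_scores(self) -> np.ndarray:
        frac = self.satisfaction_fraction
        if len(frac) == 0:
            return frac
        sd = frac.std()
        if sd == 0:
            return np.zeros_like(frac)
        return (frac - frac.mean()) / sd

    @property
    def degenerate_sd(self) -> bool:
        return len(self.restraints) > 0 and float(self.satisfaction_fraction.std()) == 0.0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "accessible_pose_count": self.accessible_pose_count,
            "total_pose_count": self.total_pose_count,
            "complexes_consistent_with_n": {
                str(k): v for k, v in sorted(self.complexes_consistent_with_n.items())
            },
            "restraints": [
                {
                    "name": r.name,
                    "max_span": r.max_span,
                    "satisfaction_fraction": float(f),
                    "z_score": float(z),
                }
                for r, f, z in zip(self.restraints, self.satisfaction_fraction, self.z_scores)
            ],
            "rotation_max_gap_rad": self.rotation_max_gap,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _resolve_restraints(
    restraints: Sequence[Restraint],
    fixed_view: StructureView,
    scan_view: StructureView,
    atom_rule: str,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Anchor coordinates; fixed anchors keep all copies (min rule applies)."""
    fixed_anchors = []
    scan_anchors = []
    for r in restraints:
        try:
            fixed_anchors.append(
                np.asarray(fixed_view.coords(r.fixed_protein, r.fixed_residue, atom_rule))
            )
            scan_anchors.append(
                scan_view.coords(r.scanning_protein, r.scanning_residue, atom_rule)[0]
            )
        except Exception as exc:
            raise RestraintError(f"restraint {r.name}: {exc}") from exc
    return fixed_anchors, np.asarray(scan_anchors).reshape(len(restraints), 3)


def default_translation_lattice(
    fixed_coords: np.ndarray,
    scan_coords: np.ndarray,
    config: ScanConfig,
) -> np.ndarray:
    """Centroid positions covering every placement that could touch the shell."""
    c_s = scan_coords.mean(axis=0)
    scan_radius = float(np.linalg.norm(scan_coords - c_s, axis=1).max())
    lo = fixed_coords.min(axis=0) - scan_radius - config.interaction_shell - config.translation_step
    hi = fixed_coords.max(axis=0) + scan_radius + config.interaction_shell + config.translation_step
    axes = [
        np.arange(lo[d], hi[d] + 0.5 * config.translation_step, config.translation_step)
        for d in range(3)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def accessible_interaction_space(
    fixed,
    scanning,
    restraints: Sequence[Restraint],
    config: ScanConfig = ScanConfig(),
    rotations: RotationSet | None = None,
    translations: np.ndarray | None = None,
    atom_rule: str = "CA",
) -> ScanResult:
    """Scan every (rotation, translation) pose and count restraint satisfaction.

    ``complexes_consistent_with_n[N]`` is the number of accessible poses that
    satisfy at least N restraints simultaneously (non-increasing in N by
    construction; N=0 equals the accessible pose count).
    """
    fixed_view = load_structure(fixed)
    scan_view = load_structure(scanning)
    F = fixed_view.all_coords(atom_rule)
    S = scan_view.all_coords(atom_rule)
    fixed_anchors, scan_anchors = _resolve_restraints(
        restraints, fixed_view, scan_view, atom_rule
    )
    c_s = S.mean(axis=0)
    if rotations is None:
        rotations = rotation_set(config.rotation_set_size)
    if translations is None:
        translations = default_translation_lattice(F, S, config)
    translations = np.asarray(translations, dtype=float).reshape(-1, 3)

    # Grid covers the full excursion of scanning atoms so off-grid means "far".
    scan_radius = float(np.linalg.norm(S - c_s, axis=1).max())
    pad = scan_radius + config.interaction_shell + config.translation_step + config.voxel_spacing
    lo = np.minimum(F.min(axis=0), translations.min(axis=0)) - pad
    hi = np.maximum(F.max(axis=0), translations.max(axis=0)) + pad
    grid = voxelize(F, config.voxel_spacing, bounds=(lo, hi))
    # distance (Å) from each voxel center to the nearest occupied voxel center
    dt = ndimage.distance_transform_edt(~grid.occupied, sampling=config.voxel_spacing)

    n_r = len(restraints)
    accessible_total = 0
    satisfied_counts = np.zeros(n_r, dtype=np.int64)
    nsat_hist = np.zeros(n_r + 1, dtype=np.int64)
    offs_all = S - c_s
    anchor_offs = scan_anchors - c_s if n_r else np.zeros((0, 3))

    occ_f = grid.occupied.astype(float)
    for R in rotations.matrices:
        offs = offs_all @ R.T  # (n_atoms, 3)
        pos = translations[:, None, :] + offs[None, :, :]  # (M, n_atoms, 3)
        overlap = grid.lookup(pos, fill=0.0, values=occ_f).sum(axis=1)
        sep = grid.lookup(pos, fill=np.inf, values=dt).min(axis=1)
        accessible = (
            (overlap <= config.clash_overlap_max)
            & (sep <= config.interaction_shell)
            & (sep >= config.collision_radius)
        )
        n_acc = int(accessible.sum())
        if n_acc == 0:
            continue
        accessible_total += n_acc
        t_acc = translations[accessible]
        if n_r:
            nsat = np.zeros(n_acc, dtype=np.int64)
            for r_i in range(n_r):
                y = t_acc + (anchor_offs[r_i] @ R.T)  # (n_acc, 3)
                d = np.linalg.norm(
                    y[:, None, :] - fixed_anchors[r_i][None, :, :], axis=-1
                ).min(axis=1)
                sat = d <= restraints[r_i].max_span
                satisfied_counts[r_i] += int(sat.sum())
                nsat += sat
            nsat_hist += np.bincount(nsat, minlength=n_r + 1)
        else:
            nsat_hist[0] += n_acc

    # cumulative: poses satisfying ≥ N restraints
    cum = np.cumsum(nsat_hist[::-1])[::-1]
    complexes = {n: int(cum[n]) for n in range(n_r + 1)}
    complexes[0] = accessible_total
    return ScanResult(
        accessible_pose_count=accessible_total,
        total_pose_count=len(translations) * len(rotations),
        complexes_consistent_with_n=complexes,
        restraints=list(restraints),
        satisfied_counts=satisfied_counts,
        rotation_max_gap=rotations.max_gap,
        config=config,
    )


@dataclass
class FlagReport:
    """Restraints whose satisfaction fraction is anomalously low."""

    flagged: list[Restraint]
    flagged_indices: list[int]
    fractions: np.ndarray
    z_scores: np.ndarray
    degenerate_sd: bool


def flag_false_positives(result: ScanResult, z_cutoff: float = 1.0) -> FlagReport:
    """Flag restraints with satisfaction z-score below −z_cutoff.

    The z-score compares each restraint's satisfaction fraction over the
    accessible space with the mean and (population) SD across restraints; a
    strongly sub-typical restraint is geometrically implausible given its
    peers — the likely false positive.  With all fractions identical the SD
    degenerates and nothing is flagged (reported as a warning flag).
    """
    if len(result.restraints) < 2:
        raise ValueError("need at least 2 restraints to define a z-score")
    frac = result.satisfaction_fraction
    z = result.z_scores
    if result.degenerate_sd:
        return FlagReport(
            flagged=[], flagged_indices=[], fractions=frac, z_scores=z, degenerate_sd=True
        )
    idx = [i for i in range(len(frac)) if z[i] < -z_cutoff]
    return FlagReport(
        flagged=[result.restraints[i] for i in idx],
        flagged_indices=idx,
        fractions=frac,
        z_scores=z,
        degenerate_sd=False,
    )


@dataclass
class PoseScore:
    n_satisfied: int
    total_violation: float
    distances: np.ndarray


def score_fixed_pose(
    fixed,
    scanning,
    pose: Pose,
    restraints: Sequence[Restraint],
    atom_rule: str = "CA",
) -> PoseScore:
    """Evaluate one candidate pose: satisfied count and summed violations.

    The summed positive violation (Å beyond each restraint's limit) is the
    "overall shortest cross-linker length" criterion used to rank candidate
    scanning structures or poses against each other.
    """
    fixed_view = load_structure(fixed)
    scan_view = load_structure(scanning)
    S = scan_view.all_coords(atom_rule)
    fixed_anchors, scan_anchors = _resolve_restraints(
        restraints, fixed_view, scan_view, atom_rule
    )
    c_s = S.mean(axis=0)
    placed = pose.apply(scan_anchors, c_s)
    distances = np.array(
        [
            float(np.linalg.norm(placed[i][None, :] - fixed_anchors[i], axis=-1).min())
            for i in range(len(restraints))
        ]
    )
    limits = np.array([r.max_span for r in restraints])
    violations = np.clip(distances - limits, 0.0, None)
    return PoseScore(
        n_satisfied=int((distances <= limits).sum()),
        total_violation=float(violations.sum()),
        distances=distances,
    )
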