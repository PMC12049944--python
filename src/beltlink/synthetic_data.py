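"""Synthetic fixtures with known ground truth for every pipeline stage.

Every generator is a pure function of its arguments and seed, and every
output is written in the same formats the pipeline reads, so fixtures
exercise the real readers.  Defaults encode the study conditions the
pipeline is meant to analyse: a 243-residue scaffold double belt of 300 Å
circumference, three replicate cross-link experiments filtered at 5 ppm,
and ligand-spacing distributions with a dominant ~81 Å mode (weight 0.85),
a minor ~150 Å mode, and a +26 Å major-mode shift for the
duplicated-helix-5 mutant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .belt_model import BeltModel, build_double_belt, default_site_azimuths
from .docking_scan import Pose, Restraint
from .errors import GenerationError
from .structures import StructureView, ToyStructure
from .xlink_io import ChemistrySpec, CrossLink

__all__ = [
    "SyntheticTruth",
    "SpacingTruth",
    "Scene",
    "make_toy_reference",
    "simulate_crosslinks",
    "simulate_spacing",
    "make_belt_lcat_scene",
    "SPACING_DEFAULTS",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Spacing-mixture truth per condition: (modes Å, weights, SDs Å).  The WT
#: modes/weights are the measured values the generator emulates; the mutant
#: minor mode (176 = 150 + 26) and all SDs (10 Å) are documented assumptions.
SPACING_DEFAULTS: dict[str, dict[str, tuple[float, ...]]] = {
    "WT": {"modes": (81.0, 150.0), "weights": (0.85, 0.15), "sds": (10.0, 10.0)},
    "D5h": {"modes": (107.0, 176.0), "weights": (0.85, 0.15), "sds": (10.0, 10.0)},
}


@dataclass
class SyntheticTruth:
    """Ground truth emitted beside simulated cross-link replicates."""

    true_links: list[CrossLink]
    fp_links: list[CrossLink]
    spans: dict[tuple, float]
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        true_keys = {self._key(x) for x in self.true_links}
        fp_keys = {self._key(x) for x in self.fp_links}
        if true_keys & fp_keys:
            raise GenerationError("true and false-positive link sets overlap")

    @staticmethod
    def _key(xl: CrossLink) -> tuple:
        return tuple(sorted(xl.ends))


def make_toy_reference(
    n_residues: int,
    fold: str = "helix",
    seed: int = 0,
    circumference: float | None = None,
    sequence: str | None = None,
    name: str = "REF",
) -> ToyStructure:
    """Deterministic coarse reference structure (one bead per residue).

    ``"helix"`` uses the ideal α-helical geometry (1.5 Å rise, 100° turn,
    2.3 Å Cα radius); ``"ring"`` places residues on a circle (default
    circumference ``3.8·n``); ``"random-walk"`` takes seeded 3.8 Å steps.
    The sequence is drawn uniformly from the 20 amino acids unless given.
    """
    if n_residues < 2:
        raise GenerationError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(_AA), size=n_residues))
    if len(sequence) != n_residues:
        raise GenerationError("sequence length must equal n_residues")
    i = np.arange(n_residues, dtype=float)
    if fold == "helix":
        rise, turn, radius = 1.5, math.radians(100.0), 2.3
        coords = np.column_stack(
            [radius * np.cos(i * turn), radius * np.sin(i * turn), i * rise]
        )
    elif fold == "ring":
        c = circumference if circumference is not None else 3.8 * n_residues
        r = c / (2.0 * math.pi)
        theta = 2.0 * math.pi * i / n_residues
        coords = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros(n_residues)])
    elif fold == "random-walk":
        steps = rng.normal(size=(n_residues - 1, 3))
        steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    else:
        raise GenerationError(f"unknown fold {fold!r}")
    return ToyStructure(
        name=name,
        sequence=sequence,
        coords=coords,
        metadata={"fold": fold, "seed": seed},
    )


@dataclass
class SimulatedCrosslinks:
    replicates: list[list[CrossLink]]
    truth: SyntheticTruth


def _reactive_positions(sequence: str, chem: ChemistrySpec) -> list[int]:
    pos = [i + 1 for i, aa in enumerate(sequence) if aa in chem.reactive_residues]
    if chem.allows_protein_nterm and 1 not in pos:
        pos.insert(0, 1)
    return pos


def _pair_reactive(sequence: str, chem: ChemistrySpec, i: int, j: int) -> bool:
    if chem.pairing is None:
        return True
    set_a, set_b = chem.pairing
    aa_i, aa_j = sequence[i - 1], sequence[j - 1]
    def a(aa: str, pos: int) -> bool:
        return aa in set_a
    def b(aa: str, pos: int) -> bool:
        return aa in set_b or (pos == 1 and chem.allows_protein_nterm)
    return (a(aa_i, i) and b(aa_j, j)) or (a(aa_j, j) and b(aa_i, i))


def simulate_crosslinks(
    structure: ToyStructure,
    chem: ChemistrySpec,
    n_true: int = 20,
    fp_rate: float = 0.1,
    span_noise_sd: float = 2.0,
    n_replicates: int = 3,
    dropout_rate: float = 0.0,
    ppm_noise_sd: float = 2.0,
    seed: int = 0,
    min_separation: int = 3,
) -> SimulatedCrosslinks:
    """Simulate replicate cross-link tables with planted truth.

    True links are drawn among chemically reactive residue pairs whose
    structural span (plus Gaussian measurement noise of ``span_noise_sd``)
    fits the reagent's maximum span; false positives among reactive pairs
    whose span exceeds the maximum by > 10 Å.  Each link drops out of each
    replicate independently at ``dropout_rate``; every observation gets a
    mass error drawn N(0, ``ppm_noise_sd``) truncated at ±8 ppm.
    """
    if chem.max_span is None:
        raise GenerationError(f"chemistry {chem.name} has no calibrated max_span")
    rng = np.random.default_rng(seed)
    seq = structure.sequence
    coords = structure.coords
    positions = _reactive_positions(seq, chem)
    candidates_true, candidates_fp = [], []
    for a_i, i in enumerate(positions):
        for j in positions[a_i + 1 :]:
            if j - i < min_separation or not _pair_reactive(seq, chem, i, j):
                continue
            span = float(np.linalg.norm(coords[i - 1] - coords[j - 1]))
            noisy = span + rng.normal(0.0, span_noise_sd)
            if noisy <= chem.max_span and span <= chem.max_span:
                candidates_true.append((i, j, span))
            elif span > chem.max_span + 10.0:
                candidates_fp.append((i, j, span))
    n_fp = int(round(fp_rate * n_true))
    if len(candidates_true) < n_true:
        raise GenerationError(
            f"only {len(candidates_true)} reactive in-range pairs, need {n_true}"
        )
    if len(candidates_fp) < n_fp:
        raise GenerationError(
            f"only {len(candidates_fp)} long-range reactive pairs, need {n_fp}"
        )
    pick_t = rng.choice(len(candidates_true), size=n_true, replace=False)
    pick_f = rng.choice(len(candidates_fp), size=n_fp, replace=False) if n_fp else []
    chosen = [(candidates_true[k], False) for k in pick_t] + [
        (candidates_fp[k], True) for k in pick_f
    ]

    def _mk(i: int, j: int, rep: str, ppm: float) -> CrossLink:
        return CrossLink(
            protein_1=structure.name,
            residue_1=i,
            protein_2=structure.name,
            residue_2=j,
            chemistry=chem.name,
            replicate=rep,
            score=float(rng.uniform(20.0, 100.0)),
            mass_error_ppm=ppm,
        )

    replicates: list[list[CrossLink]] = [[] for _ in range(n_replicates)]
    spans: dict[tuple, float] = {}
    true_links, fp_links = [], []
    for (i, j, span), is_fp in chosen:
        key = ((structure.name, i), (structure.name, j))
        spans[key] = span
        proto = _mk(i, j, "0", 0.0)
        (fp_links if is_fp else true_links).append(proto)
        for rep in range(n_replicates):
            if rng.uniform() < dropout_rate:
                continue
            ppm = float(np.clip(rng.normal(0.0, ppm_noise_sd), -8.0, 8.0)) if ppm_noise_sd > 0 else 0.0
            replicates[rep].append(_mk(i, j, str(rep + 1), ppm))
    truth = SyntheticTruth(
        true_links=true_links,
        fp_links=fp_links,
        spans=spans,
        seed=seed,
        params={
            "chemistry": chem.name,
            "max_span": chem.max_span,
            "n_true": n_true,
            "fp_rate": fp_rate,
            "span_noise_sd": span_noise_sd,
            "dropout_rate": dropout_rate,
            "ppm_noise_sd": ppm_noise_sd,
            "n_replicates": n_replicates,
        },
    )
    return SimulatedCrosslinks(replicates=replicates, truth=truth)


@dataclass
class SpacingTruth:
    modes: tuple[float, ...]
    weights: tuple[float, ...]
    sds: tuple[float, ...]
    condition: str
    seed: int

    @property
    def major_mode(self) -> float:
        return self.modes[int(np.argmax(self.weights))]

    @property
    def mean(self) -> float:
        return float(np.dot(self.modes, self.weights))


@dataclass
class SpacingSample:
    samples: np.ndarray
    truth: SpacingTruth


def simulate_spacing(
    condition: str | dict = "WT",
    n: int = 250,
    seed: int = 7,
) -> SpacingSample:
    """Draw ligand–ligand center distances from the condition's mixture truth.

    ``condition`` is ``"WT"``, ``"D5h"`` or a dict with ``modes``,
    ``weights`` and ``sds``.  The truth metadata rides along with the
    samples.
    """
    if n < 1:
        raise GenerationError("n must be ≥ 1")
    if isinstance(condition, str):
        try:
            spec = SPACING_DEFAULTS[condition]
        except KeyError:
            raise GenerationError(f"unknown condition {condition!r}") from None
        name = condition
    else:
        spec = condition
        name = str(condition.get("name", "custom"))
    modes = tuple(float(v) for v in spec["modes"])
    weights = tuple(float(v) for v in spec["weights"])
    sds = tuple(float(v) for v in spec["sds"])
    if not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
        raise GenerationError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(modes), size=n, p=weights)
    samples = rng.normal(np.asarray(modes)[comp], np.asarray(sds)[comp])
    return SpacingSample(
        samples=samples,
        truth=SpacingTruth(modes=modes, weights=weights, sds=sds, condition=name, seed=seed),
    )


@dataclass
class Scene:
    """A lipid-filled belt + placed ligand decoy with restraints and truth.

    ``fixed`` is the scan's fixed structure: the scaffold anchors (protein
    ``APOA1``, continuous numbering) plus a solid pseudo-lipid disc filling
    the particle body, so poses that would thread through the disc clash.
    """

    belt: BeltModel
    fixed: "StructureView"
    decoy: ToyStructure
    planted_pose: Pose
    restraints: list[Restraint]
    true_restraints: list[Restraint]
    fp_restraints: list[Restraint]
    site: str
    seed: int
    params: dict = field(default_factory=dict)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_belt_lcat_scene(
    belt: BeltModel | None = None,
    site: str = "A",
    n_true: int = 10,
    n_false: int = 2,
    restraint_span: float = 26.0,
    n_surface_beads: int = 36,
    semi_axes: tuple[float, float, float] = (25.0, 30.0, 30.0),
    seed: int = 0,
) -> Scene:
    """Place an ellipsoidal ligand decoy tangent to the belt at one site.

    The decoy (≈50×60×60 Å extents, ~40 beads) touches the belt circle at
    the chosen site's azimuth.  The fixed structure is the belt plus a solid
    pseudo-lipid lattice filling the disc body — the scanned particle is
    protein *and* lipid, so poses threading through the disc clash.  True
    restraints connect belt-facing surface beads to their nearest belt
    residues with ``restraint_span`` (the calibrated mean+1SD limit) — all
    satisfiable at the planted pose.  False positives anchor to the decoy's
    buried central bead, whose burial depth (the 25 Å semi-minor axis) plus
    hard-sphere contact clearance exceeds the span in every clash-free pose:
    the geometric signature of a spurious identification.
    """
    if site not in ("A", "B"):
        raise GenerationError("site must be 'A' or 'B'")
    if belt is None:
        belt = build_double_belt(243, 300.0)
    rng = np.random.default_rng(seed)
    a, b, c = semi_axes
    unit = _fibonacci_sphere(n_surface_beads)
    surface = unit * np.array([a, b, c])
    interior = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.4 * c], [0.0, 0.0, -0.4 * c]])
    local = np.vstack([surface, interior])

    az_a, az_b = default_site_azimuths(belt)
    az = az_a if site == "A" else az_b
    u = np.array([math.cos(az), math.sin(az), 0.0])  # radial direction at the site
    # rotate local +x onto the inward direction (decoy faces the belt)
    inward = -u
    x_axis = np.array([1.0, 0.0, 0.0])
    v = np.cross(x_axis, inward)
    s, co = np.linalg.norm(v), float(np.dot(x_axis, inward))
    if s < 1e-12:
        rot = np.eye(3) if co > 0 else np.diag([-1.0, -1.0, 1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - co) / s**2)
    center = (belt.radius + a + 1.0) * u
    world = local @ rot.T + center
    sequence = "".join(rng.choice(list(_AA), size=len(world)))
    decoy = ToyStructure(name="LCAT", sequence=sequence, coords=world,
                         metadata={"seed": seed, "site": site, "synthetic": True})
    pose = Pose.identity(world.mean(axis=0))

    anchors_all = np.vstack([belt.coords_a, belt.coords_b])
    n_mono = belt.n_residues_per_monomer

    def nearest_belt(continuous_excluded: set[int], xyz: np.ndarray) -> int:
        d = np.linalg.norm(anchors_all - xyz, axis=1)
        order = np.argsort(d)
        for k in order:
            ci = int(k) + 1
            if ci not in continuous_excluded:
                return ci
        raise GenerationError("no belt residue available")

    # true restraints: belt-facing surface beads, nearest belt anchors
    dist_to_belt = np.min(
        np.linalg.norm(world[:n_surface_beads, None, :] - anchors_all[None, :, :], axis=-1),
        axis=1,
    )
    facing = np.argsort(dist_to_belt)
    used: set[int] = set()
    true_restraints = []
    for bead in facing:
        if len(true_restraints) == n_true:
            break
        ci = nearest_belt(used, world[bead])
        d = float(np.linalg.norm(world[bead] - anchors_all[ci - 1]))
        if d > restraint_span - 4.0:
            continue
        used.add(ci)
        true_restraints.append(
            Restraint(
                fixed_protein="APOA1",
                fixed_residue=ci,
                scanning_protein="LCAT",
                scanning_residue=int(bead) + 1,
                max_span=restraint_span,
                label=f"true-{len(true_restraints)}",
            )
        )
    if len(true_restraints) < n_true:
        raise GenerationError("could not place the requested number of true restraints")

    # false positives: interior beads to belt residues at a far azimuth
    fp_restraints = []
    far_az = az + math.pi
    for k in range(n_false):
        bead = n_surface_beads  # the central, deeply buried bead
        res_float = (far_az / belt.delta_theta + rng.integers(-10, 11)) % n_mono
        ci = int(res_float) + 1
        while ci in used:
            ci = ci % (2 * n_mono) + 1
        used.add(ci)
        fp_restraints.append(
            Restraint(
                fixed_protein="APOA1",
                fixed_residue=ci,
                scanning_protein="LCAT",
                scanning_residue=bead + 1,
                max_span=restraint_span,
                label=f"fp-{k}",
            )
        )
    # solid pseudo-lipid disc filling the particle body
    disc_spacing = 4.0
    disc_r = belt.radius - 1.0
    half_z = belt.belt_separation / 2.0
    ax = np.arange(-disc_r, disc_r + disc_spacing / 2, disc_spacing)
    zax = np.arange(-half_z, half_z + disc_spacing / 2, disc_spacing)
    gx, gy, gz = np.meshgrid(ax, ax, zax, indexing="ij")
    disc = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    disc = disc[np.hypot(disc[:, 0], disc[:, 1]) <= disc_r]
    n_mono2 = belt.n_residues_per_monomer
    belt_copy = {i + 1: {"CA": belt.coords_a[i]} for i in range(n_mono2)}
    belt_copy.update({n_mono2 + i + 1: {"CA": belt.coords_b[i]} for i in range(n_mono2)})
    lipid_copy = {i + 1: {"CA": disc[i]} for i in range(len(disc))}
    fixed = StructureView({"APOA1": [belt_copy], "LIPID": [lipid_copy]})

    return Scene(
        belt=belt,
        fixed=fixed,
        decoy=decoy,
        planted_pose=pose,
        restraints=true_restraints + fp_restraints,
        true_restraints=true_restraints,
        fp_restraints=fp_restraints,
        site=site,
        seed=seed,
        params={
            "restraint_span": restraint_span,
            "semi_axes": semi_axes,
            "n_true": n_true,
            "n_false": n_false,
        },
    )
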