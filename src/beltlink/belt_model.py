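"""Idealized geometry of the APOA1 antiparallel double belt.

Discoidal HDL is modelled as two ring-shaped APOA1 monomers (chains A and B)
lying on parallel circles of equal radius and running in opposite azimuthal
directions.  Each residue gets a single anchor point on its circle, spaced by
a constant arc length (the *rise per residue* = circumference / monomer
length).  The two chains are phased so that *registry partners* — residue
``i`` on one chain and ``registry_constant − i`` on the other — share the same
azimuth.  With the default constant of 263 the helix-5 span (121–142) maps
onto itself end-to-end (the LL5/5 registry), which places the helix 4/6
interface on one side of the helix 5/5 pair and the 6/4 interface on the
other; those two interfaces are the LCAT binding sites A and B.

The model supports duplication of a helix segment in each monomer (the D5h
construct doubles helix 5, 243 → 265 residues), which lengthens the belt and
moves the two sites further apart; :func:`predict_spacing` turns site
azimuths into chord/arc separations so geometric predictions can be compared
with measured ligand–ligand spacings.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import InvalidGeometryError
from .structures import StructureView, write_pseudo_pdb

__all__ = [
    "HelixSegment",
    "BeltModel",
    "ParticleGeometry",
    "SpacingPrediction",
    "InsertionResult",
    "load_helices",
    "HELICES",
    "build_double_belt",
    "insert_segment_repeat",
    "predict_spacing",
    "circumference_from_diameter",
    "diameter_from_circumference",
    "default_site_azimuths",
    "RISE_IDEAL",
]

#: Ideal alpha-helical rise per residue (Å); the *effective* rise along a real
#: belt (circumference / monomer length from measured diameters) is smaller,
#: roughly 1.1–1.25 Å.
RISE_IDEAL = 1.5


@dataclass(frozen=True)
class HelixSegment:
    """One amphipathic helical repeat, inclusive 1-based residue bounds."""

    id: str
    start_residue: int
    end_residue: int

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise InvalidGeometryError(
                f"{self.id}: start {self.start_residue} > end {self.end_residue}"
            )

    def __len__(self) -> int:
        return self.end_residue - self.start_residue + 1

    def __contains__(self, residue: float) -> bool:
        return self.start_residue <= residue <= self.end_residue

    @property
    def midpoint(self) -> float:
        return (self.start_residue + self.end_residue) / 2.0


def load_helices(path: str | Path | None = None) -> tuple[HelixSegment, ...]:
    """Load the helix segmentation table (packaged default or user TSV)."""
    if path is None:
        text = resources.files("beltlink.data").joinpath("helices.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    segments = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        segments.append(
            HelixSegment(
                id=parts[idx["id"]],
                start_residue=int(parts[idx["start"]]),
                end_residue=int(parts[idx["end"]]),
            )
        )
    segments.sort(key=lambda s: s.start_residue)
    for a, b in zip(segments, segments[1:]):
        if b.start_residue <= a.end_residue:
            raise InvalidGeometryError(f"segments {a.id} and {b.id} overlap")
    return tuple(segments)


HELICES: tuple[HelixSegment, ...] = load_helices()


def helix(id: str, helices: tuple[HelixSegment, ...] = HELICES) -> HelixSegment:
    for seg in helices:
        if seg.id == id:
            return seg
    raise KeyError(id)


@dataclass(frozen=True)
class ParticleGeometry:
    """Measured disc dimensions and lipid stoichiometry."""

    diameter: float
    circumference: float
    phospholipid_per_apoa1: float = 80.0

    def check(self, rel_tol: float) -> bool:
        """Is circumference = π·diameter within the caller's tolerance?"""
        return math.isclose(self.circumference, math.pi * self.diameter, rel_tol=rel_tol)


@dataclass(frozen=True)
class BeltModel:
    """Anchor coordinates and registry bookkeeping for one double belt."""

    n_residues_per_monomer: int
    circumference: float
    belt_separation: float
    registry_constant: int
    coords_a: np.ndarray
    coords_b: np.ndarray

    @property
    def rise_per_residue(self) -> float:
        return self.circumference / self.n_residues_per_monomer

    @property
    def radius(self) -> float:
        return self.circumference / (2.0 * math.pi)

    @property
    def delta_theta(self) -> float:
        """Azimuthal step between consecutive residues (radians)."""
        return 2.0 * math.pi / self.n_residues_per_monomer

    # ---- residue bookkeeping -------------------------------------------------

    def continuous_index(self, chain: str, residue: int) -> int:
        """Map (chain, residue) to the joined 1..2N numbering.

        Chain A keeps its numbering; chain B is appended after it, so chain B
        residue 1 becomes N+1 — the convention that treats the two monomers as
        one continuous chain for restraint bookkeeping.
        """
        n = self.n_residues_per_monomer
        if not 1 <= residue <= n:
            raise IndexError(f"residue {residue} outside 1..{n}")
        if chain == "A":
            return residue
        if chain == "B":
            return residue + n
        raise IndexError(f"chain must be 'A' or 'B', got {chain!r}")

    def from_continuous(self, index: int) -> tuple[str, int]:
        """Inverse of :meth:`continuous_index`."""
        n = self.n_residues_per_monomer
        if not 1 <= index <= 2 * n:
            raise IndexError(f"continuous index {index} outside 1..{2 * n}")
        return ("A", index) if index <= n else ("B", index - n)

    def registry_partner(self, residue: int) -> int | None:
        """Opposite-chain residue sharing this residue's azimuth.

        Returns ``None`` (no partner — belt ends) when the arithmetic falls
        outside the monomer.
        """
        n = self.n_residues_per_monomer
        if not 1 <= residue <= n:
            raise IndexError(f"residue {residue} outside 1..{n}")
        partner = self.registry_constant - residue
        return partner if 1 <= partner <= n else None

    # ---- geometry ------------------------------------------------------------

    def azimuth(self, chain: str, residue: float) -> float:
        """Anchor azimuth in radians (fractional residues allowed)."""
        dt = self.delta_theta
        if chain == "A":
            return (residue * dt) % (2.0 * math.pi)
        if chain == "B":
            return ((self.registry_constant - residue) * dt) % (2.0 * math.pi)
        raise IndexError(f"chain must be 'A' or 'B', got {chain!r}")

    def anchor(self, chain: str, residue: int) -> np.ndarray:
        if chain == "A":
            return self.coords_a[residue - 1]
        if chain == "B":
            return self.coords_b[residue - 1]
        raise IndexError(f"chain must be 'A' or 'B', got {chain!r}")

    def anchor_continuous(self, index: int) -> np.ndarray:
        chain, residue = self.from_continuous(index)
        return self.anchor(chain, residue)

    # ---- interchange with the rest of the pipeline ---------------------------

    def to_view(self, protein: str = "APOA1", continuous: bool = False) -> StructureView:
        """Expose anchors as a structure view.

        With ``continuous=False`` the two chains are two *copies* of one
        protein (residue i has two candidate positions); with
        ``continuous=True`` the belt is a single 1..2N chain.
        """
        n = self.n_residues_per_monomer
        if continuous:
            copy = {i + 1: {"CA": self.coords_a[i]} for i in range(n)}
            copy.update({n + i + 1: {"CA": self.coords_b[i]} for i in range(n)})
            return StructureView({protein: [copy]})
        copy_a = {i + 1: {"CA": self.coords_a[i]} for i in range(n)}
        copy_b = {i + 1: {"CA": self.coords_b[i]} for i in range(n)}
        return StructureView({protein: [copy_a, copy_b]})

    def to_pdb(self, path: str | Path, sequence: str | None = None) -> None:
        """Export one CA pseudo-atom per residue, chains A and B."""
        n = self.n_residues_per_monomer
        seq = sequence if sequence is not None else "G" * n
        write_pseudo_pdb(path, [("A", seq, self.coords_a), ("B", seq, self.coords_b)])


def build_double_belt(
    n_residues: int,
    circumference: float,
    belt_separation: float = 15.0,
    registry_constant: int = 263,
) -> BeltModel:
    """Construct the antiparallel double belt.

    Chain A residue ``i`` sits at azimuth ``i·Δθ`` on the upper circle; chain
    B runs the other way, phased so that residue ``registry_constant − i``
    faces residue ``i`` (identical azimuth).  ``belt_separation`` is the axial
    gap between the two rings.
    """
    if n_residues < 1:
        raise InvalidGeometryError("n_residues must be ≥ 1")
    if circumference <= 0:
        raise InvalidGeometryError("circumference must be positive")
    radius = circumference / (2.0 * math.pi)
    dt = 2.0 * math.pi / n_residues
    idx = np.arange(1, n_residues + 1)
    theta_a = idx * dt
    theta_b = (registry_constant - idx) * dt
    za = +belt_separation / 2.0
    zb = -belt_separation / 2.0
    coords_a = np.column_stack(
        [radius * np.cos(theta_a), radius * np.sin(theta_a), np.full(n_residues, za)]
    )
    coords_b = np.column_stack(
        [radius * np.cos(theta_b), radius * np.sin(theta_b), np.full(n_residues, zb)]
    )
    return BeltModel(
        n_residues_per_monomer=n_residues,
        circumference=circumference,
        belt_separation=belt_separation,
        registry_constant=registry_constant,
        coords_a=coords_a,
        coords_b=coords_b,
    )


@dataclass(frozen=True)
class InsertionResult:
    """A mutant belt plus the old→new residue renumbering map."""

    belt: BeltModel
    old_to_new: dict[int, int]


def insert_segment_repeat(belt: BeltModel, segment: HelixSegment) -> InsertionResult:
    """Duplicate a helix segment in each monomer (tandem repeat).

    The duplicate is inserted immediately after the segment, so downstream
    residues shift by the segment length.  The rise per residue is preserved:
    the circumference grows by ``len(segment) × rise``.  The registry constant
    shifts by the same length, which keeps the duplicated block registered
    onto itself and leaves the helix 4/6 interfaces intact in the new
    numbering.
    """
    n = belt.n_residues_per_monomer
    if not (1 <= segment.start_residue and segment.end_residue <= n):
        raise InvalidGeometryError(
            f"segment {segment.id} ({segment.start_residue}-{segment.end_residue}) "
            f"outside monomer 1..{n}"
        )
    length = len(segment)
    new_belt = build_double_belt(
        n_residues=n + length,
        circumference=belt.circumference + length * belt.rise_per_residue,
        belt_separation=belt.belt_separation,
        registry_constant=belt.registry_constant + length,
    )
    old_to_new = {
        old: (old if old <= segment.end_residue else old + length)
        for old in range(1, n + 1)
    }
    return InsertionResult(belt=new_belt, old_to_new=old_to_new)


@dataclass(frozen=True)
class SpacingPrediction:
    """Chord and arc separation of two site centers at an offset radius."""

    chord: float
    arc: float
    azimuth_a: float
    azimuth_b: float
    radius: float


def _circular_midpoint(t1: float, t2: float) -> float:
    """Midpoint of two azimuths along the shorter arc between them."""
    d = (t2 - t1 + math.pi) % (2.0 * math.pi) - math.pi
    return (t1 + d / 2.0) % (2.0 * math.pi)


def site_azimuth(belt: BeltModel, residue_pair: tuple[float, float]) -> float:
    """Azimuth of an interface center given its (chain A, chain B) residues.

    For registry-paired residues the two azimuths coincide; otherwise the
    circular midpoint is used.
    """
    ra, rb = residue_pair
    return _circular_midpoint(belt.azimuth("A", ra), belt.azimuth("B", rb))


def default_site_azimuths(
    belt: BeltModel,
    helices: tuple[HelixSegment, ...] = HELICES,
    renumber: dict[int, int] | None = None,
) -> tuple[float, float]:
    """Azimuths of Site A (chain-A H4 / chain-B H6) and Site B (mirror).

    Each site center is the midpoint between the registry-paired helix 4 and
    helix 6 midpoints.  ``renumber`` (an old→new map from
    :func:`insert_segment_repeat`) translates the helix table onto a mutant
    belt.
    """
    h4, h6 = helix("H4", helices), helix("H6", helices)

    def _mid(seg: HelixSegment) -> float:
        if renumber is None:
            return seg.midpoint
        return (renumber[seg.start_residue] + renumber[seg.end_residue]) / 2.0

    site_a = site_azimuth(belt, (_mid(h4), _mid(h6)))
    site_b = site_azimuth(belt, (_mid(h6), _mid(h4)))
    return site_a, site_b


def predict_spacing(
    belt: BeltModel,
    site_a_center: tuple[float, float],
    site_b_center: tuple[float, float],
    radial_offset: float = 15.0,
) -> SpacingPrediction:
    """Chord and arc distance between two site centers.

    Both sites are projected onto a circle of radius ``belt radius +
    radial_offset`` (the bound ligand's effective center sits outward from
    the protein ring); the chord is the straight-line separation a projection
    image would measure, the arc is the along-belt separation at the same
    radius.  Chord ≤ arc always, with equality only in the small-angle limit.
    """
    if radial_offset < 0:
        raise InvalidGeometryError("radial_offset must be ≥ 0")
    ta = site_azimuth(belt, site_a_center)
    tb = site_azimuth(belt, site_b_center)
    dtheta = abs((tb - ta + math.pi) % (2.0 * math.pi) - math.pi)
    r = belt.radius + radial_offset
    chord = 2.0 * r * math.sin(dtheta / 2.0)
    arc = r * dtheta
    return SpacingPrediction(chord=chord, arc=arc, azimuth_a=ta, azimuth_b=tb, radius=r)


def circumference_from_diameter(diameter: float) -> float:
    if diameter <= 0:
        raise InvalidGeometryError("diameter must be positive")
    return math.pi * diameter


def diameter_from_circumference(circumference: float) -> float:
    if circumference <= 0:
        raise InvalidGeometryError("circumference must be positive")
    return circumference / math.pi
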