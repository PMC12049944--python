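"""Mapping filtered cross-links onto the double belt.

Three jobs: (1) resolve whether a scaffold-scaffold link is intra-chain or
inter-chain — on an antiparallel double belt the same residue pair can be
read either way, and the shorter reading is taken unless the two are too
close to call; (2) assign scaffold↔ligand links to binding Site A or Site B
by arc proximity to the helix 4/6 and 6/4 interface centers; (3) compare
mapped links against a reference contact plot and cluster the discordant
ones into contiguous regions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .belt_model import BeltModel, HELICES, HelixSegment, default_site_azimuths, helix
from .calibration import ContactPlot
from .errors import CoordinateError
from .xlink_io import CrossLink

__all__ = [
    "MappedLink",
    "SiteAssignment",
    "ConcordanceReport",
    "resolve_ambiguity",
    "assign_site",
    "belt_concordance_report",
    "write_restraint_file",
    "read_restraint_file",
]


@dataclass(frozen=True)
class MappedLink:
    """A cross-link placed on the belt with both chain readings recorded."""

    link: CrossLink
    span: float
    assignment: str  # "intra" | "inter" | "ambiguous"
    intra_span: float | None
    inter_span: float | None
    continuous: tuple[int, int]
    continuous_alt: tuple[int, int] | None = None
    site: str | None = None
    within_constraint: bool | None = None


def resolve_ambiguity(
    xl: CrossLink,
    belt: BeltModel,
    ambiguity_margin: float = 5.0,
) -> MappedLink:
    """Choose the intra- or inter-chain reading of a scaffold-scaffold link.

    Residue numbers ≤ N are chain-ambiguous: the intra reading puts both ends
    on one chain, the inter reading puts them on opposite chains (the belt's
    mirror symmetry makes the two inter assignments equivalent).  The shorter
    span wins; when the two differ by less than ``ambiguity_margin`` the link
    is flagged ambiguous (span still = the minimum).  Residues already given
    in continuous 1..2N numbering (> N) fix the reading outright.
    """
    n = belt.n_residues_per_monomer
    r1, r2 = xl.residue_1, xl.residue_2
    if r1 > 2 * n or r2 > 2 * n:
        raise CoordinateError(f"residue beyond continuous range 1..{2 * n}")
    if r1 > n or r2 > n:
        # Continuous numbering: the reading is fixed.
        c1, c2 = belt.from_continuous(r1), belt.from_continuous(r2)
        span = float(np.linalg.norm(belt.anchor(*c1) - belt.anchor(*c2)))
        assignment = "intra" if c1[0] == c2[0] else "inter"
        return MappedLink(
            link=xl,
            span=span,
            assignment=assignment,
            intra_span=span if assignment == "intra" else None,
            inter_span=span if assignment == "inter" else None,
            continuous=(r1, r2),
        )
    intra = float(np.linalg.norm(belt.anchor("A", r1) - belt.anchor("A", r2)))
    inter = float(np.linalg.norm(belt.anchor("A", r1) - belt.anchor("B", r2)))
    intra_idx = (belt.continuous_index("A", r1), belt.continuous_index("A", r2))
    inter_idx = (belt.continuous_index("A", r1), belt.continuous_index("B", r2))
    if abs(intra - inter) < ambiguity_margin:
        assignment = "ambiguous"
    else:
        assignment = "intra" if intra < inter else "inter"
    chosen, alt = (
        (intra_idx, inter_idx) if intra <= inter else (inter_idx, intra_idx)
    )
    return MappedLink(
        link=xl,
        span=min(intra, inter),
        assignment=assignment,
        intra_span=intra,
        inter_span=inter,
        continuous=chosen,
        continuous_alt=alt,
    )


@dataclass(frozen=True)
class SiteAssignment:
    site: str | None  # "A" | "B" | None
    tie: bool
    arc_to_a: float
    arc_to_b: float


def _arc_distance(t1: float, t2: float, radius: float) -> float:
    d = abs((t2 - t1 + math.pi) % (2.0 * math.pi) - math.pi)
    return d * radius


def assign_site(
    xl: CrossLink,
    belt: BeltModel,
    helices: tuple[HelixSegment, ...] = HELICES,
    scaffold_protein: str = "APOA1",
    chain: str = "A",
    arc_margin: float = 25.0,
    tie_tol: float = 1e-6,
) -> SiteAssignment:
    """Assign a scaffold↔ligand link to binding Site A or B.

    The site anchors are the azimuths of the helix 4/6 (Site A) and 6/4
    (Site B) interface centers; the link goes to whichever anchor is nearer
    in arc distance to its scaffold residue's azimuth.  Residues falling
    outside the central helix span (helix 3 through 7) by more than
    ``arc_margin`` Å of arc get no site; exact ties are reported, not forced.
    Only the scaffold-side azimuth is used, so no docked ligand pose is
    required.
    """
    scaffold_ends = [(p, r) for (p, r) in xl.ends if p == scaffold_protein]
    if not scaffold_ends:
        raise ValueError(f"link has no {scaffold_protein} end")
    residue = scaffold_ends[0][1]
    az_a, az_b = default_site_azimuths(belt, helices)
    theta = belt.azimuth(chain, residue)
    d_a = _arc_distance(theta, az_a, belt.radius)
    d_b = _arc_distance(theta, az_b, belt.radius)
    lo = helix("H3", helices).start_residue
    hi = helix("H7", helices).end_residue
    margin_res = arc_margin / belt.rise_per_residue
    if residue < lo - margin_res or residue > hi + margin_res:
        return SiteAssignment(site=None, tie=False, arc_to_a=d_a, arc_to_b=d_b)
    if abs(d_a - d_b) <= tie_tol:
        return SiteAssignment(site=None, tie=True, arc_to_a=d_a, arc_to_b=d_b)
    return SiteAssignment(site="A" if d_a < d_b else "B", tie=False, arc_to_a=d_a, arc_to_b=d_b)


@dataclass
class ConcordanceReport:
    """Contact-plot agreement of mapped links, with discordant regions ranked."""

    per_link: list[tuple[MappedLink, bool]]
    regions: list[tuple[int, int, int]]  # (window start, window end, discordant count)
    n_concordant: int
    n_discordant: int


def belt_concordance_report(
    mapped_links: Sequence[MappedLink],
    contacts: ContactPlot,
    window: int = 10,
    protein: str = "APOA1",
) -> ConcordanceReport:
    """Check each mapped link against a contact plot over continuous indices.

    A link is concordant when its chosen reading's residue pair is in contact
    in the reference plot.  Discordant link endpoints are histogrammed into
    contiguous continuous-index windows of ``window`` residues; windows are
    ranked by count (ties broken by window start, so the ranking is
    deterministic and independent of input order).
    """
    per_link: list[tuple[MappedLink, bool]] = []
    counts: dict[int, int] = {}
    for ml in sorted(mapped_links, key=lambda m: (m.continuous, m.link.chemistry)):
        ci1, ci2 = ml.continuous
        ok = contacts.in_contact(protein, ci1, protein, ci2)
        per_link.append((ml, ok))
        if not ok:
            for ci in (ci1, ci2):
                counts[(ci - 1) // window] = counts.get((ci - 1) // window, 0) + 1
    regions = [
        (w * window + 1, (w + 1) * window, c)
        for w, c in sorted(counts.items(), key=lambda t: (-t[1], t[0]))
    ]
    n_disc = sum(1 for _, ok in per_link if not ok)
    return ConcordanceReport(
        per_link=per_link,
        regions=regions,
        n_concordant=len(per_link) - n_disc,
        n_discordant=n_disc,
    )


def write_restraint_file(
    restraints: Iterable[tuple[str, int, str, int, float]],
    path: str | Path,
) -> None:
    """Plain-text restraint list: fixed_protein fixed_res scan_protein scan_res max_Å."""
    lines = ["# fixed_protein\tfixed_res\tscanning_protein\tscanning_res\tmax_span_A"]
    for fp, fr, sp, sr, span in restraints:
        lines.append(f"{fp}\t{fr}\t{sp}\t{sr}\t{span:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_restraint_file(path: str | Path) -> list[tuple[str, int, str, int, float]]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fp, fr, sp, sr, span = line.split("\t")
        out.append((fp, int(fr), sp, int(sr), float(span)))
    return out
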