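"""Per-reagent distance calibration against a reference structure.

Each cross-linking reagent bridges a characteristic range of residue-residue
distances.  Measuring the spans of high-confidence links on a protein of
known structure (a serum-albumin-style reference) gives an empirical span
distribution per reagent; the *mean span + 1 SD* is then used as that
reagent's maximum-distance restraint for pose screening.  A Cα contact plot
(< 24 Å) provides the concordance baseline.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import CoordinateError
from .structures import load_structure
from .xlink_io import CrossLink

__all__ = [
    "SpanStats",
    "DistanceResult",
    "ContactPlot",
    "CalibrationResult",
    "ConcordanceResult",
    "residue_distance",
    "calibrate",
    "contact_plot",
    "concordance",
]


@dataclass(frozen=True)
class SpanStats:
    """Empirical span statistics for one chemistry on the reference."""

    chemistry: str
    n_links: int
    mean_span: float
    sd_span: float
    atom_rule: str = "CA"

    def __post_init__(self) -> None:
        if self.n_links < 1:
            raise ValueError("n_links must be ≥ 1")
        if self.sd_span < 0:
            raise ValueError("sd_span must be ≥ 0")

    @property
    def constraint(self) -> float:
        """The downstream maximum-span restraint: mean + 1 SD."""
        return self.mean_span + self.sd_span


def span_stats_to_json(stats: Mapping[str, SpanStats], path: str | Path | None = None) -> str:
    payload = {
        name: {
            "chemistry": s.chemistry,
            "n_links": s.n_links,
            "mean_span": s.mean_span,
            "sd_span": s.sd_span,
            "constraint": s.constraint,
            "atom_rule": s.atom_rule,
        }
        for name, s in stats.items()
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def span_stats_from_json(source: str | Path) -> dict[str, SpanStats]:
    try:
        is_file = Path(str(source)).exists()
    except OSError:
        is_file = False
    text = Path(source).read_text() if is_file else str(source)
    payload = json.loads(text)
    return {
        name: SpanStats(
            chemistry=d["chemistry"],
            n_links=d["n_links"],
            mean_span=d["mean_span"],
            sd_span=d["sd_span"],
            atom_rule=d.get("atom_rule", "CA"),
        )
        for name, d in payload.items()
    }


@dataclass(frozen=True)
class DistanceResult:
    """Minimum residue-residue distance with the per-assignment breakdown.

    For multi-copy structures (e.g. a homodimer) every chain-assignment
    combination is measured and the minimum is reported — a cross-link cannot
    distinguish the copies, so the shortest consistent interpretation is
    used.
    """

    distance: float
    by_assignment: tuple[tuple[tuple[int, int], float], ...]

    def __float__(self) -> float:
        return self.distance


def residue_distance(
    structure,
    protein_1: str,
    res_1: int,
    protein_2: str,
    res_2: int,
    atom_rule: str = "CA",
) -> DistanceResult:
    """Euclidean distance between two residues' reference atoms.

    ``atom_rule`` selects Cα (default) or Cβ (glycine and coarse models fall
    back to Cα).  Missing residues raise :class:`CoordinateError` naming the
    residue.
    """
    view = load_structure(structure)
    coords_1 = view.coords(protein_1, res_1, atom_rule)
    coords_2 = view.coords(protein_2, res_2, atom_rule)
    pairs = []
    for i, a in enumerate(coords_1):
        for j, b in enumerate(coords_2):
            if protein_1 == protein_2 and res_1 == res_2 and i == j:
                continue  # same physical atom
            pairs.append(((i, j), float(np.linalg.norm(a - b))))
    if not pairs:
        # identical residue, single copy: distance to itself
        pairs = [((0, 0), 0.0)]
    pairs.sort(key=lambda t: (t[1], t[0]))
    return DistanceResult(distance=pairs[0][1], by_assignment=tuple(pairs))


@dataclass
class CalibrationResult:
    """Span statistics per chemistry plus the links that could not be mapped."""

    stats: dict[str, SpanStats]
    spans: dict[str, list[float]]
    unmappable: list[tuple[CrossLink, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def calibrate(
    xls: Iterable[CrossLink],
    structure,
    atom_rule: str = "CA",
    sd_mode: str = "population",
) -> CalibrationResult:
    """Measure link spans on a reference structure, per chemistry.

    Returns mean, SD (population SD by default; ``sd_mode="sample"`` for the
    n−1 flavour) and the mean+1SD constraint.  Links whose residues are
    absent from the structure are listed as unmappable, never counted.
    Chemistries with zero mappable links are omitted with a warning record.
    """
    if sd_mode not in ("population", "sample"):
        raise ValueError("sd_mode must be 'population' or 'sample'")
    view = load_structure(structure)
    spans: dict[str, list[float]] = {}
    result = CalibrationResult(stats={}, spans=spans)
    seen_chems: set[str] = set()
    for xl in xls:
        seen_chems.add(xl.chemistry)
        try:
            d = residue_distance(
                view, xl.protein_1, xl.residue_1, xl.protein_2, xl.residue_2, atom_rule
            )
        except CoordinateError as exc:
            result.unmappable.append((xl, str(exc)))
            continue
        spans.setdefault(xl.chemistry, []).append(d.distance)
    for chem in sorted(seen_chems):
        values = spans.get(chem, [])
        if not values:
            result.warnings.append(f"chemistry {chem}: no mappable links, omitted")
            continue
        arr = np.asarray(values, dtype=float)
        ddof = 0 if sd_mode == "population" else 1
        sd = float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0
        result.stats[chem] = SpanStats(
            chemistry=chem,
            n_links=len(arr),
            mean_span=float(arr.mean()),
            sd_span=sd,
            atom_rule=atom_rule,
        )
    return result


@dataclass
class ContactPlot:
    """Symmetric boolean proximity matrix over a structure's residues."""

    matrix: np.ndarray
    index: list[tuple[str, int]]
    threshold: float
    atom_rule: str

    def __post_init__(self) -> None:
        self._lookup = {key: i for i, key in enumerate(self.index)}

    def in_contact(self, protein_1: str, res_1: int, protein_2: str, res_2: int) -> bool:
        try:
            i = self._lookup[(protein_1, res_1)]
            j = self._lookup[(protein_2, res_2)]
        except KeyError as exc:
            raise CoordinateError(f"residue {exc.args[0]} not in contact plot") from None
        return bool(self.matrix[i, j])

    def to_tsv(self, path: str | Path) -> None:
        labels = [f"{p}:{r}" for p, r in self.index]
        lines = ["\t" + "\t".join(labels)]
        for label, row in zip(labels, self.matrix):
            lines.append(label + "\t" + "\t".join("1" if v else "0" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def contact_plot(
    structure,
    threshold: float = 24.0,
    atom_rule: str = "CA",
) -> ContactPlot:
    """Residue-pair proximity matrix: true iff distance < threshold (strict).

    The diagonal is true.  For multi-copy proteins the first copy is used
    (documented choice — contact plots describe a single fold).
    """
    view = load_structure(structure)
    index: list[tuple[str, int]] = []
    coords = []
    for protein in view.proteins:
        for res in view.residues(protein, 0):
            index.append((protein, res))
            coords.append(view.coords(protein, res, atom_rule)[0])
    pts = np.asarray(coords)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    matrix = dist < threshold
    np.fill_diagonal(matrix, True)
    return ContactPlot(matrix=matrix, index=index, threshold=threshold, atom_rule=atom_rule)


@dataclass
class ConcordanceResult:
    """Per-chemistry fraction of links whose span fits the calibrated limit."""

    fraction: dict[str, float]
    outliers: list[tuple[CrossLink, float]]
    n_checked: dict[str, int]


def concordance(
    xls: Iterable[CrossLink],
    structure,
    constraint_per_chem: Mapping[str, float],
    atom_rule: str = "CA",
) -> ConcordanceResult:
    """Fraction of links with span ≤ the chemistry's constraint; outliers listed."""
    view = load_structure(structure)
    ok: dict[str, int] = {}
    total: dict[str, int] = {}
    outliers: list[tuple[CrossLink, float]] = []
    for xl in xls:
        limit = constraint_per_chem.get(xl.chemistry)
        if limit is None:
            continue
        d = residue_distance(
            view, xl.protein_1, xl.residue_1, xl.protein_2, xl.residue_2, atom_rule
        ).distance
        total[xl.chemistry] = total.get(xl.chemistry, 0) + 1
        if d <= limit:
            ok[xl.chemistry] = ok.get(xl.chemistry, 0) + 1
        else:
            outliers.append((xl, d))
    fraction = {c: ok.get(c, 0) / n for c, n in total.items()}
    return ConcordanceResult(fraction=fraction, outliers=outliers, n_checked=total)
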