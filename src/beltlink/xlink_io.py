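"""Cross-linker chemistry registry, link-table I/O and identification filters.

Cross-link identifications arrive as tables (one row per residue-pair
identification, from a spectral search run upstream at 1% FDR).  This module
reads them into :class:`CrossLink` records, applies the reproducibility rule
(a link counts only if seen in *every* replicate with every observation's
mass error within tolerance), checks chemical plausibility against the
reagent's reactive-residue set, and removes links touching dynamic regions
that cannot carry distance information.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CoordinateError, FormatError

__all__ = [
    "ChemistrySpec",
    "CrossLink",
    "ReadReport",
    "builtin_chemistries",
    "read_xl_table",
    "write_xl_table",
    "link_key",
    "filter_reproducible",
    "validate_reactivity",
    "exclude_dynamic_regions",
]

#: Canonical column names of the package's minimal link-table dialect.
CANONICAL_COLUMNS = (
    "protein1",
    "pos1",
    "protein2",
    "pos2",
    "chemistry",
    "replicate",
    "score",
    "ppm_error",
)


@dataclass(frozen=True)
class ChemistrySpec:
    """One cross-linking reagent.

    ``mass_shift`` is the monoisotopic shift applied to the linked product in
    the spectral search (negative for condensation chemistries).
    ``pairing``, when set, declares a heterobifunctional reagent: a valid
    link needs one end in each of the two sets.  ``max_span`` is filled by
    reference-structure calibration (mean span + 1 SD) and is ``None`` until
    then.
    """

    name: str
    mass_shift: float
    reactive_residues: frozenset[str]
    allows_protein_nterm: bool = True
    pairing: tuple[frozenset[str], frozenset[str]] | None = None
    max_span: float | None = None

    def __post_init__(self) -> None:
        if not self.reactive_residues:
            raise ValueError("reactive_residues must be non-empty")
        if not math.isfinite(self.mass_shift):
            raise ValueError("mass_shift must be finite")

    def with_max_span(self, max_span: float) -> "ChemistrySpec":
        return replace(self, max_span=max_span)


def builtin_chemistries() -> dict[str, ChemistrySpec]:
    """The three reagents with their spectral-search parameters.

    Formaldehyde (FM, +24.000 Da) is promiscuous across Lys/Arg/Asn/His/Asp/
    Tyr/Gln; BS3 (+138.068 Da) is Lys-to-Lys; EDC (−18.011 Da, condensation)
    is heterobifunctional carboxyl-to-amine, so a valid EDC link pairs one
    acidic end (D/E) with one amine end (K or a protein N-terminus).
    """
    return {
        "FM": ChemistrySpec(
            name="FM",
            mass_shift=24.000,
            reactive_residues=frozenset("KRNHDYQ"),
            allows_protein_nterm=True,
        ),
        "BS3": ChemistrySpec(
            name="BS3",
            mass_shift=138.068,
            reactive_residues=frozenset("K"),
            allows_protein_nterm=True,
        ),
        "EDC": ChemistrySpec(
            name="EDC",
            mass_shift=-18.011,
            reactive_residues=frozenset("KDE"),
            allows_protein_nterm=True,
            pairing=(frozenset("DE"), frozenset("K")),
        ),
    }


@dataclass(frozen=True)
class CrossLink:
    """One residue-pair identification."""

    protein_1: str
    residue_1: int
    protein_2: str
    residue_2: int
    chemistry: str
    replicate: str = "1"
    score: float = float("nan")
    mass_error_ppm: float = 0.0
    #: replicate id -> number of supporting observations (set by the
    #: reproducibility filter)
    evidence: tuple[tuple[str, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.residue_1 < 1 or self.residue_2 < 1:
            raise ValueError("residue positions are 1-based and must be ≥ 1")
        if not math.isfinite(self.mass_error_ppm):
            raise ValueError("mass_error_ppm must be finite")

    @property
    def ends(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.protein_1, self.residue_1), (self.protein_2, self.residue_2)

    def swapped(self) -> "CrossLink":
        return replace(
            self,
            protein_1=self.protein_2,
            residue_1=self.residue_2,
            protein_2=self.protein_1,
            residue_2=self.residue_1,
        )


def link_key(xl: CrossLink) -> tuple:
    """Order-normalized identity: sorted endpoints + chemistry."""
    a, b = sorted(xl.ends)
    return (a, b, xl.chemistry)


@dataclass
class ReadReport:
    """Parsed links plus rows that failed validation (never silently dropped)."""

    links: list[CrossLink]
    rejects: list[dict] = field(default_factory=list)


def read_xl_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> ReadReport:
    """Read a cross-link identification table (CSV or TSV).

    ``dialect`` maps canonical column names to the file's column names, so
    differently-labelled exports (search-engine version drift) are handled by
    configuration rather than code.  Malformed rows go to the rejects list
    with a reason.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if dialect:
        colmap.update(dialect)
    required = ("protein1", "pos1", "protein2", "pos2", "chemistry")
    for canon in required:
        if colmap[canon] not in df.columns:
            raise FormatError(f"missing required column {colmap[canon]!r} (for {canon})")
    report = ReadReport(links=[])
    for i, row in df.iterrows():
        raw = {c: row.get(colmap[c]) for c in CANONICAL_COLUMNS if colmap[c] in df.columns}
        try:
            xl = CrossLink(
                protein_1=str(raw["protein1"]),
                residue_1=int(raw["pos1"]),
                protein_2=str(raw["protein2"]),
                residue_2=int(raw["pos2"]),
                chemistry=str(raw["chemistry"]),
                replicate=str(raw.get("replicate", "1")),
                score=float(raw["score"]) if raw.get("score") is not None else float("nan"),
                mass_error_ppm=float(raw.get("ppm_error", 0.0)),
            )
        except (ValueError, TypeError) as exc:
            report.rejects.append({"row": int(i), "reason": str(exc), "data": raw})
            continue
        report.links.append(xl)
    return report


def write_xl_table(links: Iterable[CrossLink], path: str | Path, sep: str | None = None) -> None:
    """Write links in the canonical dialect (inverse of :func:`read_xl_table`)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    rows = [
        {
            "protein1": xl.protein_1,
            "pos1": xl.residue_1,
            "protein2": xl.protein_2,
            "pos2": xl.residue_2,
            "chemistry": xl.chemistry,
            "replicate": xl.replicate,
            "score": xl.score,
            "ppm_error": xl.mass_error_ppm,
        }
        for xl in links
    ]
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, sep=sep, index=False)


def filter_reproducible(
    replicates: Sequence[Sequence[CrossLink]],
    ppm_tol: float = 5.0,
) -> list[CrossLink]:
    """Keep links identified in *every* replicate with all masses in tolerance.

    A link is keyed by its order-normalized residue pair plus chemistry.  It
    survives iff the key appears in each replicate list and every supporting
    observation satisfies ``|mass_error_ppm| ≤ ppm_tol`` (boundary
    inclusive).  Survivors carry per-replicate evidence counts.
    """
    if len(replicates) == 0:
        raise ValueError("at least one replicate list is required")
    per_rep: list[dict[tuple, list[CrossLink]]] = []
    for rep in replicates:
        d: dict[tuple, list[CrossLink]] = {}
        for xl in rep:
            d.setdefault(link_key(xl), []).append(xl)
        per_rep.append(d)
    common = set(per_rep[0])
    for d in per_rep[1:]:
        common &= set(d)
    survivors = []
    for key in sorted(common):
        observations = [xl for d in per_rep for xl in d.get(key, [])]
        if any(abs(xl.mass_error_ppm) > ppm_tol for xl in observations):
            continue
        evidence = tuple(
            (obs[0].replicate if obs else str(i + 1), len(obs))
            for i, d in enumerate(per_rep)
            for obs in [d[key]]
        )
        survivors.append(replace(observations[0], evidence=evidence))
    return survivors


@dataclass(frozen=True)
class ReactivityResult:
    passed: bool
    reason: str

    def __bool__(self) -> bool:
        return self.passed


def _end_identity(xl_end: tuple[str, int], sequences: Mapping[str, str]) -> tuple[str, bool]:
    protein, pos = xl_end
    seq = sequences.get(protein)
    if seq is None:
        raise CoordinateError(f"no sequence for protein {protein!r}")
    if pos > len(seq):
        raise CoordinateError(f"{protein}:{pos} beyond sequence length {len(seq)}")
    return seq[pos - 1].upper(), pos == 1


def validate_reactivity(
    xl: CrossLink,
    chem: ChemistrySpec,
    sequences: Mapping[str, str],
) -> ReactivityResult:
    """Can this reagent chemically form this link?

    Each end must carry a reactive side chain (or be a protein N-terminus,
    for amine-directed reagents).  Heterobifunctional reagents additionally
    require one end from each of their two reactive classes — e.g. a
    carboxyl-to-amine reagent cannot join two lysines.
    """
    (aa1, nterm1), (aa2, nterm2) = (
        _end_identity(end, sequences) for end in xl.ends
    )

    def end_ok(aa: str, nterm: bool) -> bool:
        return aa in chem.reactive_residues or (nterm and chem.allows_protein_nterm)

    if not end_ok(aa1, nterm1):
        return ReactivityResult(False, f"end 1 ({aa1}) not reactive for {chem.name}")
    if not end_ok(aa2, nterm2):
        return ReactivityResult(False, f"end 2 ({aa2}) not reactive for {chem.name}")
    if chem.pairing is not None:
        set_a, set_b = chem.pairing

        def in_a(aa: str, nterm: bool) -> bool:
            return aa in set_a
        def in_b(aa: str, nterm: bool) -> bool:
            return aa in set_b or (nterm and chem.allows_protein_nterm)

        if not (
            (in_a(aa1, nterm1) and in_b(aa2, nterm2))
            or (in_a(aa2, nterm2) and in_b(aa1, nterm1))
        ):
            return ReactivityResult(
                False,
                f"{chem.name} is heterobifunctional: needs one end in "
                f"{sorted(set_a)} and one in {sorted(set_b)}/N-term",
            )
    return ReactivityResult(True, "ok")


def exclude_dynamic_regions(
    xls: Iterable[CrossLink],
    regions: Sequence[tuple[str, int, int]] = (("APOA1", 1, 1),),
) -> tuple[list[CrossLink], list[CrossLink]]:
    """Split links into (kept, excluded) by dynamic-region membership.

    Any link with an end inside a ``(protein, start, end)`` region is
    excluded: a highly mobile segment cross-links promiscuously and its spans
    carry no structural signal.  The default region is the APOA1 N-terminal
    residue only.
    """
    kept, excluded = [], []
    for xl in xls:
        touches = any(
            protein == p and start <= pos <= end
            for (p, pos) in xl.ends
            for (protein, start, end) in regions
        )
        (excluded if touches else kept).append(xl)
    return kept, excluded


def summary_json(stages: Mapping[str, Sequence[CrossLink]]) -> str:
    """Counts per chemistry at each named filter stage, as JSON."""
    out = {}
    for stage, links in stages.items():
        by_chem: dict[str, int] = {}
        for xl in links:
            by_chem[xl.chemistry] = by_chem.get(xl.chemistry, 0) + 1
        out[stage] = {"total": len(list(links)), "by_chemistry": by_chem}
    return json.dumps(out, indent=2, sort_keys=True)
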