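"""Uniform coordinate access over atomic and coarse structures.

Distance-based operations elsewhere in the package accept several kinds of
input — a real PDB/mmCIF structure, a coarse one-bead-per-residue model, or
the idealized belt — through a single adapter, :class:`StructureView`.  A view
maps ``(protein, residue, atom_rule)`` to one coordinate per *copy* of that
protein, so homodimers and the two belt chains are handled with the same
minimum-over-assignments logic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import CoordinateError

__all__ = ["ToyStructure", "StructureView", "load_structure"]

# 3-letter codes for PDB export of coarse models
_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_ONE = {v: k for k, v in _THREE.items()}


@dataclass
class ToyStructure:
    """One-bead-per-residue structure with an attached sequence.

    ``coords`` has one row per residue (1-based residue ``i`` is row
    ``i - 1``); the single pseudo-atom is treated as a Cα.
    """

    name: str
    sequence: str
    coords: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sequence), 3):
            raise ValueError("coords must be (len(sequence), 3)")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def to_view(self) -> "StructureView":
        copy = {i + 1: {"CA": self.coords[i]} for i in range(self.n_residues)}
        seq = {i + 1: self.sequence[i] for i in range(self.n_residues)}
        return StructureView({self.name: [copy]}, sequences={self.name: seq})

    def to_pdb(self, path: str | Path, chain: str = "A") -> None:
        write_pseudo_pdb(path, [(chain, self.sequence, self.coords)])


class StructureView:
    """Coordinate lookup over named proteins with one or more copies each.

    Parameters
    ----------
    copies
        ``{protein: [copy, ...]}`` where each copy is
        ``{residue_number: {atom_name: xyz}}``.
    sequences
        Optional ``{protein: {residue_number: one_letter}}``.
    """

    def __init__(
        self,
        copies: Mapping[str, Sequence[Mapping[int, Mapping[str, np.ndarray]]]],
        sequences: Mapping[str, Mapping[int, str]] | None = None,
    ) -> None:
        self._copies = {p: list(cs) for p, cs in copies.items()}
        self._sequences = {p: dict(s) for p, s in (sequences or {}).items()}

    @property
    def proteins(self) -> list[str]:
        return list(self._copies)

    def n_copies(self, protein: str) -> int:
        return len(self._copies.get(protein, ()))

    def residues(self, protein: str, copy: int = 0) -> list[int]:
        try:
            return sorted(self._copies[protein][copy])
        except (KeyError, IndexError):
            raise CoordinateError(f"protein {protein!r} copy {copy} not present")

    def residue_name(self, protein: str, residue: int) -> str | None:
        return self._sequences.get(protein, {}).get(residue)

    def coords(self, protein: str, residue: int, atom_rule: str = "CA") -> list[np.ndarray]:
        """One coordinate per copy that contains the residue.

        ``atom_rule`` is ``"CA"`` or ``"CB"``; under ``"CB"`` glycine and
        coarse models lacking a Cβ fall back to the Cα position.
        """
        if atom_rule not in ("CA", "CB"):
            raise ValueError(f"unknown atom rule {atom_rule!r}")
        if protein not in self._copies:
            raise CoordinateError(f"protein {protein!r} not in structure")
        out = []
        for copy in self._copies[protein]:
            atoms = copy.get(residue)
            if atoms is None:
                continue
            xyz = atoms.get(atom_rule)
            if xyz is None and atom_rule == "CB":
                xyz = atoms.get("CA")
            if xyz is not None:
                out.append(np.asarray(xyz, dtype=float))
        if not out:
            raise CoordinateError(
                f"residue {protein}:{residue} (atom rule {atom_rule}) absent from structure"
            )
        return out

    def has_residue(self, protein: str, residue: int) -> bool:
        return any(residue in c for c in self._copies.get(protein, ()))

    def all_coords(self, atom_rule: str = "CA") -> np.ndarray:
        """Stack of every residue anchor across proteins and copies."""
        rows = []
        for protein, copies in self._copies.items():
            for copy in copies:
                for residue in sorted(copy):
                    atoms = copy[residue]
                    xyz = atoms.get(atom_rule)
                    if xyz is None:
                        xyz = atoms.get("CA")
                    if xyz is not None:
                        rows.append(xyz)
        return np.asarray(rows, dtype=float)

    def first_copy_index(self, protein: str) -> list[int]:
        return self.residues(protein, 0)


def _from_gemmi(
    structure: gemmi.Structure,
    chain_map: Mapping[str, Iterable[str]] | None = None,
) -> StructureView:
    model = structure[0]  # first model only (NMR ensembles not averaged)
    by_chain: dict[str, dict[int, dict[str, np.ndarray]]] = {}
    seq_by_chain: dict[str, dict[int, str]] = {}
    for chain in model:
        res_map: dict[int, dict[str, np.ndarray]] = {}
        seq_map: dict[int, str] = {}
        for res in chain:
            if res.het_flag == "H" and res.name not in _ONE:
                continue
            num = res.seqid.num
            atoms = {}
            for atom in res:
                if atom.name in ("CA", "CB"):
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                    )
            if atoms:
                res_map[num] = atoms
                seq_map[num] = _ONE.get(res.name, "X")
        if res_map:
            by_chain[chain.name] = res_map
            seq_by_chain[chain.name] = seq_map
    if chain_map is None:
        chain_map = {name: [name] for name in by_chain}
    copies = {}
    seqs: dict[str, dict[int, str]] = {}
    for protein, chains in chain_map.items():
        copies[protein] = [by_chain[c] for c in chains if c in by_chain]
        merged: dict[int, str] = {}
        for c in chains:
            merged.update(seq_by_chain.get(c, {}))
        seqs[protein] = merged
    return StructureView(copies, sequences=seqs)


def load_structure(
    source: "StructureView | ToyStructure | gemmi.Structure | str | Path",
    chain_map: Mapping[str, Iterable[str]] | None = None,
) -> StructureView:
    """Normalize any supported structure source into a :class:`StructureView`.

    ``chain_map`` maps protein names to gemmi chain names (e.g. a homodimer's
    two chains to one protein); by default each chain is its own protein.
    """
    if isinstance(source, StructureView):
        return source
    if isinstance(source, ToyStructure):
        return source.to_view()
    if isinstance(source, gemmi.Structure):
        return _from_gemmi(source, chain_map)
    if isinstance(source, (str, Path)):
        st = gemmi.read_structure(str(source))
        return _from_gemmi(st, chain_map)
    raise TypeError(f"unsupported structure source: {type(source).__name__}")


def load_chains_as_protein(
    source: "str | Path | gemmi.Structure",
    protein: str,
) -> StructureView:
    """Read a structure and join all its chains into one continuously
    numbered protein (chain order as in the file) — the convention used for
    the double belt, whose two monomers form one 1..2N chain."""
    st = source if isinstance(source, gemmi.Structure) else gemmi.read_structure(str(source))
    merged: dict[int, dict[str, np.ndarray]] = {}
    seq: dict[int, str] = {}
    index = 0
    for chain in st[0]:
        for res in chain:
            atoms = {
                a.name: np.array([a.pos.x, a.pos.y, a.pos.z])
                for a in res
                if a.name in ("CA", "CB")
            }
            if not atoms:
                continue
            index += 1
            merged[index] = atoms
            seq[index] = _ONE.get(res.name, "X")
    return StructureView({protein: [merged]}, sequences={protein: seq})


def write_pseudo_pdb(
    path: str | Path,
    chains: Sequence[tuple[str, str, np.ndarray]],
) -> None:
    """Write a coarse model as PDB, one CA pseudo-atom per residue.

    ``chains`` is a sequence of ``(chain_id, sequence, coords)``.
    """
    st = gemmi.Structure()
    st.name = "beltlink-model"
    model = gemmi.Model("1")
    for chain_id, sequence, coords in chains:
        chain = gemmi.Chain(chain_id)
        coords = np.asarray(coords, dtype=float)
        for i, (aa, xyz) in enumerate(zip(sequence, coords), start=1):
            res = gemmi.Residue()
            res.name = _THREE.get(aa.upper(), "GLY")
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
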