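"""Macromolecular structure I/O and slicing.

Structures are held as a lightweight chain → residue → heavy-atom hierarchy
(:class:`Structure`), the common currency of the whole pipeline.  Parsing and
writing of PDB/mmCIF goes through :mod:`gemmi`; on read, hydrogens and waters
are dropped, alternate locations are resolved to the highest-occupancy copy
(first on a tie) and only the first model of multi-model files is kept.

Residue numbering follows the author numbering of the input file, including
insertion codes, so domain definitions can be written in the familiar
``A:283-327`` style.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import gemmi
import numpy as np

PolymerType = Literal["protein", "dna", "rna", "other"]

#: Standard residue names used for polymer-type classification.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
DNA_BASES = {"DA", "DC", "DG", "DT"}
RNA_BASES = {"A", "C", "G", "U"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    """Raised for unreadable, empty, or inconsistent structures."""


class DomainDefinitionError(ValueError):
    """Raised when a domain definition cannot be resolved against a structure."""


def classify_polymer_type(res_name: str) -> PolymerType:
    """Classify a residue name: 20 standard amino acids → protein,
    DA/DC/DG/DT → dna, A/C/G/U → rna, anything else → other."""
    name = res_name.strip().upper()
    if name in AMINO_ACIDS:
        return "protein"
    if name in DNA_BASES:
        return "dna"
    if name in RNA_BASES:
        return "rna"
    return "other"


@dataclass
class Atom:
    """A heavy atom: label, element symbol and position in Å."""

    name: str
    element: str
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not self.element:
            raise StructureError(f"atom {self.name!r} has empty element")
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise StructureError(f"atom {self.name!r} has invalid position")


@dataclass
class Residue:
    """One residue with author numbering and its heavy atoms."""

    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom]
    polymer_type: PolymerType = "other"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)


@dataclass
class Structure:
    """Ordered chains of residues; the universal pipeline currency."""

    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureError(f"duplicate chain ids in {ids}")

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"chain {chain_id!r} not found (have {self.chain_ids})")

    def residues(self) -> Iterator[Residue]:
        for _, residues in self.chains:
            yield from residues

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    @property
    def n_residues(self) -> int:
        return sum(len(r) for _, r in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.residues())

    def coords(self) -> np.ndarray:
        """All heavy-atom coordinates as an (n_atoms, 3) array, file order."""
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.array([a.pos for a in self.atoms()], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        """Overwrite atom positions in file order from an (n_atoms, 3) array."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise StructureError(
                f"coordinate array {xyz.shape} does not match {self.n_atoms} atoms"
            )
        for atom, row in zip(self.atoms(), xyz):
            atom.pos = row.copy()

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain (X for nonstandard protein residues)."""
        out = []
        for res in self.chain(chain_id):
            if res.polymer_type == "protein":
                out.append(THREE_TO_ONE.get(res.res_name, "X"))
            elif res.polymer_type == "dna":
                out.append(res.res_name[-1])
            elif res.polymer_type == "rna":
                out.append(res.res_name)
            else:
                out.append("X")
        return "".join(out)


@dataclass(frozen=True)
class DomainDefinition:
    """A named domain as inclusive author-numbered segments."""

    domain_id: str
    segments: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise DomainDefinitionError(f"domain {self.domain_id!r} has no segments")
        seen: list[tuple[str, int, int]] = []
        for chain_id, first, last in self.segments:
            if last < first:
                raise DomainDefinitionError(
                    f"domain {self.domain_id!r}: segment {chain_id}:{first}-{last} inverted"
                )
            for c2, f2, l2 in seen:
                if c2 == chain_id and not (last < f2 or first > l2):
                    raise DomainDefinitionError(
                        f"domain {self.domain_id!r}: overlapping segments on chain {chain_id}"
                    )
            seen.append((chain_id, first, last))

    def contains(self, res: Residue) -> bool:
        return any(
            res.chain_id == cid and first <= res.seq_num <= last
            for cid, first, last in self.segments
        )

    @classmethod
    def parse(cls, domain_id: str, text: str) -> "DomainDefinition":
        """Parse ``A:10-100`` or ``A:10-100,B:5-40`` style segment lists."""
        segments = []
        for part in text.split(","):
            chain_id, _, rng = part.strip().partition(":")
            first, _, last = rng.partition("-")
            segments.append((chain_id, int(first), int(last)))
        return cls(domain_id, tuple(segments))


# ---------------------------------------------------------------------------
# gemmi-backed reading and writing


def _from_gemmi(st: gemmi.Structure, label: str) -> Structure:
    st.setup_entities()
    st.remove_alternative_conformations()  # keeps highest occupancy, first on tie
    st.remove_hydrogens()
    st.remove_waters()
    if len(st) == 0:
        raise StructureError(f"{label}: file contains no models")
    model = st[0]
    chains: list[tuple[str, list[Residue]]] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            if res.name in WATER_NAMES:
                continue
            atoms = [
                Atom(a.name, a.element.name or "X", np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in res
                if not a.is_hydrogen()
            ]
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            residues.append(
                Residue(
                    chain_id=ch.name,
                    seq_num=res.seqid.num,
                    icode=icode,
                    res_name=res.name,
                    atoms=atoms,
                    polymer_type=classify_polymer_type(res.name),
                )
            )
        if residues:
            chains.append((ch.name, residues))
    if not chains:
        raise StructureError(f"{label}: no heavy atoms after filtering")
    return Structure(chains=chains, label=label)


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    ``format`` may be ``"pdb"`` or ``"mmcif"``; when omitted it is inferred
    from the file extension.  Hydrogens and waters are dropped, altlocs are
    resolved to highest occupancy, and only the first model is kept.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    if format is None:
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    return _from_gemmi(st, label=path.stem)


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as PDB, preserving chain ids and numbering."""
    st = gemmi.Structure()
    st.name = s.label or "model"
    model = gemmi.Model("1")
    for chain_id, residues in s.chains:
        ch = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.pos)
                ga.occ = 1.0
                gres.add_atom(ga)
            ch.add_residue(gres)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))


def write_complex(receptor: Structure, ligand: Structure, path: str | Path) -> None:
    """Write receptor and ligand into one PDB file as separate chains."""
    merged = Structure(
        chains=[(cid, [r for r in res]) for cid, res in receptor.chains]
        + [(cid, [r for r in res]) for cid, res in ligand.chains],
        label="complex",
    )
    write_structure(merged, path)


# ---------------------------------------------------------------------------
# slicing


def select_chains(s: Structure, chain_ids: Sequence[str]) -> Structure:
    """Sub-structure containing exactly the named chains, in the given order."""
    missing = [cid for cid in chain_ids if cid not in s.chain_ids]
    if missing:
        raise KeyError(f"chains {missing} not in structure (have {s.chain_ids})")
    chains = [(cid, copy.deepcopy(s.chain(cid))) for cid in chain_ids]
    return Structure(chains=chains, label=s.label)


def extract_domain(
    s: Structure, d: DomainDefinition
) -> tuple[Structure, dict[int, int]]:
    """Extract the residues of a domain definition from a structure.

    Returns the domain sub-structure together with an atom-index map from
    domain atom index to atom index in ``s`` (file order on both sides), so
    domain poses can later be projected back onto the full molecule.
    """
    atom_index_of: dict[int, int] = {}
    chains: list[tuple[str, list[Residue]]] = []
    seg_hit = {seg: False for seg in d.segments}
    src_index = 0
    dom_index = 0
    for chain_id, residues in s.chains:
        kept: list[Residue] = []
        for res in residues:
            inside = False
            for seg in d.segments:
                cid, first, last = seg
                if res.chain_id == cid and first <= res.seq_num <= last:
                    inside = True
                    seg_hit[seg] = True
                    break
            if inside:
                kept.append(copy.deepcopy(res))
                for _ in res.atoms:
                    atom_index_of[dom_index] = src_index
                    dom_index += 1
                    src_index += 1
            else:
                src_index += len(res.atoms)
        if kept:
            chains.append((chain_id, kept))
    for seg, hit in seg_hit.items():
        if not hit:
            cid, first, last = seg
            raise DomainDefinitionError(
                f"domain {d.domain_id!r}: segment {cid}:{first}-{last} matches no residue"
            )
    return Structure(chains=chains, label=f"{s.label}:{d.domain_id}"), atom_index_of
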