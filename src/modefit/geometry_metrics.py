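"""Rigid superposition, residue pairing, and CAPRI model-quality metrics.

The evaluation stack follows the standard CAPRI conventions for docking
assessment:

* the native **interface** is every residue with at least one heavy atom
  within 10.0 Å of any heavy atom of the other subunit;
* **f_nat** is the fraction of native cross-subunit residue contacts
  (5.0 Å heavy-atom cutoff) reproduced by a model;
* **I-RMSD** superposes the backbone atoms of the native interface residues
  onto the corresponding model atoms and reports their RMSD;
* **L-RMSD** superposes the model receptor onto the native receptor and
  reports the ligand backbone RMSD in that frame, with no further fitting;
* a model is **acceptable** when f_nat ≥ 0.10 and (I-RMSD ≤ 4.0 Å or
  L-RMSD ≤ 10.0 Å).

Backbone atoms are N, CA, C, O for proteins and P, O5', C5', C4', C3', O3'
for nucleic acids (the usual DockQ/CAPRI choice).  Unbound→bound residue
correspondence comes from global sequence alignment (BLOSUM62 −11/−1 for
proteins, +1/−1 identity for nucleic acids).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .structure_io import Residue, Structure

PROTEIN_BACKBONE = ("N", "CA", "C", "O")
NUCLEIC_BACKBONE = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")

INTERFACE_CUTOFF = 10.0  # Å, heavy atom, native interface definition
CONTACT_CUTOFF = 5.0  # Å, heavy atom, native contacts for f_nat
FNAT_ACCEPTABLE = 0.10
IRMSD_ACCEPTABLE = 4.0
LRMSD_ACCEPTABLE = 10.0


class MetricError(ValueError):
    """Raised when a metric is undefined or its inputs are degenerate."""


# ---------------------------------------------------------------------------
# superposition


@dataclass(frozen=True)
class Superposition:
    """Proper rigid transform x ↦ R x + t and the residual RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch(P: np.ndarray, Q: np.ndarray) -> Superposition:
    """Least-squares superposition of point set P onto Q (reflections excluded).

    Returns the proper rotation R and translation t minimizing
    RMSD(R·P + t, Q).  Requires at least 3 non-collinear points.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise MetricError(f"shape mismatch: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise MetricError(f"need at least 3 points, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinear / coincident point sets leave the rotation underdetermined
    if S[1] < 1e-9 * max(S[0], 1.0):
        raise MetricError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def rmsd_between(P: np.ndarray, Q: np.ndarray) -> float:
    """Plain coordinate RMSD with no superposition."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    if P.shape != Q.shape:
        raise MetricError(f"shape mismatch: {P.shape} vs {Q.shape}")
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# residue pairing by global sequence alignment


@dataclass(frozen=True)
class ResiduePairing:
    """One-to-one, order-preserving residue correspondence between two chains."""

    pairs: tuple[tuple[Residue, Residue], ...]
    coverage: float


def _chain_kind(residues: Sequence[Residue]) -> str:
    kinds = {r.polymer_type for r in residues if r.polymer_type != "other"}
    if kinds <= {"protein"} and "protein" in kinds:
        return "protein"
    if kinds <= {"dna", "rna"} and kinds:
        return "nucleic"
    if not kinds:
        return "other"
    return "mixed"


def _sequence(residues: Sequence[Residue]) -> str:
    from .structure_io import THREE_TO_ONE

    out = []
    for r in residues:
        if r.polymer_type == "protein":
            out.append(THREE_TO_ONE.get(r.res_name, "X"))
        elif r.polymer_type in ("dna", "rna"):
            out.append(r.res_name.strip()[-1].upper())
        else:
            out.append("X")
    return "".join(out)


def pair_residues(a: Sequence[Residue], b: Sequence[Residue]) -> ResiduePairing:
    """Pair residues of two chains by global alignment.

    Both chains must be protein or both nucleic; only aligned non-gap
    positions are paired.  Coverage is the paired fraction of the shorter
    chain.
    """
    if not a or not b:
        raise MetricError("cannot pair an empty chain")
    ka, kb = _chain_kind(a), _chain_kind(b)
    if ka == "protein" and kb == "protein":
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
    elif ka == "nucleic" and kb == "nucleic":
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -1
    else:
        raise MetricError(
            f"cannot pair chains of kinds {ka!r} and {kb!r}; "
            "both must be protein or both nucleic"
        )
    sa, sb = _sequence(a), _sequence(b)
    alignment = aligner.align(sa, sb)[0]
    pairs: list[tuple[Residue, Residue]] = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((a[i], b[j]))
    coverage = len(pairs) / min(len(a), len(b))
    return ResiduePairing(pairs=tuple(pairs), coverage=coverage)


def pair_structures(a: Structure, b: Structure) -> list[tuple[Residue, Residue]]:
    """Chain-by-chain residue pairing between two structures.

    Chains are matched by id when possible, else by order.
    """
    pairs: list[tuple[Residue, Residue]] = []
    b_ids = b.chain_ids
    used: set[str] = set()
    for idx, (cid, residues) in enumerate(a.chains):
        if cid in b_ids and cid not in used:
            other = b.chain(cid)
            used.add(cid)
        elif idx < len(b.chains):
            other = b.chains[idx][1]
            used.add(b.chains[idx][0])
        else:
            continue
        pairs.extend(pair_residues(residues, other).pairs)
    return pairs


def conformational_difference(unbound: Structure, bound: Structure) -> float:
    """Cα RMSD between two conformations of the same protein.

    Residues are paired by sequence alignment; the Cα sets are superposed by
    least squares and their RMSD returned.  This is the standard measure of
    how far a binding event deforms a subunit.
    """
    pairs = pair_structures(unbound, bound)
    P, Q = [], []
    for ra, rb in pairs:
        aa, ab = ra.atom("CA"), rb.atom("CA")
        if aa is not None and ab is not None:
            P.append(aa.pos)
            Q.append(ab.pos)
    if len(P) < 3:
        raise MetricError(f"only {len(P)} paired Cα atoms; need ≥ 3")
    return kabsch(np.array(P), np.array(Q)).rmsd


# ---------------------------------------------------------------------------
# interfaces and contacts


@dataclass(frozen=True)
class InterfaceDefinition:
    receptor_residues: frozenset[tuple[str, int, str]]
    ligand_residues: frozenset[tuple[str, int, str]]
    cutoff: float


@dataclass(frozen=True)
class ContactSet:
    contacts: frozenset[tuple[tuple[str, int, str], tuple[str, int, str]]]
    cutoff: float


def _residue_atom_arrays(s: Structure) -> tuple[list[Residue], np.ndarray, np.ndarray]:
    """Flatten a structure into residues, atom coords, and per-atom residue index."""
    residues = list(s.residues())
    coords = []
    res_idx = []
    for i, res in enumerate(residues):
        for atom in res.atoms:
            coords.append(atom.pos)
            res_idx.append(i)
    return residues, np.asarray(coords, float), np.asarray(res_idx, int)


def _cross_residue_pairs(
    receptor: Structure, ligand: Structure, cutoff: float
) -> set[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    """All (receptor residue, ligand residue) pairs with any heavy-atom pair
    within cutoff, via a KD-tree over both atom sets."""
    r_res, r_xyz, r_idx = _residue_atom_arrays(receptor)
    l_res, l_xyz, l_idx = _residue_atom_arrays(ligand)
    if len(r_xyz) == 0 or len(l_xyz) == 0:
        raise MetricError("empty structure in interface computation")
    tree_r = cKDTree(r_xyz)
    tree_l = cKDTree(l_xyz)
    pairs = tree_r.query_ball_tree(tree_l, r=cutoff)
    out: set[tuple[tuple[str, int, str], tuple[str, int, str]]] = set()
    for ai, hits in enumerate(pairs):
        if not hits:
            continue
        rkey = r_res[r_idx[ai]].key
        for bj in hits:
            out.add((rkey, l_res[l_idx[bj]].key))
    return out


def define_interface(
    receptor: Structure, ligand: Structure, cutoff: float = INTERFACE_CUTOFF
) -> InterfaceDefinition:
    """Interface of a (native) complex: residues of either subunit with at
    least one heavy atom within ``cutoff`` of any atom of the other subunit."""
    pairs = _cross_residue_pairs(receptor, ligand, cutoff)
    return InterfaceDefinition(
        receptor_residues=frozenset(r for r, _ in pairs),
        ligand_residues=frozenset(l for _, l in pairs),
        cutoff=cutoff,
    )


def native_contacts(
    receptor: Structure, ligand: Structure, cutoff: float = CONTACT_CUTOFF
) -> ContactSet:
    """Cross-subunit residue contacts at the (5.0 Å) contact cutoff."""
    return ContactSet(
        contacts=frozenset(_cross_residue_pairs(receptor, ligand, cutoff)),
        cutoff=cutoff,
    )


def _key_map(native: Structure, model: Structure) -> dict[tuple[str, int, str], Residue]:
    """Map native residue keys to model residues via sequence pairing."""
    pairs = pair_structures(native, model)
    return {rn.key: rm for rn, rm in pairs}


def f_nat(
    native: ContactSet,
    model_receptor: Structure,
    model_ligand: Structure,
    receptor_map: dict[tuple[str, int, str], Residue] | None = None,
    ligand_map: dict[tuple[str, int, str], Residue] | None = None,
) -> float:
    """Fraction of native contacts reproduced in a model at the 5.0 Å cutoff.

    ``receptor_map``/``ligand_map`` translate native residue keys into model
    residues; identity mapping is assumed when omitted (model uses native
    numbering, the common case for docking output).
    """
    if not native.contacts:
        raise MetricError("native contact set is empty; f_nat undefined")
    model_pairs = _cross_residue_pairs(model_receptor, model_ligand, native.cutoff)
    if receptor_map is None and ligand_map is None:
        present = native.contacts & model_pairs
        return len(present) / len(native.contacts)
    count = 0
    for rk, lk in native.contacts:
        mr = receptor_map.get(rk) if receptor_map else None
        ml = ligand_map.get(lk) if ligand_map else None
        mrk = mr.key if mr is not None else rk
        mlk = ml.key if ml is not None else lk
        if (mrk, mlk) in model_pairs:
            count += 1
    return count / len(native.contacts)


def _backbone_names(res: Residue) -> tuple[str, ...]:
    if res.polymer_type == "protein":
        return PROTEIN_BACKBONE
    if res.polymer_type in ("dna", "rna"):
        return NUCLEIC_BACKBONE
    return PROTEIN_BACKBONE  # nonstandard residues: try the protein set


def _paired_backbone(
    native_residues: Iterable[Residue],
    model_of: dict[tuple[str, int, str], Residue],
) -> tuple[np.ndarray, np.ndarray]:
    """Matched native/model backbone coordinates; missing atoms drop the
    atom pair, unmappable residues raise."""
    P, Q = [], []
    for res in native_residues:
        model_res = model_of.get(res.key)
        if model_res is None:
            raise MetricError(f"interface residue {res.key} not mappable into model")
        for name in _backbone_names(res):
            a, b = res.atom(name), model_res.atom(name)
            if a is not None and b is not None:
                P.append(a.pos)
                Q.append(b.pos)
    return np.asarray(P, float), np.asarray(Q, float)


def _model_map(
    native: Structure, model: Structure, pair_by_sequence: bool
) -> dict[tuple[str, int, str], Residue]:
    if pair_by_sequence:
        return _key_map(native, model)
    return {res.key: res for res in model.residues()}


def i_rmsd(
    native_receptor: Structure,
    native_ligand: Structure,
    model_receptor: Structure,
    model_ligand: Structure,
    interface: InterfaceDefinition | None = None,
    pair_by_sequence: bool = False,
) -> float:
    """Interface RMSD: superpose native-interface backbone atoms onto the
    corresponding model atoms and report their RMSD."""
    if interface is None:
        interface = define_interface(native_receptor, native_ligand)
    rmap = _model_map(native_receptor, model_receptor, pair_by_sequence)
    lmap = _model_map(native_ligand, model_ligand, pair_by_sequence)
    nat_r = [r for r in native_receptor.residues() if r.key in interface.receptor_residues]
    nat_l = [r for r in native_ligand.residues() if r.key in interface.ligand_residues]
    Pr, Qr = _paired_backbone(nat_r, rmap)
    Pl, Ql = _paired_backbone(nat_l, lmap)
    P = np.vstack([Pr, Pl])
    Q = np.vstack([Qr, Ql])
    return kabsch(P, Q).rmsd


def l_rmsd(
    native_receptor: Structure,
    native_ligand: Structure,
    model_receptor: Structure,
    model_ligand: Structure,
    pair_by_sequence: bool = False,
    backbone_only: bool = True,
) -> float:
    """Ligand RMSD: superpose the model receptor onto the native receptor,
    then report the ligand backbone RMSD in that frame (no refitting)."""
    rmap = _model_map(native_receptor, model_receptor, pair_by_sequence)
    lmap = _model_map(native_ligand, model_ligand, pair_by_sequence)
    # receptor superposition over backbone atoms
    Pr, Qr = _paired_backbone(list(native_receptor.residues()), rmap)
    sup = kabsch(Qr, Pr)  # model → native frame
    P, Q = [], []
    for res in native_ligand.residues():
        model_res = lmap.get(res.key)
        if model_res is None:
            raise MetricError(f"ligand residue {res.key} not mappable into model")
        names = _backbone_names(res) if backbone_only else None
        if names is None:
            for a in res.atoms:
                b = model_res.atom(a.name)
                if b is not None:
                    P.append(a.pos)
                    Q.append(b.pos)
        else:
            for name in names:
                a, b = res.atom(name), model_res.atom(name)
                if a is not None and b is not None:
                    P.append(a.pos)
                    Q.append(b.pos)
    if not P:
        raise MetricError("no matched ligand backbone atoms")
    Qm = sup.apply(np.asarray(Q, float))
    return rmsd_between(np.asarray(P, float), Qm)


# ---------------------------------------------------------------------------
# CAPRI classification


@dataclass(frozen=True)
class CapriMetrics:
    f_nat: float
    i_rmsd: float
    l_rmsd: float

    @property
    def quality(self) -> Literal["incorrect", "acceptable_or_better"]:
        return capri_class(self)


def capri_class(m: CapriMetrics) -> Literal["incorrect", "acceptable_or_better"]:
    """CAPRI quality: acceptable iff f_nat ≥ 0.10 and (I-RMSD ≤ 4.0 Å or
    L-RMSD ≤ 10.0 Å)."""
    for v in (m.f_nat, m.i_rmsd, m.l_rmsd):
        if not np.isfinite(v):
            raise MetricError("CAPRI metrics must be finite")
    ok = m.f_nat >= FNAT_ACCEPTABLE and (
        m.i_rmsd <= IRMSD_ACCEPTABLE or m.l_rmsd <= LRMSD_ACCEPTABLE
    )
    return "acceptable_or_better" if ok else "incorrect"


def evaluate_model(
    native_receptor: Structure,
    native_ligand: Structure,
    model_receptor: Structure,
    model_ligand: Structure,
    pair_by_sequence: bool = False,
) -> CapriMetrics:
    """Full CAPRI triple (f_nat, I-RMSD, L-RMSD) of a model against a native
    complex."""
    contacts = native_contacts(native_receptor, native_ligand)
    if pair_by_sequence:
        rmap = _key_map(native_receptor, model_receptor)
        lmap = _key_map(native_ligand, model_ligand)
        fn = f_nat(contacts, model_receptor, model_ligand, rmap, lmap)
    else:
        fn = f_nat(contacts, model_receptor, model_ligand)
    ir = i_rmsd(
        native_receptor, native_ligand, model_receptor, model_ligand,
        pair_by_sequence=pair_by_sequence,
    )
    lr = l_rmsd(
        native_receptor, native_ligand, model_receptor, model_ligand,
        pair_by_sequence=pair_by_sequence,
    )
    return CapriMetrics(f_nat=fn, i_rmsd=ir, l_rmsd=lr)
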