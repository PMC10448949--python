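"""Ground-truthed synthetic systems for exercising the whole pipeline.

The generator emulates the regime the fitting engine targets: a two-domain
protein whose domains are near-rigid but reorient about a flexible linker by
10 Å Cα RMSD or more on binding.  It produces

* an *unbound* backbone-only (N, CA, C, O) poly-alanine chain — two idealized
  α-helical domains joined by an extended linker, built from standard
  internal coordinates so the restraint minimizer's references are sane;
* a *bound* conformation made by rigidly rotating the second domain about a
  hinge axis through the linker midpoint (linker interpolated, domains
  internally rigid by construction);
* a rigid toy double-helical receptor with P/C4'/N1 pseudo-atoms per
  nucleotide (polymer type rna), placed in contact with the bound ligand;
* labeled decoy pose pools: near-native poses are small rigid perturbations
  of the native domain placement, wrong poses are placed at random
  non-overlapping locations around the receptor, and synthetic shape scores
  correlate with pose quality so the consensus scorer has signal to learn.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .flexfit import DomainPose, pose_from_structure
from .geometry_metrics import kabsch
from .structure_io import Atom, DomainDefinition, Residue, Structure, extract_domain

# backbone internal coordinates (Å, degrees): Engh–Huber-like ideal values
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_C_N_CA, A_N_CA_C, A_CA_C_N, A_CA_C_O = 121.7, 111.2, 116.2, 120.5
HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -120.0, 140.0


class FixtureError(RuntimeError):
    pass


@dataclass(frozen=True)
class HingeSpec:
    """Parameters of the two-domain hinge fixture."""

    residues_per_domain: int = 24
    linker_length: int = 10
    #: rotation axis; None → perpendicular to the pivot→domain-2 direction,
    #: which produces a genuine bending motion rather than axial spin
    hinge_axis: tuple[float, float, float] | None = None
    hinge_angle: float = 160.0  # degrees of total torsion budget across the linker
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hinge_angle <= 180.0):
            raise FixtureError("hinge angle must be in [0, 180] degrees")
        if self.residues_per_domain < 5 or self.linker_length < 1:
            raise FixtureError("domains need ≥5 residues and linker ≥1")


@dataclass(frozen=True)
class DecoySpec:
    """Parameters of a labeled decoy pose pool."""

    n_near_native: int = 5
    n_wrong: int = 20
    rotation_sigma: float = 3.0  # degrees
    translation_sigma: float = 1.0  # Å
    score_noise_sigma: float = 0.5  # noise on quality-correlated shape scores
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_near_native < 0 or self.n_wrong < 0:
            raise FixtureError("pose counts must be non-negative")
        if self.rotation_sigma < 0 or self.translation_sigma < 0:
            raise FixtureError("perturbation sigmas must be non-negative")


# ---------------------------------------------------------------------------
# internal-coordinate chain building


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D from A-B-C plus
    (C-D length, B-C-D angle, A-B-C-D torsion)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(ang),
        length * np.cos(tor) * np.sin(ang),
        length * np.sin(tor) * np.sin(ang),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phi_psi: list[tuple[float, float]]) -> np.ndarray:
    """Backbone N, CA, C, O coordinates for a chain with given (φ, ψ) per
    residue (φ of residue 0 and ψ of the last are not used); ω fixed at 180°."""
    n_res = len(phi_psi)
    coords = np.zeros((n_res, 4, 3))  # N, CA, C, O
    # seed first residue explicitly
    coords[0, 0] = np.array([0.0, 0.0, 0.0])  # N
    coords[0, 1] = np.array([B_N_CA, 0.0, 0.0])  # CA
    ang = np.radians(A_N_CA_C)
    coords[0, 2] = coords[0, 1] + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        phi, psi = phi_psi[i]
        if i > 0:
            coords[i, 0] = _place_atom(  # N(i) from N(i-1)-CA(i-1)-C(i-1), torsion ψ(i-1)
                coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2],
                B_C_N, A_CA_C_N, phi_psi[i - 1][1],
            )
            coords[i, 1] = _place_atom(  # CA(i), torsion ω = 180
                coords[i - 1, 1], coords[i - 1, 2], coords[i, 0],
                B_N_CA, A_C_N_CA, 180.0,
            )
            coords[i, 2] = _place_atom(  # C(i), torsion φ(i)
                coords[i - 1, 2], coords[i, 0], coords[i, 1],
                B_CA_C, A_N_CA_C, phi,
            )
        # O(i): in the peptide plane, torsion ψ(i) + 180 about N-CA-C
        coords[i, 3] = _place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2],
            B_C_O, A_CA_C_O, psi + 180.0,
        )
    return coords


def make_two_domain_protein(spec: HingeSpec) -> tuple[Structure, list[DomainDefinition]]:
    """Backbone-only poly-alanine hinge protein: helix–linker–helix.

    Returns the unbound structure (chain L, residues numbered from 1) and the
    two domain definitions flanking the linker.  The seed jitters the
    backbone dihedrals by a fraction of a degree so distinct seeds give
    distinct but equally idealized chains.
    """
    rng = np.random.default_rng(spec.seed)
    n_dom, n_link = spec.residues_per_domain, spec.linker_length
    n_res = 2 * n_dom + n_link
    phi_psi = []
    for i in range(n_res):
        if n_dom <= i < n_dom + n_link:
            base = (EXTENDED_PHI, EXTENDED_PSI)
        else:
            base = (HELIX_PHI, HELIX_PSI)
        jitter = rng.normal(0.0, 0.5, size=2)
        phi_psi.append((base[0] + jitter[0], base[1] + jitter[1]))
    xyz = _build_backbone(phi_psi)
    residues = []
    for i in range(n_res):
        atoms = [
            Atom("N", "N", xyz[i, 0]),
            Atom("CA", "C", xyz[i, 1]),
            Atom("C", "C", xyz[i, 2]),
            Atom("O", "O", xyz[i, 3]),
        ]
        residues.append(
            Residue(chain_id="L", seq_num=i + 1, icode="", res_name="ALA",
                    atoms=atoms, polymer_type="protein")
        )
    s = Structure(chains=[("L", residues)], label="hinge-unbound")
    domains = [
        DomainDefinition("D1", (("L", 1, n_dom),)),
        DomainDefinition("D2", (("L", n_dom + n_link + 1, n_res),)),
    ]
    return s, domains


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _rotate_downstream(bound: Structure, p0: np.ndarray, p1: np.ndarray,
                       angle_deg: float, start_res: int, start_atoms: list[int]) -> None:
    """Rotate ``start_atoms`` of residue ``start_res`` and every atom of all
    later residues about the bond axis p0→p1 (a torsion move: bonds and
    angles are exactly preserved)."""
    axis = p1 - p0
    R = _rotation_about_axis(axis, angle_deg)
    for i, res in enumerate(bound.residues()):
        if i < start_res:
            continue
        for j, atom in enumerate(res.atoms):
            if i == start_res and j not in start_atoms:
                continue
            atom.pos = R @ (atom.pos - p1) + p1

def make_bound_state(unbound: Structure, domains: list[DomainDefinition],
                     spec: HingeSpec) -> Structure:
    """Bound conformation produced by a hinge motion of the second domain.

    By default (``hinge_axis=None``) the hinge is applied in torsion space:
    the total hinge angle is distributed evenly over the φ and ψ dihedrals of
    the linker residues, so every bond length, bond angle and domain-internal
    coordinate of the unbound chain is preserved exactly — the bound state is
    reachable by any bonded deformation.  The sign of the torsion change is
    chosen to avoid steric collision of the closing domains.

    With an explicit ``hinge_axis`` the second domain is instead rigidly
    rotated by the hinge angle about that axis through the linker-midpoint
    CA, with linker residues carried through fractional rotations; this
    idealized variant reorients exactly as requested but does not preserve
    the covalent geometry across linker junctions.
    """
    if spec.hinge_angle == 0.0:
        import warnings

        warnings.warn("hinge angle 0: bound state equals unbound", stacklevel=2)
        return unbound.copy()
    residues = list(unbound.residues())
    d1, d2 = domains
    link_keys = [r.key for r in residues if not (d1.contains(r) or d2.contains(r))]
    if not link_keys:
        raise FixtureError("hinge pivot requires a non-empty linker")
    if spec.hinge_axis is not None:
        return _make_bound_rigid_rotation(unbound, domains, spec, link_keys)
    n_link = len(link_keys)
    link_set = set(link_keys)
    link_res_idx = [i for i, r in enumerate(residues) if r.key in link_set]
    delta = spec.hinge_angle / (2 * n_link)

    def build(sign: float) -> Structure:
        bound = unbound.copy()
        bound.label = "hinge-bound"
        for ri in link_res_idx:
            res = list(bound.residues())[ri]
            n_pos, ca_pos, c_pos = (res.atoms[0].pos.copy(), res.atoms[1].pos.copy(),
                                    res.atoms[2].pos.copy())
            # φ: rotate about N–CA, moving C and O of this residue onward
            _rotate_downstream(bound, n_pos, ca_pos, sign * delta, ri, [2, 3])
            c_pos = list(bound.residues())[ri].atoms[2].pos.copy()
            # ψ: rotate about CA–C, moving O of this residue onward
            _rotate_downstream(bound, ca_pos, c_pos, sign * delta, ri, [3])
        return bound

    bound = build(+1.0)
    # reject a closing direction that collides the domains
    xyz1 = np.array([a.pos for r in bound.residues() if d1.contains(r) for a in r.atoms])
    xyz2 = np.array([a.pos for r in bound.residues() if d2.contains(r) for a in r.atoms])
    from scipy.spatial import cKDTree

    if cKDTree(xyz1).query(xyz2)[0].min() < 3.0:
        bound = build(-1.0)
    return bound


def _make_bound_rigid_rotation(
    unbound: Structure, domains: list[DomainDefinition], spec: HingeSpec,
    link_keys: list,
) -> Structure:
    d1, d2 = domains
    residues = list(unbound.residues())
    mid = link_keys[len(link_keys) // 2]
    pivot_res = next(r for r in residues if r.key == mid)
    pivot = pivot_res.atom("CA").pos.copy()
    axis = np.asarray(spec.hinge_axis, dtype=float)
    axis /= np.linalg.norm(axis)
    bound = unbound.copy()
    bound.label = "hinge-bound"
    n_link = len(link_keys)
    link_order = {k: i for i, k in enumerate(link_keys)}
    for res in bound.residues():
        if d1.contains(res):
            continue
        if d2.contains(res):
            frac = 1.0
        else:
            frac = (link_order[res.key] + 1) / (n_link + 1)
        R = _rotation_about_axis(axis, spec.hinge_angle * frac)
        for atom in res.atoms:
            atom.pos = R @ (atom.pos - pivot) + pivot
    return bound


# ---------------------------------------------------------------------------
# toy receptor


def make_receptor(n_units: int = 12, seed: int = 0) -> Structure:
    """Rigid toy double-helical nucleic acid with P/C4'/N1 pseudo-atoms.

    Two antiparallel strands (chains R and S) of ``n_units`` nucleotides each
    on an ideal helix (rise 2.8 Å, twist 33°/step); residue names cycle
    through A/C/G/U so every residue classifies as RNA.
    """
    if n_units < 4:
        raise FixtureError("receptor needs at least 4 units per strand")
    rng = np.random.default_rng(seed)
    phase0 = rng.uniform(0.0, 2 * np.pi)
    rise, twist = 2.8, np.radians(33.0)
    names = "ACGU"
    chains = []
    for strand, (cid, phase, direction) in enumerate(
        [("R", phase0, 1.0), ("S", phase0 + np.pi * 0.85, -1.0)]
    ):
        residues = []
        for i in range(n_units):
            z = direction * i * rise
            ang = phase + direction * i * twist
            def ring(radius: float, dphi: float = 0.0) -> np.ndarray:
                return np.array([
                    radius * np.cos(ang + dphi), radius * np.sin(ang + dphi), z
                ])
            atoms = [
                Atom("P", "P", ring(9.0)),
                Atom("C4'", "C", ring(7.0, 0.25)),
                Atom("N1", "N", ring(4.0, 0.5)),
            ]
            residues.append(
                Residue(chain_id=cid, seq_num=i + 1, icode="",
                        res_name=names[i % 4], atoms=atoms, polymer_type="rna")
            )
        chains.append((cid, residues))
    return Structure(chains=chains, label="toy-receptor")


def place_receptor_against(ligand: Structure, receptor: Structure,
                           contact_gap: float = 3.2) -> Structure:
    """Translate the receptor until its closest heavy-atom approach to the
    ligand equals ``contact_gap``.  The approach direction is the ligand's
    smallest principal axis (its broadside), which maximizes the buried
    interface; the slide distance is found by bisection, deterministically."""
    from scipy.spatial import cKDTree

    lig = ligand.coords()
    rec = receptor.copy()
    xyz = rec.coords()
    xyz -= xyz.mean(axis=0)
    center = lig.mean(axis=0)
    cov = np.cov((lig - center).T)
    _, evecs = np.linalg.eigh(cov)
    tree = cKDTree(lig)
    offset = np.max(np.linalg.norm(lig - center, axis=1)) + np.max(
        np.linalg.norm(xyz, axis=1)
    ) + contact_gap + 5.0

    def slide(direction: np.ndarray) -> np.ndarray:
        lo, hi = 0.0, offset
        for _ in range(60):  # bisect on closest-approach distance
            midv = 0.5 * (lo + hi)
            d = tree.query(xyz + center + direction * midv)[0].min()
            if d < contact_gap:
                lo = midv
            else:
                hi = midv
        return xyz + center + direction * hi

    # try each principal-axis direction and keep the placement burying the
    # most 5 Å atom contacts — nests the rod into the hinge cleft
    best, best_contacts = None, -1
    for k in range(3):
        for sign in (1.0, -1.0):
            placed = slide(sign * evecs[:, k])
            n_contact = int(np.sum(tree.query(placed)[0] < 5.0))
            if n_contact > best_contacts:
                best, best_contacts = placed, n_contact
    rec.set_coords(best)
    return rec


def make_hinge_complex(
    spec: HingeSpec | None = None, receptor_units: int = 12,
) -> tuple[Structure, Structure, Structure, list[DomainDefinition]]:
    """Full fixture: (unbound ligand, bound ligand, receptor in contact with
    the bound ligand, domain definitions)."""
    spec = spec or HingeSpec()
    unbound, domains = make_two_domain_protein(spec)
    bound = make_bound_state(unbound, domains, spec)
    receptor = place_receptor_against(bound, make_receptor(receptor_units, spec.seed))
    return unbound, bound, receptor, domains


# ---------------------------------------------------------------------------
# decoy pose pools


@dataclass
class LabeledPose:
    """A decoy domain pose with its ground-truth quality labels.

    ``capri`` is filled when the decoy generator is given the domain's
    residue template and the native placement forms an interface with the
    receptor; it is recomputed from scratch with the evaluation stack, not
    inherited from the perturbation parameters.
    """

    pose: DomainPose
    rmsd_to_native: float  # RMSD of pose atoms to the native placement, Å
    near_native: bool
    capri: "CapriMetrics | None" = None


def _random_rotation(rng: np.random.Generator, sigma_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, sigma_deg)
    return _rotation_about_axis(axis, angle)


def make_decoy_pool(
    native_pose: DomainPose,
    receptor: Structure,
    spec: DecoySpec,
    domain_template: Structure | None = None,
) -> list[LabeledPose]:
    """Labeled decoy pool around a native domain placement.

    Near-native poses perturb the native placement by a random rotation about
    the domain centroid (angle ~ N(0, rotation_sigma)) plus a random
    translation (~N(0, translation_sigma) per axis).  Wrong poses are placed
    at uniformly random orientations and random clash-free positions around
    the receptor.  Synthetic shape scores decrease with RMSD to the native
    placement plus seeded noise, so scoring has learnable signal.
    """
    rng = np.random.default_rng(spec.seed)
    rec_xyz = receptor.coords()
    from scipy.spatial import cKDTree

    rec_tree = cKDTree(rec_xyz)
    native_xyz = native_pose.coords
    centroid = native_xyz.mean(axis=0)
    radius = float(np.max(np.linalg.norm(native_xyz - centroid, axis=1)))
    rec_center = rec_xyz.mean(axis=0)
    rec_radius = float(np.max(np.linalg.norm(rec_xyz - rec_center, axis=1)))
    out: list[LabeledPose] = []
    native_template = None
    if domain_template is not None:
        native_template = domain_template.copy()
        native_template.set_coords(native_xyz)

    def finish(xyz: np.ndarray, near: bool) -> None:
        rmsd = float(np.sqrt(np.mean(np.sum((xyz - native_xyz) ** 2, axis=1))))
        score = 10.0 - rmsd + rng.normal(0.0, spec.score_noise_sigma)
        pose = DomainPose(
            domain_id=native_pose.domain_id,
            coords=xyz,
            atom_map=native_pose.atom_map.copy(),
            shape_score=score,
        )
        capri = None
        if native_template is not None:
            from .geometry_metrics import MetricError, evaluate_model

            placed = domain_template.copy()
            placed.set_coords(xyz)
            try:
                capri = evaluate_model(receptor, native_template, receptor, placed)
            except MetricError:
                capri = None  # native domain forms no interface/contacts
        out.append(LabeledPose(pose=pose, rmsd_to_native=rmsd, near_native=near,
                               capri=capri))

    for _ in range(spec.n_near_native):
        R = _random_rotation(rng, spec.rotation_sigma)
        t = rng.normal(0.0, spec.translation_sigma, size=3)
        finish((native_xyz - centroid) @ R.T + centroid + t, near=True)
    for _ in range(spec.n_wrong):
        for _attempt in range(1000):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            R = _rotation_about_axis(axis, rng.uniform(0.0, 360.0))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = rec_radius + radius + rng.uniform(2.0, 6.0)
            center = rec_center + direction * dist
            xyz = (native_xyz - centroid) @ R.T + center
            min_gap = rec_tree.query(xyz)[0].min()
            clearly_wrong = (
                np.sqrt(np.mean(np.sum((xyz - native_xyz) ** 2, axis=1))) > 8.0
            )
            if min_gap > 2.5 and clearly_wrong:
                finish(xyz, near=False)
                break
        else:
            raise FixtureError("could not place a non-overlapping wrong pose in 1000 tries")
    return out


def native_domain_pose(
    unbound: Structure, bound: Structure, domain: DomainDefinition
) -> DomainPose:
    """The ground-truth pose of one domain: bound-conformation coordinates
    mapped onto the unbound ligand's atom indexing."""
    from .flexfit import poses_from_bound

    return poses_from_bound(unbound, bound, [domain])[0]
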