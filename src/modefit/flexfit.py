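"""Iterative elastic-network fitting of a full ligand to docked domain poses.

Given rigid placements of two (or more) extracted domains relative to a fixed
receptor, the engine deforms the whole unbound ligand — including linker
residues not covered by any domain — until it matches the poses:

1. the full ligand is rigidly superposed onto the union of the domain poses
   (once, at iteration 0);
2. each iteration recomputes ANM/RTB normal modes on the *current* ligand
   coordinates, projects the displacement from ligand atoms to their pose
   counterparts into the 20-mode subspace, and applies the reconstructed
   step scaled so no atom moves more than a small amplitude (0.5 Å default);
3. a short restraint minimization (bonds, angles, clashes — no long-range
   terms) repairs stereochemistry; the receptor joins the minimization on a
   sparse schedule (every 10th iteration after the 100th by default);
4. the loop ends at the iteration cap, the wall-clock budget, or when the
   RMSD to the domain poses stops improving.

Atoms outside the domains carry no projection target but still move, through
the modes (each mode has a component for every atom) and the minimizer, which
is what lets the linker follow the hinge.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial import cKDTree

from .elastic_modes import (
    ElasticNetwork,
    RTBBlocks,
    compute_modes,
    project_displacement,
)
from .geometry_metrics import MetricError, Superposition, kabsch
from .structure_io import DomainDefinition, Structure, extract_domain

BOND_DETECT_CUTOFF = 1.8  # Å: heavy-atom pairs closer than this are bonded
CLASH_DMIN = 2.8  # Å minimum nonbonded heavy-atom separation
HBOND_MAX = 3.5  # Å: N···O pairs below this (≥3 residues apart) are H-bonded
K_BOND = 100.0
K_ANGLE = 20.0
K_CLASH = 50.0
K_HBOND = 10.0  # weak tether preserving secondary-structure H-bonds


class FittingError(RuntimeError):
    """Raised for unusable poses or non-finite geometry during fitting."""


# ---------------------------------------------------------------------------
# domain poses


@dataclass
class DomainPose:
    """A rigid placement of one extracted ligand domain in the receptor frame.

    ``atom_map[i]`` is the index (file order) in the *unbound ligand* of the
    domain's i-th atom; it must be injective and cover every domain atom.
    """

    domain_id: str
    coords: np.ndarray
    atom_map: np.ndarray
    shape_score: float | None = None
    external_potentials: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_map = np.asarray(self.atom_map, dtype=int)
        if self.coords.shape != (len(self.atom_map), 3):
            raise FittingError(
                f"pose {self.domain_id!r}: {self.coords.shape} coords vs "
                f"{len(self.atom_map)} mapped atoms"
            )
        if len(np.unique(self.atom_map)) != len(self.atom_map):
            raise FittingError(f"pose {self.domain_id!r}: atom_map not injective")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_map)


def pose_from_structure(
    domain: Structure, atom_index_map: dict[int, int], domain_id: str | None = None,
    shape_score: float | None = None,
    external_potentials: dict[str, float] | None = None,
) -> DomainPose:
    """Build a pose from a placed domain structure plus the atom-index map
    produced by :func:`modefit.structure_io.extract_domain`."""
    order = sorted(atom_index_map)
    return DomainPose(
        domain_id=domain_id or domain.label,
        coords=domain.coords()[order],
        atom_map=np.array([atom_index_map[i] for i in order]),
        shape_score=shape_score,
        external_potentials=external_potentials or {},
    )


# ---------------------------------------------------------------------------
# configuration and state


@dataclass
class FittingConfig:
    """Knobs of the fitting loop; defaults follow the published schedule."""

    max_iterations: int = 500
    wall_clock_budget: float = 14400.0  # seconds
    n_modes: int = 20
    anm_cutoff: float = 15.0
    step_max_displacement: float = 0.5  # Å max per-atom move per iteration
    minimizer_steps_per_iteration: int = 50
    receptor_min_start_iteration: int = 100
    receptor_min_period: int = 10
    convergence_tol: float = 0.01  # Å improvement over the convergence window
    convergence_window: int = 20
    mode_recompute_stride: int = 1
    trajectory_stride: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations <= 0 or self.receptor_min_period < 1:
            raise ValueError("iteration counts must be positive")
        if self.step_max_displacement <= 0 or self.anm_cutoff <= 0:
            raise ValueError("step cap and ANM cutoff must be positive")


@dataclass
class FittingState:
    """Evolving ligand coordinates plus iteration bookkeeping."""

    ligand_coords: np.ndarray
    iteration: int = 0
    trajectory: list[np.ndarray] = dc_field(default_factory=list)
    rmsd_to_domains: list[float] = dc_field(default_factory=list)
    termination: str = "running"
    no_op_steps: int = 0


# ---------------------------------------------------------------------------
# restraint field


@dataclass
class RestraintField:
    """Bond/angle/clash restraints referenced to the input geometry.

    The bond list carries per-term force constants so it can hold, besides
    covalent bonds, two classes of virtual bonds that a backbone-only model
    needs to stay protein-like: a CA(i)–CA(i+1) tether standing in for
    peptide-plane (ω) rigidity, and weak N···O tethers preserving the
    secondary-structure hydrogen-bond network of the input conformation.
    """

    bonds: np.ndarray  # (nb, 2) atom indices
    bond_refs: np.ndarray  # (nb,) Å
    bond_k: np.ndarray  # (nb,) per-term force constants
    angles: np.ndarray  # (na, 3) atom indices, vertex in the middle
    angle_refs: np.ndarray  # (na,) radians
    excluded: set[tuple[int, int]]  # pairs exempt from the clash term, i<j
    clash_dmin: float = CLASH_DMIN


def build_restraint_field(
    source: "Structure | np.ndarray", clash_dmin: float = CLASH_DMIN
) -> RestraintField:
    """Derive bonds (heavy-atom pairs < 1.8 Å), angles (bonded triples), the
    clash exclusion list, and — when a :class:`Structure` is given — peptide
    CA–CA tethers and N···O hydrogen-bond tethers, all referenced to the
    input conformation.  A bare coordinate array yields bonds/angles/clashes
    only.
    """
    if isinstance(source, Structure):
        coords = source.coords()
        atom_names: list[str] | None = []
        res_index: list[int] = []
        for i, res in enumerate(source.residues()):
            for a in res.atoms:
                atom_names.append(a.name)
                res_index.append(i)
    else:
        coords = np.asarray(source, dtype=float)
        atom_names = None
        res_index = []
    n = len(coords)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=BOND_DETECT_CUTOFF, output_type="ndarray")
    if len(pairs) == 0:
        bonds = np.zeros((0, 2), dtype=int)
        refs = np.zeros(0)
    else:
        bonds = np.sort(pairs, axis=1)
        refs = np.linalg.norm(coords[bonds[:, 0]] - coords[bonds[:, 1]], axis=1)
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    angles = []
    for b in range(n):
        nb = sorted(neighbors[b])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                angles.append((nb[x], b, nb[y]))
    angles_arr = np.asarray(angles, dtype=int).reshape(-1, 3)
    if len(angles_arr):
        u = coords[angles_arr[:, 0]] - coords[angles_arr[:, 1]]
        v = coords[angles_arr[:, 2]] - coords[angles_arr[:, 1]]
        cosang = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        angle_refs = np.arccos(np.clip(cosang, -1.0, 1.0))
    else:
        angle_refs = np.zeros(0)
    ks = [np.full(len(bonds), K_BOND)]
    all_bonds = [bonds]
    all_refs = [refs]
    if atom_names is not None:
        ridx = np.asarray(res_index, dtype=int)
        names = np.asarray(atom_names)
        # peptide-plane tether: consecutive-residue CA pairs
        ca = np.nonzero(names == "CA")[0]
        ca_pairs = [
            (int(a), int(b))
            for a, b in zip(ca[:-1], ca[1:])
            if ridx[b] == ridx[a] + 1
            and np.linalg.norm(coords[a] - coords[b]) < 4.2
        ]
        if ca_pairs:
            arr = np.asarray(ca_pairs, dtype=int)
            all_bonds.append(arr)
            all_refs.append(np.linalg.norm(coords[arr[:, 0]] - coords[arr[:, 1]], axis=1))
            ks.append(np.full(len(arr), K_BOND))
        # hydrogen-bond tethers: N···O pairs ≥3 residues apart within 3.5 Å
        n_idx = np.nonzero(names == "N")[0]
        o_idx = np.nonzero((names == "O") | (names == "OXT"))[0]
        hb = []
        if len(n_idx) and len(o_idx):
            otree = cKDTree(coords[o_idx])
            for a in n_idx:
                for jo in otree.query_ball_point(coords[a], r=HBOND_MAX):
                    b = int(o_idx[jo])
                    if abs(int(ridx[a]) - int(ridx[b])) >= 3:
                        hb.append((min(int(a), b), max(int(a), b)))
        if hb:
            arr = np.asarray(sorted(set(hb)), dtype=int)
            all_bonds.append(arr)
            all_refs.append(np.linalg.norm(coords[arr[:, 0]] - coords[arr[:, 1]], axis=1))
            ks.append(np.full(len(arr), K_HBOND))
    bonds_all = np.vstack([b.reshape(-1, 2) for b in all_bonds])
    excluded: set[tuple[int, int]] = set(map(tuple, bonds_all))
    for a, _, c in angles_arr:
        excluded.add((min(a, c), max(a, c)))
    # pairs already inside the clash distance at reference are grandfathered,
    # so the input conformation is exactly stationary
    for i, j in tree.query_pairs(r=clash_dmin, output_type="ndarray"):
        excluded.add((min(int(i), int(j)), max(int(i), int(j))))
    return RestraintField(
        bonds=bonds_all,
        bond_refs=np.concatenate(all_refs),
        bond_k=np.concatenate(ks),
        angles=angles_arr,
        angle_refs=angle_refs,
        excluded=excluded,
        clash_dmin=clash_dmin,
    )


def _clash_pairs(
    coords: np.ndarray, excluded: set[tuple[int, int]], dmin: float,
    context: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nonbonded pairs currently within dmin (internal) and mobile-vs-context
    pairs within dmin.  Returns (internal (k,2), context (m,2)) index arrays;
    context indices are (mobile_atom, context_atom)."""
    tree = cKDTree(coords)
    raw = tree.query_pairs(r=dmin, output_type="ndarray")
    if len(raw):
        raw = np.sort(raw, axis=1)
        mask = np.array([(i, j) not in excluded for i, j in raw])
        internal = raw[mask] if mask.any() else np.zeros((0, 2), dtype=int)
    else:
        internal = np.zeros((0, 2), dtype=int)
    if context is not None and len(context):
        ctree = cKDTree(context)
        hits = tree.query_ball_tree(ctree, r=dmin)
        cross = [(i, j) for i, js in enumerate(hits) for j in js]
        cross_arr = np.asarray(cross, dtype=int).reshape(-1, 2)
    else:
        cross_arr = np.zeros((0, 2), dtype=int)
    return internal, cross_arr


def _energy_and_grad(
    x: np.ndarray,
    field: RestraintField,
    internal_clash: np.ndarray,
    cross_clash: np.ndarray,
    context: np.ndarray | None,
) -> tuple[float, np.ndarray]:
    coords = x.reshape(-1, 3)
    grad = np.zeros_like(coords)
    energy = 0.0
    if len(field.bonds):
        i, j = field.bonds[:, 0], field.bonds[:, 1]
        d = coords[i] - coords[j]
        dist = np.linalg.norm(d, axis=1)
        dev = dist - field.bond_refs
        energy += float(np.sum(field.bond_k * dev**2))
        g = (2.0 * field.bond_k * dev / np.maximum(dist, 1e-12))[:, None] * d
        np.add.at(grad, i, g)
        np.add.at(grad, j, -g)
    if len(field.angles):
        a, b, c = field.angles[:, 0], field.angles[:, 1], field.angles[:, 2]
        u = coords[a] - coords[b]
        v = coords[c] - coords[b]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        h = np.sum(u * v, axis=1) / np.maximum(nu * nv, 1e-12)
        h = np.clip(h, -1.0 + 1e-9, 1.0 - 1e-9)
        theta = np.arccos(h)
        sin_t = np.sqrt(1.0 - h**2)
        dev = theta - field.angle_refs
        energy += K_ANGLE * float(np.sum(dev**2))
        pref = 2.0 * K_ANGLE * dev / np.maximum(sin_t, 1e-9)
        dth_da = (h[:, None] * u / nu[:, None] - v / nv[:, None]) / nu[:, None]
        dth_dc = (h[:, None] * v / nv[:, None] - u / nu[:, None]) / nv[:, None]
        ga = pref[:, None] * dth_da
        gc = pref[:, None] * dth_dc
        np.add.at(grad, a, ga)
        np.add.at(grad, c, gc)
        np.add.at(grad, b, -(ga + gc))
    dmin = field.clash_dmin
    if len(internal_clash):
        i, j = internal_clash[:, 0], internal_clash[:, 1]
        d = coords[i] - coords[j]
        dist = np.linalg.norm(d, axis=1)
        pen = np.maximum(0.0, dmin - dist)
        energy += K_CLASH * float(np.sum(pen**2))
        g = (-2.0 * K_CLASH * pen / np.maximum(dist, 1e-12))[:, None] * d
        np.add.at(grad, i, g)
        np.add.at(grad, j, -g)
    if len(cross_clash) and context is not None:
        i, j = cross_clash[:, 0], cross_clash[:, 1]
        d = coords[i] - context[j]
        dist = np.linalg.norm(d, axis=1)
        pen = np.maximum(0.0, dmin - dist)
        energy += K_CLASH * float(np.sum(pen**2))
        g = (-2.0 * K_CLASH * pen / np.maximum(dist, 1e-12))[:, None] * d
        np.add.at(grad, i, g)
    if not np.isfinite(energy):
        raise FittingError("non-finite restraint energy")
    return energy, grad.ravel()


def restraint_energy(coords: np.ndarray, field: RestraintField,
                     context: np.ndarray | None = None) -> float:
    """Current restraint energy of a conformation (diagnostics)."""
    internal, cross = _clash_pairs(np.asarray(coords, float), field.excluded,
                                   field.clash_dmin, context)
    e, _ = _energy_and_grad(np.asarray(coords, float).ravel(), field,
                            internal, cross, context)
    return e


def minimize(
    coords: np.ndarray,
    field: RestraintField,
    steps: int = 50,
    context: np.ndarray | None = None,
) -> np.ndarray:
    """Short L-BFGS descent on the restraint energy.

    ``context`` holds immobile atoms that contribute clash terms only (the
    receptor during ligand-only iterations).  The clash pair list is frozen at
    entry — appropriate for the small per-iteration motions of the fitting
    loop.  Energy is non-increasing by construction of the line search.
    """
    coords = np.asarray(coords, dtype=float)
    internal, cross = _clash_pairs(coords, field.excluded, field.clash_dmin, context)
    e0, g0 = _energy_and_grad(coords.ravel(), field, internal, cross, context)
    if np.linalg.norm(g0) < 1e-6:
        return coords.copy()
    res = scipy_minimize(
        _energy_and_grad,
        coords.ravel(),
        args=(field, internal, cross, context),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": steps, "ftol": 1e-12, "gtol": 1e-10},
    )
    e1, _ = _energy_and_grad(res.x, field, internal, cross, context)
    if e1 > e0 + 1e-9:  # defensive; L-BFGS should never go uphill
        return coords.copy()
    return res.x.reshape(-1, 3)


# ---------------------------------------------------------------------------
# fitting primitives


def _stack_pose_targets(poses: list[DomainPose]) -> tuple[np.ndarray, np.ndarray]:
    idx = np.concatenate([p.atom_map for p in poses])
    target = np.vstack([p.coords for p in poses])
    if len(np.unique(idx)) != len(idx):
        raise FittingError("domain poses overlap on ligand atoms")
    return idx, target


def superimpose_to_domains(
    ligand: Structure, poses: list[DomainPose]
) -> tuple[Structure, Superposition]:
    """Apply the single rigid transform minimizing the ligand's RMSD to the
    union of the domain poses' mapped atoms."""
    idx, target = _stack_pose_targets(poses)
    coords = ligand.coords()
    if len(idx) < 3:
        raise FittingError("fewer than 3 mapped atoms across poses")
    try:
        sup = kabsch(coords[idx], target)
    except MetricError as exc:
        raise FittingError(str(exc)) from exc
    moved = ligand.copy()
    moved.set_coords(sup.apply(coords))
    return moved, sup


def target_displacement(
    coords: np.ndarray, poses: list[DomainPose]
) -> np.ndarray:
    """3n displacement from current ligand atoms to their pose counterparts;
    unmapped atoms (linker etc.) get zero components."""
    d = np.zeros_like(coords)
    idx, target = _stack_pose_targets(poses)
    d[idx] = target - coords[idx]
    return d.ravel()


def rmsd_to_domains(coords: np.ndarray, poses: list[DomainPose]) -> float:
    idx, target = _stack_pose_targets(poses)
    return float(np.sqrt(np.mean(np.sum((coords[idx] - target) ** 2, axis=1))))


def mode_step(
    coords: np.ndarray,
    modes,
    d: np.ndarray,
    step_max_displacement: float = 0.5,
) -> tuple[np.ndarray, bool]:
    """Move along the mode-subspace reconstruction of ``d``, rescaled so the
    largest per-atom move is at most the cap.  Returns (new coords, stepped)."""
    _, recon = project_displacement(modes, d)
    per_atom = np.linalg.norm(recon.reshape(-1, 3), axis=1)
    peak = float(per_atom.max()) if len(per_atom) else 0.0
    if peak < 1e-12:
        return coords.copy(), False
    scale = min(1.0, step_max_displacement / peak)
    return coords + scale * recon.reshape(-1, 3), True


def residue_blocks(s: Structure) -> RTBBlocks:
    """One RTB block per residue, in file order."""
    assignment = []
    for i, res in enumerate(s.residues()):
        assignment.extend([i] * len(res.atoms))
    return RTBBlocks(np.asarray(assignment, dtype=int))


# ---------------------------------------------------------------------------
# the fitting loop


def fit(
    ligand: Structure,
    poses: list[DomainPose],
    receptor: Structure | None,
    cfg: FittingConfig | None = None,
) -> tuple[Structure, FittingState]:
    """Iterative normal-mode fitting of the full unbound ligand to the poses.

    Returns the fitted ligand (receptor coordinates are held in the receptor
    structure, modified only on the sparse receptor-minimization schedule)
    and the :class:`FittingState` with the RMSD-to-domains history.
    """
    cfg = cfg or FittingConfig()
    t0 = time.monotonic()
    fitted, _ = superimpose_to_domains(ligand, poses)
    coords = fitted.coords()
    lig_field = build_restraint_field(ligand)
    blocks = residue_blocks(ligand)
    rec_coords = receptor.coords() if receptor is not None else None
    rec_field = build_restraint_field(receptor) if rec_coords is not None and len(rec_coords) else None

    state = FittingState(ligand_coords=coords)
    state.rmsd_to_domains.append(rmsd_to_domains(coords, poses))
    state.trajectory.append(coords.copy())
    modes = None
    for it in range(1, cfg.max_iterations + 1):
        state.iteration = it
        if time.monotonic() - t0 > cfg.wall_clock_budget:
            state.termination = "wall_clock_budget"
            break
        if modes is None or (it - 1) % cfg.mode_recompute_stride == 0:
            net = ElasticNetwork(coords, cutoff=cfg.anm_cutoff)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                modes = compute_modes(net, blocks, n_modes=cfg.n_modes)
        d = target_displacement(coords, poses)
        coords, stepped = mode_step(coords, modes, d, cfg.step_max_displacement)
        if not stepped:
            state.no_op_steps += 1
        minimize_receptor = (
            rec_coords is not None
            and it >= cfg.receptor_min_start_iteration
            and it % cfg.receptor_min_period == 0
        )
        if minimize_receptor:
            # macrocycle: ligand + receptor minimized jointly (receptor mobile),
            # cross clashes push the partners into steric complementarity
            n_lig = len(coords)
            joint = np.vstack([coords, rec_coords])
            jfield = _join_fields(lig_field, rec_field, n_lig, len(rec_coords))
            joint = minimize(joint, jfield, cfg.minimizer_steps_per_iteration)
            coords, rec_coords = joint[:n_lig], joint[n_lig:]
        else:
            # microcycle: the ligand is minimized alone — the receptor exerts
            # no force here, so the ligand can sweep through its volume while
            # closing (complementarity is restored on the macrocycle schedule)
            coords = minimize(coords, lig_field, cfg.minimizer_steps_per_iteration)
        state.ligand_coords = coords
        state.rmsd_to_domains.append(rmsd_to_domains(coords, poses))
        if it % cfg.trajectory_stride == 0:
            state.trajectory.append(coords.copy())
        w = cfg.convergence_window
        hist = state.rmsd_to_domains
        if len(hist) > w and hist[-1 - w] - hist[-1] < cfg.convergence_tol:
            state.termination = "converged"
            break
    else:
        state.termination = "max_iterations"
    if rec_coords is not None:
        # final polish: ligand-only minimization against the fixed receptor
        # clears residual interpenetration left by an early-converged run
        # (the receptor stays bit-identical unless its schedule fired)
        coords = minimize(
            coords, lig_field, cfg.minimizer_steps_per_iteration,
            context=rec_coords,
        )
        state.ligand_coords = coords
        state.rmsd_to_domains.append(rmsd_to_domains(coords, poses))
    out = ligand.copy()
    out.set_coords(coords)
    if receptor is not None and rec_coords is not None:
        receptor.set_coords(rec_coords)
    return out, state


def _join_fields(
    lig: RestraintField, rec: RestraintField | None, n_lig: int, n_rec: int
) -> RestraintField:
    """Concatenate ligand and receptor restraint fields with shifted indices."""
    if rec is None or n_rec == 0:
        return lig
    bonds = np.vstack([lig.bonds.reshape(-1, 2), rec.bonds.reshape(-1, 2) + n_lig])
    refs = np.concatenate([lig.bond_refs, rec.bond_refs])
    bond_k = np.concatenate([lig.bond_k, rec.bond_k])
    angles = np.vstack([lig.angles.reshape(-1, 3), rec.angles.reshape(-1, 3) + n_lig])
    arefs = np.concatenate([lig.angle_refs, rec.angle_refs])
    excluded = set(lig.excluded) | {(i + n_lig, j + n_lig) for i, j in rec.excluded}
    return RestraintField(
        bonds=bonds, bond_refs=refs, bond_k=bond_k, angles=angles,
        angle_refs=arefs, excluded=excluded, clash_dmin=lig.clash_dmin,
    )


def poses_from_bound(
    unbound_ligand: Structure,
    bound_ligand: Structure,
    domains: list[DomainDefinition],
) -> list[DomainPose]:
    """Domain poses taken from the bound conformation's own domain coordinates.

    Residues are matched between unbound and bound by (chain, number,
    insertion code); atoms by name.  Used for flex-fitting-to-native, the
    upper-bound diagnostic where the correct domain placements are known.
    """
    bound_res = {r.key: r for r in bound_ligand.residues()}
    poses = []
    for dom in domains:
        sub, amap = extract_domain(unbound_ligand, dom)
        coords, lig_idx = [], []
        flat = 0  # domain atom index in file order; amap[flat] indexes the ligand
        for res in sub.residues():
            match = bound_res.get(res.key)
            for atom in res.atoms:
                if match is not None:
                    batom = match.atom(atom.name)
                    if batom is not None:
                        coords.append(batom.pos)
                        lig_idx.append(amap[flat])
                flat += 1
        if len(coords) < 3:
            raise FittingError(
                f"domain {dom.domain_id!r}: fewer than 3 atoms matched in bound structure"
            )
        poses.append(
            DomainPose(
                domain_id=dom.domain_id,
                coords=np.asarray(coords),
                atom_map=np.asarray(lig_idx, dtype=int),
            )
        )
    return poses


def fit_to_native(
    unbound_ligand: Structure,
    bound_ligand: Structure,
    domains: list[DomainDefinition],
    receptor: Structure | None = None,
    cfg: FittingConfig | None = None,
) -> tuple[Structure, FittingState]:
    """Flexible fitting of the unbound ligand directly to the native bound
    domain positions (diagnostic upper bound for the fitting engine)."""
    poses = poses_from_bound(unbound_ligand, bound_ligand, domains)
    return fit(unbound_ligand, poses, receptor, cfg)
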