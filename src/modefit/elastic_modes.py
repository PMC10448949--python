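"""Anisotropic network model (ANM) normal modes with RTB reduction.

All heavy atoms are nodes of an elastic network: every pair within the
connectivity cutoff (15.0 Å by default) is joined by a harmonic spring whose
equilibrium length is the input inter-atomic distance,

    V = (γ/2) Σ_{|s⁰_ij| ≤ c} (s_ij − s⁰_ij)²,

with a uniform spring constant γ.  The Hessian of V at the input geometry
has, for each connected pair, the 3×3 off-diagonal super-element
−(γ/s⁰²)·d dᵀ (d the equilibrium difference vector) and diagonal
super-elements equal to minus the row sums, so rigid-body motions are in the
null space exactly.

Diagonalizing the full 3n×3n Hessian is wasteful for large molecules, so the
problem is projected onto rotations-and-translations-of-blocks (RTB): each
block (one residue, by default) contributes 6 orthonormalized rigid-body
degrees of freedom, the reduced 6b×6b matrix Pᵀ H P is diagonalized, and the
reduced eigenvectors are expanded back to full-atom space.  The 20 modes of
lowest nonzero eigenvalue span the deformation subspace used by the fitting
engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

DEFAULT_CUTOFF = 15.0  # Å connectivity cutoff
DEFAULT_N_MODES = 20
ZERO_TOL_FACTOR = 1e-6  # λ below this × max(λ) is rigid-body


class ElasticNetworkError(ValueError):
    """Raised for singular geometry or disconnected networks."""


@dataclass(frozen=True)
class ElasticNetwork:
    """Atom coordinates plus spring cutoff and uniform spring constant."""

    coords: np.ndarray
    cutoff: float = DEFAULT_CUTOFF
    gamma: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) < 2:
            raise ElasticNetworkError(f"need an (n≥2)×3 coordinate array, got {self.coords.shape}")
        if self.cutoff <= 0:
            raise ElasticNetworkError("cutoff must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class RTBBlocks:
    """Per-atom block assignment (typically one block per residue)."""

    assignment: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", a)
        if a.ndim != 1 or len(a) == 0:
            raise ElasticNetworkError("block assignment must be a non-empty 1-D array")

    @property
    def n_blocks(self) -> int:
        return int(self.assignment.max()) + 1


@dataclass
class ModeSet:
    """Orthonormal full-atom normal modes with ascending nonzero eigenvalues."""

    eigenvalues: np.ndarray
    modes: np.ndarray  # (3n, k), columns orthonormal
    n_atoms: int

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]


def _spring_pairs(net: ElasticNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i<j) within the cutoff and their distances."""
    tree = cKDTree(net.coords)
    pairs = tree.query_pairs(r=net.cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2), np.zeros(0)
    d = net.coords[pairs[:, 0]] - net.coords[pairs[:, 1]]
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist < 1e-6):
        raise ElasticNetworkError("coincident atoms in elastic network")
    return pairs, dist


def build_hessian(net: ElasticNetwork) -> np.ndarray:
    """Dense symmetric 3n×3n ANM Hessian of the harmonic network potential."""
    n = net.n_atoms
    pairs, dist = _spring_pairs(net)
    H = np.zeros((3 * n, 3 * n))
    if len(pairs) == 0:
        return H
    diff = net.coords[pairs[:, 0]] - net.coords[pairs[:, 1]]
    # per-pair 3×3 super-element  (γ/s⁰²)·d dᵀ
    blocks = (net.gamma / dist[:, None, None] ** 2) * (
        diff[:, :, None] * diff[:, None, :]
    )
    for (i, j), B in zip(pairs, blocks):
        H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= B
        H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= B
        H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += B
        H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += B
    return H


def network_components(net: ElasticNetwork) -> np.ndarray:
    """Connected-component label per atom under the spring cutoff."""
    pairs, _ = _spring_pairs(net)
    n = net.n_atoms
    data = np.ones(len(pairs))
    adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def rtb_projection(blocks: RTBBlocks, coords: np.ndarray) -> np.ndarray:
    """Orthonormal projection operator P (3n × ≤6b) onto block rigid motions.

    Each block contributes 3 translations plus up to 3 rotations about its
    centroid; the six vectors are orthonormalized per block.  Blocks whose
    rotational vectors are degenerate (single atoms, collinear atoms) fall
    back to fewer columns.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if len(blocks.assignment) != n:
        raise ElasticNetworkError("block assignment length does not match atom count")
    cols: list[np.ndarray] = []
    for b in range(blocks.n_blocks):
        idx = np.nonzero(blocks.assignment == b)[0]
        if len(idx) == 0:
            raise ElasticNetworkError(f"block {b} has no atoms")
        centroid = coords[idx].mean(axis=0)
        rel = coords[idx] - centroid
        raw = np.zeros((3 * n, 6))
        for k in range(3):  # translations
            raw[3 * idx + k, k] = 1.0
        for k, axis in enumerate(np.eye(3)):  # rotations about the centroid
            disp = np.cross(axis, rel)
            for m in range(3):
                raw[3 * idx + m, 3 + k] = disp[:, m]
        # orthonormalize within the block; drop degenerate rotational columns
        Q, R = np.linalg.qr(raw)
        keep = np.abs(np.diag(R)) > 1e-8
        cols.append(Q[:, keep])
    P = np.hstack(cols)
    return P


def rtb_reduce(
    H: np.ndarray, blocks: RTBBlocks, coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project the full Hessian onto block rigid-body space.

    Returns ``(reduced, P)`` with ``reduced = Pᵀ H P`` of size ≤6b×≤6b and
    ``P`` the orthonormal expansion operator back to full-atom space.
    """
    P = rtb_projection(blocks, coords)
    reduced = P.T @ H @ P
    return 0.5 * (reduced + reduced.T), P


def compute_modes(
    net: ElasticNetwork,
    blocks: RTBBlocks | None = None,
    n_modes: int = DEFAULT_N_MODES,
    zero_tol_factor: float = ZERO_TOL_FACTOR,
) -> ModeSet:
    """Lowest nonzero normal modes of the elastic network.

    The reduced RTB matrix is diagonalized densely, near-zero (rigid-body)
    eigenvalues are discarded, eigenvectors are expanded to full-atom space
    through P and re-orthonormalized.  With ``blocks=None`` every atom is its
    own block, i.e. the unreduced ANM.  Requires a connected network; the
    sign of each mode is fixed so its first nonzero component is positive.
    """
    labels = network_components(net)
    n_comp = labels.max() + 1
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ElasticNetworkError(
            f"elastic network is disconnected under cutoff {net.cutoff} Å: "
            f"{n_comp} components with sizes {sizes.tolist()}"
        )
    H = build_hessian(net)
    if blocks is None:
        blocks = RTBBlocks(np.arange(net.n_atoms))
    reduced, P = rtb_reduce(H, blocks, net.coords)
    evals, evecs = np.linalg.eigh(reduced)
    tol = max(zero_tol_factor * float(evals.max()), 1e-12)
    nonzero = evals > tol
    evals, evecs = evals[nonzero], evecs[:, nonzero]
    if len(evals) < n_modes:
        warnings.warn(
            f"only {len(evals)} nonzero modes available (requested {n_modes})",
            stacklevel=2,
        )
    k = min(n_modes, len(evals))
    evals, evecs = evals[:k], evecs[:, :k]
    full = P @ evecs
    # re-orthonormalize in full space (P is orthonormal, but guard numerics)
    Q, _ = np.linalg.qr(full)
    modes = Q[:, :k]
    # fix sign: first component of significant magnitude positive
    for j in range(k):
        col = modes[:, j]
        nz = np.nonzero(np.abs(col) > 1e-10)[0]
        if len(nz) and col[nz[0]] < 0:
            modes[:, j] = -col
    return ModeSet(eigenvalues=evals, modes=modes, n_atoms=net.n_atoms)


def project_displacement(ms: ModeSet, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project a 3n displacement onto the mode subspace.

    Returns ``(coefficients, reconstruction)`` with coefficient
    c_k = ⟨mode_k, d⟩ and reconstruction Σ c_k mode_k; the residual
    d − reconstruction is orthogonal to every mode.
    """
    d = np.asarray(d, dtype=float).ravel()
    if d.shape[0] != 3 * ms.n_atoms:
        raise ElasticNetworkError(
            f"displacement length {d.shape[0]} != 3×{ms.n_atoms}"
        )
    c = ms.modes.T @ d
    recon = ms.modes @ c
    return c, recon
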