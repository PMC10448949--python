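"""Pose-pool management and the consensus scoring function.

A pool of docked poses for one domain (or of full complex models) is scored
by a logistic combination of:

* the rigid-docking **shape score** (carried in from the docking stage);
* the **cluster size** after greedy 4.0 Å RMSD clustering of the pool;
* optional external knowledge-based potentials (e.g. GOAP / DFIRE /
  ITScorePro), accepted as named per-pose numbers;
* six **binding-site consensus** (BSC) terms: for each residue the occupancy
  — how many poses in the whole pool have that residue interacting under a
  cutoff y — is summed over the residues interacting in the specific model,
  for y ∈ {5.0, 10.0} Å and sides x ∈ {receptor, ligand, both};
* three **order statistics**: the first, second and third lowest z-scores
  among the model's standardized feature values, which highlight models
  strongly favored by any single term.

All features are z-standardized over the pool (population sd; sd = 0 maps to
z = 0) before entering the logistic model, so the combined score is invariant
to raw feature rescaling.  The published pipeline does not ship coefficients,
so the scoring model is either loaded from a small YAML file or trained by
regularized logistic regression on labeled decoys.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .structure_io import Structure

BSC_CUTOFFS = (5.0, 10.0)
BSC_SIDES = ("receptor", "ligand", "both")
CLUSTER_CUTOFF = 4.0  # Å ligand-pose RMSD, fixed receptor frame
TRUNCATE_N = 50_000
ORDER_STAT_NAMES = ("z1", "z2", "z3")


class ScoringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pose pools


@dataclass
class ScoredPose:
    """One pool member: coordinates in the fixed receptor frame plus features."""

    pose_id: str
    coords: np.ndarray  # (m, 3) ligand/domain atoms, receptor frame
    features: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


@dataclass
class PosePool:
    poses: list[ScoredPose]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.poses)

    def feature_frame(self) -> pd.DataFrame:
        rows = [p.features for p in self.poses]
        df = pd.DataFrame(rows, index=[p.pose_id for p in self.poses])
        return df


@dataclass
class Cluster:
    representative: ScoredPose
    members: list[ScoredPose]

    @property
    def size(self) -> int:
        return len(self.members)


def truncate_by_shape(pool: PosePool, n: int = TRUNCATE_N) -> PosePool:
    """Top ``n`` poses by descending shape score; ties keep input order."""
    for p in pool.poses:
        if "shape_score" not in p.features:
            raise ScoringError(f"pose {p.pose_id!r} has no shape_score")
    order = sorted(
        range(len(pool.poses)),
        key=lambda i: (-pool.poses[i].features["shape_score"], i),
    )
    keep = sorted(order[:n])  # stable: retain input order among the survivors
    return PosePool(poses=[pool.poses[i] for i in keep], provenance=pool.provenance)


def pose_rmsd(a: ScoredPose, b: ScoredPose) -> float:
    """RMSD between two poses in the fixed receptor frame (no re-superposition,
    the standard docking-cluster convention)."""
    if a.coords.shape != b.coords.shape:
        raise ScoringError(
            f"poses {a.pose_id!r}/{b.pose_id!r} have different atom sets"
        )
    return float(np.sqrt(np.mean(np.sum((a.coords - b.coords) ** 2, axis=1))))


def cluster_poses(pool: PosePool, cutoff: float = CLUSTER_CUTOFF) -> list[Cluster]:
    """Greedy clustering in pool order: each pose joins the first cluster whose
    representative is within ``cutoff``, else founds a new cluster."""
    clusters: list[Cluster] = []
    for pose in pool.poses:
        for cl in clusters:
            if pose_rmsd(pose, cl.representative) <= cutoff:
                cl.members.append(pose)
                break
        else:
            clusters.append(Cluster(representative=pose, members=[pose]))
    return clusters


def attach_cluster_sizes(pool: PosePool, clusters: list[Cluster]) -> None:
    """Record each pose's cluster size as a feature."""
    size_of: dict[int, int] = {}
    for cl in clusters:
        for p in cl.members:
            size_of[id(p)] = cl.size
    for p in pool.poses:
        p.features["cluster_size"] = float(size_of[id(p)])


# ---------------------------------------------------------------------------
# binding-site consensus


def _interacting_residues(
    rec_xyz: np.ndarray, rec_res_idx: np.ndarray,
    lig_xyz: np.ndarray, lig_res_idx: np.ndarray,
    cutoff: float,
) -> tuple[set[int], set[int]]:
    """Residue indices (receptor-side, ligand-side) with ≥1 heavy atom within
    cutoff of the other subunit."""
    tree = cKDTree(rec_xyz)
    hits = tree.query_ball_point(lig_xyz, r=cutoff)
    rec_set: set[int] = set()
    lig_set: set[int] = set()
    for li, near in enumerate(hits):
        if near:
            lig_set.add(int(lig_res_idx[li]))
            rec_set.update(int(rec_res_idx[ai]) for ai in near)
    return rec_set, lig_set


@dataclass
class OccupancyTables:
    """Per-cutoff residue occupancy counts over an entire pose pool."""

    receptor: dict[float, np.ndarray]  # cutoff → per-residue counts
    ligand: dict[float, np.ndarray]
    n_poses: int


def _receptor_arrays(receptor: Structure) -> tuple[np.ndarray, np.ndarray, int]:
    xyz, idx = [], []
    n_res = 0
    for res in receptor.residues():
        for a in res.atoms:
            xyz.append(a.pos)
            idx.append(n_res)
        n_res += 1
    return np.asarray(xyz), np.asarray(idx, dtype=int), n_res


def occupancies(
    pool: PosePool,
    receptor: Structure,
    ligand_res_idx: np.ndarray,
    cutoffs: Sequence[float] = BSC_CUTOFFS,
) -> OccupancyTables:
    """Residue occupancies: for each residue, the number of poses in which it
    is interacting under each cutoff.  ``ligand_res_idx`` gives the residue
    index of each pose atom (all poses share the atom set)."""
    if not pool.poses:
        raise ScoringError("empty pose pool")
    rec_xyz, rec_idx, n_rec = _receptor_arrays(receptor)
    lig_res_idx = np.asarray(ligand_res_idx, dtype=int)
    n_lig = int(lig_res_idx.max()) + 1
    rec_tab = {c: np.zeros(n_rec, dtype=int) for c in cutoffs}
    lig_tab = {c: np.zeros(n_lig, dtype=int) for c in cutoffs}
    for pose in pool.poses:
        for c in cutoffs:
            rset, lset = _interacting_residues(
                rec_xyz, rec_idx, pose.coords, lig_res_idx, c
            )
            for r in rset:
                rec_tab[c][r] += 1
            for l in lset:
                lig_tab[c][l] += 1
    return OccupancyTables(receptor=rec_tab, ligand=lig_tab, n_poses=len(pool.poses))


def bsc_terms(
    pose: ScoredPose,
    receptor: Structure,
    ligand_res_idx: np.ndarray,
    occ: OccupancyTables,
) -> dict[str, float]:
    """The six BSC_{x,y} terms of one model against pool occupancy tables.

    BSC_{receptor,y} sums the receptor-side occupancies (at cutoff y) of the
    receptor residues interacting in this model under y; ligand likewise;
    both = receptor + ligand.
    """
    rec_xyz, rec_idx, _ = _receptor_arrays(receptor)
    lig_res_idx = np.asarray(ligand_res_idx, dtype=int)
    out: dict[str, float] = {}
    for c in BSC_CUTOFFS:
        rset, lset = _interacting_residues(rec_xyz, rec_idx, pose.coords, lig_res_idx, c)
        rec_sum = float(sum(occ.receptor[c][r] for r in rset))
        lig_sum = float(sum(occ.ligand[c][l] for l in lset))
        out[f"bsc_receptor_{c:g}"] = rec_sum
        out[f"bsc_ligand_{c:g}"] = lig_sum
        out[f"bsc_both_{c:g}"] = rec_sum + lig_sum
    return out


def attach_bsc_terms(
    pool: PosePool, receptor: Structure, ligand_res_idx: np.ndarray
) -> OccupancyTables:
    """Compute occupancy tables over the pool and attach all six BSC terms to
    every pose."""
    occ = occupancies(pool, receptor, ligand_res_idx)
    for pose in pool.poses:
        pose.features.update(bsc_terms(pose, receptor, ligand_res_idx, occ))
    return occ


# ---------------------------------------------------------------------------
# standardization, order statistics, logistic combination


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Population z-scores per feature column; zero-variance columns map to 0."""
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    z = (df - mean) / sd.replace(0.0, np.inf)
    return z.fillna(0.0)


def standardize_and_order_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize pool features and append the three lowest z-scores per
    pose as order-statistic columns z1 ≤ z2 ≤ z3."""
    if len(df) < 2:
        raise ScoringError("order statistics need a pool of at least 2 poses")
    z = standardize(df)
    sorted_z = np.sort(z.to_numpy(), axis=1)
    k = sorted_z.shape[1]
    for j, name in enumerate(ORDER_STAT_NAMES):
        z[name] = sorted_z[:, min(j, k - 1)]
    return z


@dataclass
class ScoringModel:
    """Logistic combination: sigmoid(intercept + w · z-features)."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_names):
            raise ScoringError(
                f"{len(self.weights)} weights for {len(self.feature_names)} features"
            )

    def save(self, path: str | Path) -> None:
        data = {
            "feature_names": list(self.feature_names),
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
        }
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def load(cls, path: str | Path) -> "ScoringModel":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            feature_names=tuple(data["feature_names"]),
            weights=np.asarray(data["weights"], dtype=float),
            intercept=float(data["intercept"]),
        )


def combined_score(z_features: pd.Series | dict, model: ScoringModel) -> float:
    """sigmoid(intercept + Σ w_i f_i) on standardized features."""
    try:
        x = np.array([float(z_features[name]) for name in model.feature_names])
    except KeyError as exc:
        raise ScoringError(f"feature manifest mismatch: missing {exc}") from exc
    t = model.intercept + float(model.weights @ x)
    return float(1.0 / (1.0 + np.exp(-t)))


def score_pool(pool: PosePool, model: ScoringModel) -> pd.DataFrame:
    """Standardize the pool's features, compute order statistics and the
    combined logistic score; returns the full feature table with a
    ``combined`` column and attaches the score to each pose."""
    raw = pool.feature_frame()
    missing = [f for f in model.feature_names
               if f not in raw.columns and f not in ORDER_STAT_NAMES]
    if missing:
        raise ScoringError(f"pool lacks features {missing}")
    z = standardize_and_order_stats(raw[[c for c in raw.columns]])
    z["combined"] = [combined_score(z.loc[pid], model) for pid in z.index]
    for pose, score in zip(pool.poses, z["combined"]):
        pose.features["combined"] = float(score)
    return z


def train_weights(
    z_features: pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    l2_strength: float = 1.0,
) -> ScoringModel:
    """Regularized maximum-likelihood logistic fit on standardized features.

    ``labels`` are binary model-quality labels (1 = acceptable).  Training is
    deterministic given the data (lbfgs, fixed tolerance) and invariant to
    row order.
    """
    from sklearn.linear_model import LogisticRegression

    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ScoringError("training labels contain a single class")
    X = z_features.to_numpy(dtype=float)
    clf = LogisticRegression(
        C=1.0 / l2_strength, solver="lbfgs", max_iter=2000, tol=1e-10,
    )
    clf.fit(X, y)
    return ScoringModel(
        feature_names=tuple(z_features.columns),
        weights=clf.coef_[0],
        intercept=float(clf.intercept_[0]),
    )


def select_top(pool: PosePool, n: int, key: str = "combined") -> PosePool:
    """Top ``n`` poses by descending score; ties keep input order."""
    order = sorted(
        range(len(pool.poses)), key=lambda i: (-pool.poses[i].features[key], i)
    )
    return PosePool(
        poses=[pool.poses[i] for i in sorted(order[:n])],
        provenance=pool.provenance,
    )


def carry_over_bsc(
    pose_a_features: dict[str, float],
    pose_b_features: dict[str, float],
    how: Literal["mean", "sum", "max"] = "mean",
) -> dict[str, float]:
    """Complex-level BSC features carried over from the two constituent domain
    poses rather than recomputed (mean by default; sum/max selectable)."""
    combine: Callable[[float, float], float] = {
        "mean": lambda a, b: 0.5 * (a + b),
        "sum": lambda a, b: a + b,
        "max": max,
    }[how]
    out = {}
    for c in BSC_CUTOFFS:
        for side in BSC_SIDES:
            key = f"bsc_{side}_{c:g}"
            out[key] = combine(pose_a_features[key], pose_b_features[key])
    return out


def read_scores_table(path: str | Path) -> pd.DataFrame:
    """External per-pose scores (TSV: pose_id, shape_score, goap, dfire, ...).

    Absent columns are simply not part of the manifest downstream.
    """
    df = pd.read_csv(path, sep="\t")
    if "pose_id" not in df.columns:
        raise ScoringError("scores table needs a pose_id column")
    return df.set_index("pose_id")
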