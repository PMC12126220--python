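"""Population-vector geometry: PCA trajectories and NT/CS+ separation.

Each group contributes a time x neurons matrix whose rows are the NT tone
bins followed by the CS+ tone bins (block-averaged z per neuron).  The
larger group is subsampled without replacement to match the smaller, the
two matrices are stacked along the time axis, and PCA is applied with time
bins as observations and neurons as features.  Trajectory separation is
quantified per bin by the Mahalanobis distance of each NT point to the
CS+ point cloud and by the instantaneous Euclidean distance in the first
K components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class PopulationMatrix:
    """Stacked group x stimulus time bins over matched neuron columns."""

    values: np.ndarray  # (n_segments * n_bins, n_matched_neurons)
    segments: list[tuple[str, str]]  # ordered (group, stimulus) per block of rows
    n_bins: int
    provenance: dict = field(default_factory=dict)

    def segment_rows(self, group: str, stimulus: str) -> slice:
        idx = self.segments.index((group, stimulus))
        return slice(idx * self.n_bins, (idx + 1) * self.n_bins)


@dataclass
class Trajectory:
    """Per-bin coordinates of one group x stimulus segment in PC space."""

    coords: np.ndarray  # (n_bins, k)
    group: str
    stimulus: str
    variance_explained: np.ndarray  # all components, non-increasing


def _group_matrix(z_nt: np.ndarray, z_cs: np.ndarray) -> np.ndarray:
    """Per-group (2*n_bins) x n_neurons matrix, rows NT bins then CS+ bins."""
    z_nt = np.asarray(z_nt, float)
    z_cs = np.asarray(z_cs, float)
    if z_nt.shape != z_cs.shape:
        raise ValueError("NT and CS+ traces must align per neuron")
    return np.vstack([z_nt.T, z_cs.T])  # time rows, neuron columns


def build_population_matrix(
    z_nt_a: np.ndarray,
    z_cs_a: np.ndarray,
    z_nt_b: np.ndarray,
    z_cs_b: np.ndarray,
    match_seed: int,
    group_names: tuple[str, str] = ("vehicle", "treated"),
) -> PopulationMatrix:
    """Stack two groups' NT/CS+ mean traces with size-matched neuron columns.

    Inputs are (n_neurons, n_bins) mean tone-period z traces per group.
    The group with more neurons is subsampled without replacement (seeded)
    to the size of the smaller; if the nominally larger second group is in
    fact smaller, the first group is subsampled instead, with a warning.
    """
    if len(z_nt_a) == 0 or len(z_nt_b) == 0:
        raise ValueError("both groups must be non-empty")
    mat_a = _group_matrix(z_nt_a, z_cs_a)
    mat_b = _group_matrix(z_nt_b, z_cs_b)
    n_a, n_b = mat_a.shape[1], mat_b.shape[1]
    rng = np.random.default_rng(match_seed)
    sel_a, sel_b = np.arange(n_a), np.arange(n_b)
    if n_b > n_a:
        sel_b = np.sort(rng.choice(n_b, size=n_a, replace=False))
    elif n_a > n_b:
        warnings.warn(
            f"group {group_names[1]} smaller than {group_names[0]}; "
            f"subsampling {group_names[0]} instead",
            stacklevel=2,
        )
        sel_a = np.sort(rng.choice(n_a, size=n_b, replace=False))
    n_bins = z_nt_a.shape[1]
    values = np.vstack([mat_a[:, sel_a], mat_b[:, sel_b]])
    segments = [
        (group_names[0], "NT"),
        (group_names[0], "CS_PLUS"),
        (group_names[1], "NT"),
        (group_names[1], "CS_PLUS"),
    ]
    return PopulationMatrix(
        values=values,
        segments=segments,
        n_bins=n_bins,
        provenance={
            "match_seed": match_seed,
            "selected_a": sel_a.tolist(),
            "selected_b": sel_b.tolist(),
            "n_matched": int(min(n_a, n_b)),
        },
    )


def pca_reduce(matrix: PopulationMatrix, k: int = 15) -> dict[tuple[str, str], Trajectory]:
    """PCA over time bins (observations) x neurons (features).

    Features are mean-centered; trajectories are the projections of each
    group x stimulus row segment onto the leading ``k`` components.
    Variance fractions are reported for every component.
    """
    x = matrix.values
    n_obs, n_feat = x.shape
    max_k = min(n_obs, n_feat)
    if not 1 <= k <= max_k:
        raise ValueError(f"k must lie in [1, {max_k}]")
    centered = x - x.mean(axis=0, keepdims=True)
    # economy SVD: components are right singular vectors
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / max(n_obs - 1, 1)
    total = var.sum()
    frac = var / total if total > 0 else var
    scores = centered @ vt.T  # (n_obs, max_k)
    out = {}
    for group, stim in matrix.segments:
        rows = matrix.segment_rows(group, stim)
        out[(group, stim)] = Trajectory(
            coords=scores[rows, :k],
            group=group,
            stimulus=stim,
            variance_explained=frac,
        )
    return out


def mahalanobis_separation(
    traj_a: Trajectory | np.ndarray,
    traj_b: Trajectory | np.ndarray,
    shrinkage: float = 1e-3,
    symmetric: bool = False,
) -> dict:
    """Per-bin Mahalanobis distance of trajectory A to trajectory B's cloud.

    The reference cloud's mean and covariance come from B's bins, with
    shrinkage regularisation sigma + lambda*tr(sigma)/K * I so that the
    covariance is invertible when the bin count barely exceeds (or falls
    below) the dimensionality.  ``symmetric=True`` averages the A-to-B and
    B-to-A distance series.
    """
    a = traj_a.coords if isinstance(traj_a, Trajectory) else np.asarray(traj_a, float)
    b = traj_b.coords if isinstance(traj_b, Trajectory) else np.asarray(traj_b, float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("trajectories must share the component basis")

    def one_way(points: np.ndarray, cloud: np.ndarray) -> np.ndarray:
        k = cloud.shape[1]
        mu = cloud.mean(axis=0)
        sigma = np.cov(cloud, rowvar=False, ddof=1).reshape(k, k)
        lam = shrinkage * np.trace(sigma) / k
        reg = sigma + lam * np.eye(k)
        try:
            chol = np.linalg.cholesky(reg)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "covariance singular after regularization"
            ) from e
        diff = points - mu
        y = np.linalg.solve(chol, diff.T)
        return np.sqrt((y**2).sum(axis=0))

    d = one_way(a, b)
    if symmetric:
        d = 0.5 * (d + one_way(b, a))
    return {"distances": d, "mean": float(d.mean()), "n_bins": len(d)}


def euclidean_trajectory_distance(
    traj_a: Trajectory | np.ndarray, traj_b: Trajectory | np.ndarray, k: int = 15
) -> np.ndarray:
    """Instantaneous Euclidean distance per bin over the first k components."""
    a = traj_a.coords if isinstance(traj_a, Trajectory) else np.asarray(traj_a, float)
    b = traj_b.coords if isinstance(traj_b, Trajectory) else np.asarray(traj_b, float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("trajectories must have equal bin counts")
    k = min(k, a.shape[1], b.shape[1])
    return np.linalg.norm(a[:, :k] - b[:, :k], axis=1)


def compare_separation(dist_a: np.ndarray, dist_b: np.ndarray) -> dict:
    """Two-sample t test between groups' per-bin distance vectors."""
    t, p = stats.ttest_ind(dist_a, dist_b)
    return {
        "t": float(t),
        "p_value": float(p),
        "df": len(dist_a) + len(dist_b) - 2,
        "mean_a": float(np.mean(dist_a)),
        "mean_b": float(np.mean(dist_b)),
    }
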