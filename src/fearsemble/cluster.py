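"""Clustergram-style hierarchical clustering of peri-tone responses.

Concatenated NT/CS+ z-traces are first rescaled through a saturating
linear map ([-5, 5] onto [-3, 3]) to stop very large excursions from
dominating the metric, then agglomerated with Ward linkage on Euclidean
distance.  Cutting the dendrogram at 5% of the maximum merge height gives
the reported clusters, whose mean profiles are remapped to the unscaled
z-traces so magnitudes stay interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .respond import ALL_TYPE_CODES


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy (n-1, 4) merge table
    assignments: pd.Series  # neuron_id -> cluster_id (1-based)
    cluster_profiles: pd.DataFrame  # cluster_id x time-bin mean unscaled z
    cut_height: float
    frac: float

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.nunique())


def rescale_bounded(
    x: np.ndarray,
    out_min: float = -3.0,
    out_max: float = 3.0,
    in_min: float = -5.0,
    in_max: float = 5.0,
) -> np.ndarray:
    """Saturating linear rescale; values beyond [in_min, in_max] clip."""
    if in_min >= in_max:
        raise ValueError("in_min must be < in_max")
    x = np.asarray(x, float)
    if not np.isfinite(x).all():
        raise ValueError("traces must be finite")
    clipped = np.clip(x, in_min, in_max)
    return out_min + (clipped - in_min) * (out_max - out_min) / (in_max - in_min)


def ward_cluster(rescaled: np.ndarray) -> np.ndarray:
    """Ward minimum-variance linkage with Euclidean metric.

    Rows are neurons (concatenated NT-then-CS+ traces).  Returns the
    standard 4-column merge table (left, right, height, size).
    """
    x = np.asarray(rescaled, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 neurons with equal-length traces")
    if np.isnan(x).any():
        raise ValueError("NaN in clustering input")
    return hierarchy.linkage(x, method="ward", metric="euclidean")


def cut_linkage(linkage: np.ndarray, frac: float = 0.05) -> np.ndarray:
    """Flat clusters after removing merges above frac x max merge height."""
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    height = frac * linkage[:, 2].max()
    return hierarchy.fcluster(linkage, t=height, criterion="distance")


def cut_and_remap(
    linkage: np.ndarray,
    rescaled: np.ndarray,
    unscaled_z: np.ndarray,
    frac: float = 0.05,
    neuron_ids: list[str] | None = None,
) -> ClusterResult:
    """Cut the tree and compute cluster mean profiles on the unscaled traces."""
    n = rescaled.shape[0]
    if unscaled_z.shape[0] != n:
        raise ValueError("rescaled and unscaled traces must cover the same neurons")
    labels = cut_linkage(linkage, frac)
    ids = neuron_ids or [f"n{i:04d}" for i in range(n)]
    assignments = pd.Series(labels, index=pd.Index(ids, name="neuron_id"), name="cluster_id")
    profiles = (
        pd.DataFrame(unscaled_z, index=assignments.values)
        .groupby(level=0)
        .mean()
        .rename_axis("cluster_id")
    )
    return ClusterResult(
        linkage=linkage,
        assignments=assignments,
        cluster_profiles=profiles,
        cut_height=float(frac * linkage[:, 2].max()),
        frac=frac,
    )


def cluster_report(
    result: ClusterResult, taxonomy: pd.DataFrame, segment_split: int | None = None
) -> pd.DataFrame:
    """Per-cluster composition over the 9 response types plus profile peaks.

    ``segment_split`` is the bin index where the CS+ segment begins in the
    concatenated profile (defaults to the midpoint).
    """
    tax = taxonomy.set_index("neuron_id")
    common = result.assignments.index.intersection(tax.index)
    if len(common) == 0:
        raise ValueError("taxonomy does not cover any clustered neuron")
    n_bins = result.cluster_profiles.shape[1]
    split = segment_split if segment_split is not None else n_bins // 2
    rows = []
    for cid, members in result.assignments.loc[common].groupby(
        result.assignments.loc[common]
    ):
        codes = tax.loc[members.index, "type_code"]
        profile = result.cluster_profiles.loc[cid].to_numpy()
        row = {"cluster_id": cid, "size": len(members)}
        for code in ALL_TYPE_CODES:
            row[code] = int((codes == code).sum())
        row["peak_nt"] = float(np.max(np.abs(profile[:split])))
        row["peak_cs"] = float(np.max(np.abs(profile[split:])))
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster_id")


def write_linkage(linkage: np.ndarray, path) -> None:
    """Merge table as text: columns left, right, height, size."""
    pd.DataFrame(linkage, columns=["left", "right", "height", "size"]).to_csv(
        path, index=False, float_format="%.10g"
    )
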