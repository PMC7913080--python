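"""Clone tracking by clustering variant-allele-frequency trajectories.

Mutations private to one clone share a VAF trajectory across serial samples
(diagnosis and relapses), so K-means over the M x T matrix of per-timepoint
VAFs partitions mutations into clone-like clusters. Clusters with the same
trajectory (centroid L-infinity distance below a threshold) are merged,
members far from their own centroid are pruned as outliers, and each final
cluster is labelled by its clonal dynamic:

- ``ancestral``: present at every timepoint (the founding clone),
- ``falling``: present at diagnosis, absent at the final timepoint,
- ``rising``: absent at diagnosis, present at the final timepoint,
- ``transient``: absent at both ends, present somewhere in between,
- ``other``: any remaining pattern.

"Present" means a centroid VAF at or above ``presence_threshold``.

The public face is :class:`VAFTrajectoryClustering`, an sklearn-style
estimator; the stage functions (:func:`kmeans_vaf`, :func:`merge_clusters`,
:func:`prune_outliers`, :func:`label_trajectory`) are usable standalone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .filtering import compute_vaf
from .io import SampleDescriptor, VariantRecord, tumor_samples

#: Label used for mutations pruned from every cluster.
OUTLIER = -1

TRAJECTORY_LABELS = ("ancestral", "falling", "rising", "transient", "other")


@dataclass
class VAFMatrix:
    """Mutations x ordered-timepoints matrix of variant allele frequencies."""

    mutation_ids: list[str]
    timepoint_labels: list[str]
    values: np.ndarray  # M x T in [0, 1]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mutation_ids), len(self.timepoint_labels)):
            raise ValueError("VAF matrix shape does not match ids/timepoints")
        if len(self.timepoint_labels) < 2:
            raise ValueError("need at least 2 tumor timepoints to track clones")


@dataclass
class ClusteringParams:
    """Tuning knobs of the trajectory-clustering stage.

    ``k_initial`` deliberately over-segments (the study used 10 and 15 for
    its two patients); the merge step then rejoins clusters with the same
    trajectory. Distances are L-infinity in VAF space, i.e. the maximum
    per-timepoint VAF discrepancy.
    """

    k_initial: int = 10
    merge_distance: float = 0.10
    outlier_distance: float = 0.20
    min_cluster_size: int = 50
    keep_small_clusters: bool = False
    presence_threshold: float = 0.05
    n_restarts: int = 25
    seed: int = 0


@dataclass
class ClusterSet:
    """A partition of mutations into trajectory clusters.

    ``labels`` holds one integer cluster id per mutation (``OUTLIER`` = -1
    for pruned mutations); centroids are member means in VAF space.
    """

    mutation_ids: list[str]
    timepoint_labels: list[str]
    labels: np.ndarray  # int, length M
    centroids: dict[int, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(self.labels.tolist()) - {OUTLIER}
        if present - set(self.centroids):
            raise ValueError("cluster label without a centroid")
        for cid in list(self.centroids):
            if cid not in present:  # drop empty clusters
                del self.centroids[cid]

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.centroids)

    @property
    def sizes(self) -> dict[int, int]:
        return {cid: int((self.labels == cid).sum()) for cid in self.cluster_ids}

    @property
    def n_outliers(self) -> int:
        return int((self.labels == OUTLIER).sum())

    def members(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cid)

    def trajectory_labels(self, presence_threshold: float = 0.05) -> dict[int, str]:
        return {
            cid: label_trajectory(c, presence_threshold)
            for cid, c in self.centroids.items()
        }

    def to_frame(self, vafs: VAFMatrix) -> pd.DataFrame:
        df = pd.DataFrame(
            vafs.values, columns=[f"VAF_{t}" for t in vafs.timepoint_labels]
        )
        df.insert(0, "mutation_id", vafs.mutation_ids)
        df.insert(1, "cluster", [
            "OUTLIER" if l == OUTLIER else str(l) for l in self.labels
        ])
        return df


def build_vaf_matrix(
    records: list[VariantRecord], sample_descriptors: list[SampleDescriptor]
) -> VAFMatrix:
    """VAF matrix over tumor samples only, ordered by timepoint index."""
    tumors = tumor_samples(sample_descriptors)
    if len(tumors) < 2:
        raise ValueError("need >= 2 tumor timepoints to build a VAF trajectory")
    values = np.array(
        [[compute_vaf(*rec.counts[s.name]) for s in tumors] for rec in records]
    ).reshape(len(records), len(tumors))
    return VAFMatrix(
        mutation_ids=[r.key for r in records],
        timepoint_labels=[s.timepoint_label or f"T{s.timepoint_index}" for s in tumors],
        values=values,
    )


def _recompute_centroids(X: np.ndarray, labels: np.ndarray) -> dict[int, np.ndarray]:
    return {
        int(cid): X[labels == cid].mean(axis=0)
        for cid in np.unique(labels)
        if cid != OUTLIER
    }


def kmeans_vaf(vafs: VAFMatrix, params: ClusteringParams) -> ClusterSet:
    """Initial K-means over-segmentation of the VAF matrix.

    Best of ``n_restarts`` by within-cluster sum of squares (Euclidean in raw
    VAF space), deterministic given the seed. Restart-empty clusters are
    dropped, so the resulting K may be below ``k_initial``.
    """
    X = vafs.values
    if not 1 <= params.k_initial <= X.shape[0]:
        raise ValueError(
            f"k_initial={params.k_initial} exceeds the {X.shape[0]} VAF rows; "
            f"choose a smaller K"
        )
    # over-clustering beyond the distinct trajectories is harmless intent
    # (the merge step rejoins); cap K so K-means stays well posed
    n_distinct = np.unique(X, axis=0).shape[0]
    effective_k = min(params.k_initial, n_distinct)
    km = KMeans(
        n_clusters=effective_k,
        n_init=params.n_restarts,
        random_state=params.seed,
        init="k-means++",
    ).fit(X)
    labels = km.labels_.astype(int)
    return ClusterSet(
        mutation_ids=vafs.mutation_ids,
        timepoint_labels=vafs.timepoint_labels,
        labels=labels,
        centroids=_recompute_centroids(X, labels),
        provenance={
            "k_initial": params.k_initial,
            "k_effective": effective_k,
            "n_restarts": params.n_restarts,
            "seed": params.seed,
            "inertia": float(km.inertia_),
        },
    )


def merge_clusters(
    clusterset: ClusterSet,
    vafs: VAFMatrix,
    params: ClusteringParams,
    manual_map: dict[int, int] | None = None,
) -> ClusterSet:
    """Merge clusters sharing an evolutionary trajectory.

    Automatic mode iteratively merges the pair of clusters with the smallest
    centroid L-infinity distance while that distance is below
    ``merge_distance``, recomputing the merged centroid as the member mean
    after every merge. A ``manual_map`` (old cluster id -> new label) instead
    replays curator decisions verbatim.
    """
    X = vafs.values
    labels = clusterset.labels.copy()
    merge_tree: list[tuple[int, int, float]] = []

    if manual_map is not None:
        unknown = set(manual_map) - set(clusterset.centroids)
        if unknown:
            raise ValueError(f"manual_map references unknown cluster(s) {sorted(unknown)}")
        for old, new in manual_map.items():
            labels[clusterset.labels == old] = new
    else:
        centroids = dict(clusterset.centroids)
        while len(centroids) > 1:
            ids = sorted(centroids)
            best, best_d = None, np.inf
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    d = float(np.abs(centroids[a] - centroids[b]).max())
                    if d < best_d:
                        best, best_d = (a, b), d
            if best_d >= params.merge_distance:
                break
            a, b = best
            labels[labels == b] = a
            centroids[a] = X[labels == a].mean(axis=0)
            del centroids[b]
            merge_tree.append((b, a, best_d))

    provenance = dict(clusterset.provenance)
    provenance["merge_tree"] = merge_tree
    provenance["merge_distance"] = params.merge_distance
    if manual_map is not None:
        provenance["manual_map"] = dict(manual_map)
    return ClusterSet(
        mutation_ids=clusterset.mutation_ids,
        timepoint_labels=clusterset.timepoint_labels,
        labels=labels,
        centroids=_recompute_centroids(X, labels),
        provenance=provenance,
    )


def prune_outliers(
    clusterset: ClusterSet, vafs: VAFMatrix, params: ClusteringParams
) -> ClusterSet:
    """Reassign to OUTLIER every mutation farther than ``outlier_distance``
    (L-infinity) from its own cluster centroid; recompute centroids once."""
    X = vafs.values
    labels = clusterset.labels.copy()
    for cid, centroid in clusterset.centroids.items():
        members = clusterset.members(cid)
        dist = np.abs(X[members] - centroid).max(axis=1)
        labels[members[dist > params.outlier_distance]] = OUTLIER
    provenance = dict(clusterset.provenance)
    provenance["outlier_distance"] = params.outlier_distance
    provenance["n_outliers"] = int((labels == OUTLIER).sum())
    return ClusterSet(
        mutation_ids=clusterset.mutation_ids,
        timepoint_labels=clusterset.timepoint_labels,
        labels=labels,
        centroids=_recompute_centroids(X, labels),
        provenance=provenance,
    )


def drop_small_clusters(
    clusterset: ClusterSet, vafs: VAFMatrix, params: ClusteringParams
) -> ClusterSet:
    """Dissolve clusters below ``min_cluster_size`` into OUTLIER, unless the
    configuration flags small clusters as biologically relevant and keeps
    them (``keep_small_clusters``)."""
    if params.keep_small_clusters:
        return clusterset
    labels = clusterset.labels.copy()
    for cid, size in clusterset.sizes.items():
        if size < params.min_cluster_size:
            labels[labels == cid] = OUTLIER
    return ClusterSet(
        mutation_ids=clusterset.mutation_ids,
        timepoint_labels=clusterset.timepoint_labels,
        labels=labels,
        centroids=_recompute_centroids(vafs.values, labels),
        provenance=dict(clusterset.provenance),
    )


def label_trajectory(centroid: np.ndarray, presence_threshold: float = 0.05) -> str:
    """Classify a centroid's clonal dynamic from per-timepoint presence."""
    centroid = np.asarray(centroid, dtype=float)
    if centroid.size < 2:
        raise ValueError("centroid needs >= 2 timepoints")
    present = centroid >= presence_threshold
    if present.all():
        return "ancestral"
    if present[0] and not present[-1]:
        return "falling"
    if not present[0] and present[-1]:
        return "rising"
    if not present[0] and not present[-1] and present.any():
        return "transient"
    return "other"


def estimate_purity(
    vafs: VAFMatrix, clusterset: ClusterSet, presence_threshold: float = 0.05
) -> dict[str, float]:
    """Per-timepoint tumor purity from the dominant cluster's VAFs.

    Under the diploid heterozygous model the expected VAF of a clonal
    mutation is purity/2, so purity_t = min(1, 2 * median member VAF at t of
    the largest cluster present at t). Timepoints with no present cluster
    get NaN. Purity is reported, never used to rescale the VAFs.
    """
    out: dict[str, float] = {}
    sizes = clusterset.sizes
    for t, label in enumerate(vafs.timepoint_labels):
        candidates = [
            cid for cid, c in clusterset.centroids.items()
            if c[t] >= presence_threshold
        ]
        if not candidates:
            out[label] = float("nan")
            continue
        cid = max(candidates, key=lambda c: sizes[c])
        med = float(np.median(vafs.values[clusterset.members(cid), t]))
        out[label] = min(1.0, 2.0 * med)
    return out


class VAFTrajectoryClustering(ClusterMixin, BaseEstimator):
    """Clone-tracking clustering of VAF trajectories, sklearn style.

    Runs K-means over-segmentation, trajectory merging, small-cluster
    handling and outlier pruning as one ``fit``. ``X`` is the M x T matrix
    of VAFs (mutations x ordered tumor timepoints).

    Parameters mirror :class:`ClusteringParams`. Fitted attributes:

    - ``labels_``: int array, cluster id per mutation (-1 = outlier);
    - ``cluster_centers_``: K x T array of centroids (row order =
      ``cluster_ids_``);
    - ``cluster_ids_``: original cluster ids, sorted;
    - ``trajectory_labels_``: dict cluster id -> dynamic label;
    - ``clusterset_``: the full :class:`ClusterSet` with provenance.
    """

    def __init__(
        self,
        k_initial: int = 10,
        merge_distance: float = 0.10,
        outlier_distance: float = 0.20,
        min_cluster_size: int = 50,
        keep_small_clusters: bool = False,
        presence_threshold: float = 0.05,
        n_restarts: int = 25,
        random_state: int = 0,
        manual_map: dict[int, int] | None = None,
    ):
        self.k_initial = k_initial
        self.merge_distance = merge_distance
        self.outlier_distance = outlier_distance
        self.min_cluster_size = min_cluster_size
        self.keep_small_clusters = keep_small_clusters
        self.presence_threshold = presence_threshold
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.manual_map = manual_map

    def _params(self) -> ClusteringParams:
        return ClusteringParams(
            k_initial=self.k_initial,
            merge_distance=self.merge_distance,
            outlier_distance=self.outlier_distance,
            min_cluster_size=self.min_cluster_size,
            keep_small_clusters=self.keep_small_clusters,
            presence_threshold=self.presence_threshold,
            n_restarts=self.n_restarts,
            seed=self.random_state,
        )

    def fit(self, X, y=None, timepoint_labels: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be M x T with T >= 2")
        if (X < 0).any() or (X > 1).any():
            raise ValueError("VAFs must lie in [0, 1]")
        tp = timepoint_labels or [f"T{i}" for i in range(X.shape[1])]
        vafs = VAFMatrix(
            mutation_ids=[str(i) for i in range(X.shape[0])],
            timepoint_labels=tp,
            values=X,
        )
        params = self._params()
        cs = kmeans_vaf(vafs, params)
        cs = merge_clusters(cs, vafs, params, manual_map=self.manual_map)
        cs = drop_small_clusters(cs, vafs, params)
        cs = prune_outliers(cs, vafs, params)
        self.clusterset_ = cs
        self.labels_ = cs.labels
        self.cluster_ids_ = cs.cluster_ids
        self.cluster_centers_ = np.array([cs.centroids[c] for c in cs.cluster_ids])
        self.trajectory_labels_ = cs.trajectory_labels(self.presence_threshold)
        self.n_clusters_ = len(cs.cluster_ids)
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, **kwargs).labels_
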