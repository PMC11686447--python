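"""PCA and k-means clustering of glycan profiles.

Glycan profiles (fractional abundances per glycoform, one row per sample)
are explored by centered PCA and partitioned by k-means; the number of
clusters is suggested by the elbow of the within-cluster sum of squares
(WCSS) curve, operationalised as the largest relative WCSS drop.  Each
cluster is then characterised by its dominant glycoforms — e.g. a
Man5-dominated versus a G0F-dominated cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ProfileMatrix",
    "ClusterAssignment",
    "pca_profiles",
    "kmeans_profiles",
    "elbow_curve",
    "choose_k",
    "characterize_clusters",
]


@dataclass
class ProfileMatrix:
    """Samples x glycan-species fractional abundance matrix.

    ``data`` rows are samples (index = sample id), columns glycan species;
    every row sums to 1.  ``metadata`` is an optional table aligned on the
    same index carrying project / sample / replicate annotations.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        arr = self.data.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("negative glycan fractions")
        sums = arr.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = self.data.index[np.abs(sums - 1.0) > 1e-6].tolist()
            raise ValueError(f"profile rows do not sum to 1: {bad[:5]}")
        if self.metadata is not None and not self.metadata.index.equals(self.data.index):
            raise ValueError("metadata index must match profile index")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def averaged_replicates(self, sample_col: str = "sample_id") -> "ProfileMatrix":
        """Average duplicate measurements of the same sample.

        Requires metadata with a ``sample_col`` column; rows sharing a
        sample id are replaced by their mean profile (re-normalized).
        """
        if self.metadata is None or sample_col not in self.metadata.columns:
            return self
        grouped = self.data.groupby(self.metadata[sample_col]).mean()
        grouped = grouped.div(grouped.sum(axis=1), axis=0)
        meta = (
            self.metadata.groupby(self.metadata[sample_col])
            .first()
            .loc[grouped.index]
        )
        return ProfileMatrix(data=grouped, metadata=meta)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample id -> cluster int in [0, k)
    k: int
    wcss: float
    centroids: pd.DataFrame  # k x species

    def __post_init__(self) -> None:
        lab = self.labels.to_numpy()
        if lab.min() < 0 or lab.max() >= self.k:
            raise ValueError("labels outside [0, k)")


def pca_profiles(
    matrix: ProfileMatrix, n_components: int | None = None, scale: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Centered (optionally unit-scaled) SVD-based PCA of glycan profiles.

    Returns (scores, loadings, variance_explained).  Loadings columns are
    the principal axes in glycan-species space; inspecting the large
    |loading| species shows which glycoforms drive the separation.
    """
    if matrix.n_samples < 2 or len(matrix.species) < 2:
        raise ValueError("need at least 2 samples and 2 species")
    x = matrix.data.to_numpy(dtype=float)
    if np.allclose(np.var(x, axis=0), 0.0):
        raise ValueError("degenerate (constant) profile matrix")
    if scale:
        sd = x.std(axis=0, ddof=0)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    max_comp = min(matrix.n_samples - 1, len(matrix.species))
    n_components = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.data.index, columns=cols),
        pd.DataFrame(pca.components_.T, index=matrix.species, columns=cols),
        pca.explained_variance_ratio_,
    )


def kmeans_profiles(
    matrix: ProfileMatrix,
    k: int,
    n_restarts: int = 10,
    seed: int | None = None,
    init: np.ndarray | str = "k-means++",
) -> ClusterAssignment:
    """k-means (Lloyd, k-means++ init, best of ``n_restarts`` by WCSS)."""
    if not 1 <= k <= matrix.n_samples:
        raise ValueError(f"k={k} outside [1, n_samples={matrix.n_samples}]")
    x = matrix.data.to_numpy(dtype=float)
    km = KMeans(
        n_clusters=k,
        init=init,
        n_init=n_restarts if isinstance(init, str) else 1,
        random_state=None if seed is None else seed % (2**32),
        algorithm="lloyd",
    ).fit(x)
    return ClusterAssignment(
        labels=pd.Series(km.labels_, index=matrix.data.index, name="cluster"),
        k=k,
        wcss=float(km.inertia_),
        centroids=pd.DataFrame(km.cluster_centers_, columns=matrix.species),
    )


def elbow_curve(
    matrix: ProfileMatrix, k_max: int, n_restarts: int = 10, seed: int | None = None
) -> list[tuple[int, float]]:
    """WCSS as a function of k, for k = 1..k_max.

    Each k is solved by restarted k-means; in addition the previous best
    centroid set (augmented with the worst-fit sample) warm-starts the
    next k, which enforces a non-increasing curve.
    """
    if k_max > matrix.n_samples:
        raise ValueError("k_max exceeds number of samples")
    x = matrix.data.to_numpy(dtype=float)
    curve: list[tuple[int, float]] = []
    prev: ClusterAssignment | None = None
    for k in range(1, k_max + 1):
        best = kmeans_profiles(matrix, k, n_restarts=n_restarts, seed=seed)
        if prev is not None:
            # warm start: previous centroids plus the worst-fitted point
            worst = np.argmax(
                np.sum((x - prev.centroids.to_numpy()[prev.labels.to_numpy()]) ** 2, axis=1)
            )
            warm_init = np.vstack([prev.centroids.to_numpy(), x[worst]])
            warm = kmeans_profiles(matrix, k, seed=seed, init=warm_init)
            if warm.wcss < best.wcss:
                best = warm
        curve.append((k, best.wcss))
        prev = best
    return curve


def choose_k(curve: list[tuple[int, float]]) -> int:
    """Elbow heuristic: k with the largest relative WCSS drop."""
    if len(curve) < 2:
        return curve[0][0]
    best_k, best_drop = curve[1][0], -np.inf
    for (k0, w0), (k1, w1) in zip(curve, curve[1:]):
        if w0 <= 0:
            continue
        drop = (w0 - w1) / w0
        if drop > best_drop:
            best_k, best_drop = k1, drop
    return best_k


def characterize_clusters(
    assignment: ClusterAssignment,
    matrix: ProfileMatrix,
    top_n: int = 3,
    difference_threshold: float = 0.02,
) -> pd.DataFrame:
    """Per-cluster dominant glycoforms and the most discriminating species.

    Returns one row per cluster with its size, centroid-dominant species
    (top ``top_n`` by centroid fraction), and the species whose centroid
    fraction deviates most from the mean of the other clusters (empty when
    no species exceeds ``difference_threshold`` — identical clusters).
    Empty clusters are flagged with size 0.
    """
    rows = []
    centroids = assignment.centroids
    for c in range(assignment.k):
        members = assignment.labels[assignment.labels == c].index
        centroid = centroids.iloc[c]
        dominant = centroid.sort_values(ascending=False).head(top_n)
        if assignment.k > 1:
            others = centroids.drop(index=c).mean(axis=0)
            diff = (centroid - others).abs()
            discriminating = (
                diff.idxmax() if diff.max() > difference_threshold else ""
            )
            max_difference = float(diff.max())
        else:
            discriminating, max_difference = "", 0.0
        rows.append(
            {
                "cluster": c,
                "n_samples": len(members),
                "dominant_species": list(dominant.index),
                "dominant_fractions": [round(float(v), 4) for v in dominant],
                "discriminating_species": discriminating,
                "max_centroid_difference": max_difference,
                "empty": len(members) == 0,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
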