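"""UMAP embedding and Leiden clustering of corrected antibody profiles.

The corrected residual matrix u is reduced by PCA (first 16 principal
components by default, or all), a k-nearest-neighbour graph is built on
the component scores (Euclidean metric, 15 neighbours by default), the
cells are embedded in two dimensions with UMAP (minimum distance 0.1 for
the pediatric-style analysis, 0.2 otherwise) and partitioned with the
Leiden algorithm (resolution 0.1 for the cell-line-style mixture, 1
otherwise). Seeds are mandatory; a fixed seed reproduces coordinates and
labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc

__all__ = ["EmbeddingResult", "ClusterAssignment", "embed", "cluster", "annotate"]


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # cells x (umap1, umap2)
    n_neighbors: int
    n_pcs: int
    min_dist: float
    seed: int
    adata: ad.AnnData  # carries the neighbour graph for reuse by cluster()


@dataclass
class ClusterAssignment:
    labels: pd.Series  # integer community label per cell, contiguous from 0
    resolution: float
    seed: int
    names: dict[int, str] | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def _prepare(u: pd.DataFrame, n_neighbors: int, n_pcs: int | str, seed: int):
    if n_neighbors < 2:
        raise ValueError("n_neighbors must be >= 2")
    if u.shape[0] <= n_neighbors:
        raise ValueError("fewer cells than n_neighbors")
    adata = ad.AnnData(u.to_numpy(dtype=np.float64))
    adata.obs_names = u.index.astype(str)
    adata.var_names = u.columns.astype(str)
    # arpack requires n_comps strictly below min(n_cells, n_antibodies)
    cap = min(u.shape[0], u.shape[1]) - 1
    if n_pcs == "all":
        k = cap
    else:
        k = min(int(n_pcs), cap)
    sc.pp.pca(adata, n_comps=k, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(
        adata, n_neighbors=n_neighbors, n_pcs=k, metric="euclidean",
        random_state=seed,
    )
    return adata, k


def embed(
    u: pd.DataFrame,
    n_neighbors: int = 15,
    n_pcs: int | str = 16,
    min_dist: float = 0.2,
    seed: int = 0,
) -> EmbeddingResult:
    """Two-dimensional UMAP embedding of the corrected antibody signal.

    Parameters
    ----------
    u
        Corrected antibody matrix (cells x antibodies).
    n_pcs
        Number of principal components for the neighbour graph, or
        ``"all"``.
    """
    adata, k = _prepare(u, n_neighbors, n_pcs, seed)
    sc.tl.umap(adata, min_dist=min_dist, random_state=seed)
    coords = pd.DataFrame(
        adata.obsm["X_umap"], index=u.index, columns=["umap1", "umap2"]
    )
    return EmbeddingResult(coords, n_neighbors, k, min_dist, seed, adata)


def cluster(
    u: pd.DataFrame | EmbeddingResult,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
    n_pcs: int | str = 16,
) -> ClusterAssignment:
    """Leiden community detection on the antibody nearest-neighbour graph.

    Accepts either the corrected matrix (graph built as in :func:`embed`)
    or an :class:`EmbeddingResult`, whose stored graph is reused so that
    embedding and clustering share identical neighbourhoods.
    """
    if isinstance(u, EmbeddingResult):
        adata = u.adata
        index = u.coordinates.index
    else:
        if u.shape[0] == 0:
            raise ValueError("empty input")
        adata, _ = _prepare(u, n_neighbors, n_pcs, seed)
        index = u.index
    import warnings

    with warnings.catch_warnings():
        # pinned to the leidenalg backend for stable RBConfiguration
        # behaviour across scanpy versions
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            key_added="leiden",
            flavor="leidenalg",
        )
    raw = adata.obs["leiden"].astype(int)
    # relabel to contiguous ids ordered by descending cluster size
    order = raw.value_counts().index
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series(
        [remap[v] for v in raw], index=index, name="cluster", dtype=int
    )
    return ClusterAssignment(labels, resolution, seed)


def annotate(
    cluster_means: pd.DataFrame,
    rules: dict[str, str],
) -> dict[int, str]:
    """Name clusters from marker-expression rules.

    Parameters
    ----------
    cluster_means
        Clusters x antibodies mean expression (corrected signal).
    rules
        Marker -> label map, e.g. ``{"CD3": "T cell"}``. Each cluster is
        named by the rule whose marker is most enriched in it (z-score of
        the cluster mean across clusters); clusters whose top rule marker
        is not enriched (z <= 0) keep their numeric label. When several
        clusters share a name they are suffixed with an index; when two
        rules tie exactly for a cluster both are reported and the cluster
        stays numeric.
    """
    if not rules:
        return {}
    markers = [m for m in rules if m in cluster_means.columns]
    if not markers:
        return {}
    sub = cluster_means[markers]
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0).replace(0, np.nan)
    names: dict[int, str] = {}
    for cl in cluster_means.index:
        scores = z.loc[cl].dropna()
        if scores.empty:
            continue
        best = scores.max()
        if best <= 0:
            continue
        winners = [m for m in scores.index if scores[m] == best]
        if len(winners) > 1:
            # conflicting rules: report both, keep numeric
            names[int(cl)] = "/".join(sorted(rules[m] for m in winners)) + "?"
            continue
        names[int(cl)] = rules[winners[0]]
    # disambiguate duplicates with suffix indices
    from collections import Counter

    tally = Counter(names.values())
    next_idx: dict[str, int] = {}
    for cl in sorted(names):
        n = names[cl]
        if tally[n] > 1:
            i = next_idx.get(n, 0)
            names[cl] = f"{n}_{i}"
            next_idx[n] = i + 1
    return names


def cluster_mean_expression(
    u: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Clusters x antibodies mean corrected expression (heatmap input)."""
    return u.groupby(labels).mean()
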