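"""Lineage inference, pseudotime and cell-type boundary construction.

Lineages are root-to-leaf paths of the minimum spanning tree over cluster
centroids in a reduced (PCA) space.  Per-cell pseudotime is the arc-length
position of the cell's orthogonal projection onto the piecewise-linear
centroid path of its lineage; cells whose cluster sits on several lineages
receive one pseudotime per lineage and weights proportional to inverse
squared distance to each lineage path.  Cell-type boundaries are symmetric
tail-trimmed pseudotime intervals covering a target fraction (default 78%)
of each cluster's lineage-assigned cells.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import networkx as nx
from scipy.spatial.distance import cdist

from .datatypes import CellCounts, TrajectorySet

log = logging.getLogger(__name__)


def compute_reduced_space(
    counts: CellCounts, n_components: int = 15, seed: int = 0
) -> np.ndarray:
    """Truncated PCA (default 15 components) of log1p-CPM expression."""
    from sklearn.decomposition import PCA

    X = counts.matrix.astype(float).T.tocsr()  # cells x genes
    libs = np.asarray(X.sum(axis=1)).ravel()
    libs = np.maximum(libs, 1.0)
    X = X.multiply(1e4 / libs[:, None]).tocsr()
    X = np.log1p(X.toarray())
    n_comp = min(n_components, min(X.shape) - 1)
    return PCA(n_components=n_comp, random_state=seed).fit_transform(X)


def _smooth_path(path_pts: np.ndarray, subdiv: int = 12) -> np.ndarray:
    """Densify a centroid polyline with a chord-length cubic spline.

    Cells lie on a curved manifold, so a straight polyline through cluster
    centroids cuts corners; projecting onto a smoothed curve through the
    same centroids reduces the resulting pseudotime distortion near
    segment joints (a light-weight stand-in for principal curves).
    """
    if len(path_pts) < 3:
        return path_pts
    from scipy.interpolate import CubicSpline

    chord = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(path_pts, axis=0), axis=1)
    )])
    if chord[-1] == 0:
        return path_pts
    spline = CubicSpline(chord, path_pts, axis=0)
    dense = np.linspace(0, chord[-1], subdiv * (len(path_pts) - 1) + 1)
    return spline(dense)


def _project_onto_path(points: np.ndarray, path_pts: np.ndarray):
    """Arc-length position and distance of each point's projection onto a
    piecewise-linear path through ``path_pts``."""
    n = len(points)
    best_t = np.zeros(n)
    best_d = np.full(n, np.inf)
    cum = 0.0
    for a, b in zip(path_pts[:-1], path_pts[1:]):
        seg = b - a
        seg_len = float(np.linalg.norm(seg))
        if seg_len == 0:
            continue
        u = (points - a) @ seg / seg_len**2
        u = np.clip(u, 0.0, 1.0)
        proj = a + u[:, None] * seg
        d = np.linalg.norm(points - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_t[better] = cum + u[better] * seg_len
        cum += seg_len
    return best_t, best_d


def root_outlier_mask(
    pca: np.ndarray,
    clusters: pd.Series | np.ndarray,
    root: str,
    quantile: float = 0.98,
) -> np.ndarray:
    """Flag root-cluster cells beyond a centroid-distance quantile.

    Optional pre-filter for a stray outlier population inside the starting
    cluster; returns a boolean keep-mask over all cells (non-root cells are
    always kept).  Off by default — apply before :func:`infer_lineages` when
    wanted.
    """
    clusters = np.asarray(clusters, dtype=object)
    keep = np.ones(len(clusters), dtype=bool)
    in_root = clusters == root
    if in_root.sum() < 3:
        return keep
    centroid = pca[in_root].mean(axis=0)
    d = np.linalg.norm(pca[in_root] - centroid, axis=1)
    keep[np.flatnonzero(in_root)[d > np.quantile(d, quantile)]] = False
    return keep


def infer_lineages(
    pca: np.ndarray, clusters: pd.Series | np.ndarray, root: str
) -> TrajectorySet:
    """Infer lineages as root-to-leaf paths of the cluster-centroid MST.

    Parameters
    ----------
    pca
        Cells x components reduced-space coordinates.
    clusters
        Per-cell cluster labels.
    root
        Label of the starting cluster; every lineage begins here.
    """
    clusters = pd.Series(np.asarray(clusters, dtype=object), name="cluster")
    labels = sorted(clusters.unique())
    if root not in labels:
        raise ValueError(f"root cluster {root!r} not among labels {labels}")
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters to infer lineages")
    centroids = np.vstack([pca[(clusters == c).to_numpy()].mean(axis=0) for c in labels])
    D = cdist(centroids, centroids)
    G = nx.Graph()
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            G.add_edge(a, labels[j], weight=float(D[i, j]))
    mst = nx.minimum_spanning_tree(G)
    leaves = [n for n in mst.nodes if mst.degree(n) == 1 and n != root]
    if not leaves:  # root itself is the single leaf of a 2-node tree
        leaves = [n for n in mst.nodes if n != root]
    paths = [nx.shortest_path(mst, root, leaf) for leaf in sorted(leaves)]

    cidx = {c: i for i, c in enumerate(labels)}
    pt = np.full((len(clusters), len(paths)), np.nan)
    dist = np.full((len(clusters), len(paths)), np.nan)
    for li, path in enumerate(paths):
        path_pts = _smooth_path(centroids[[cidx[c] for c in path]])
        on_lineage = clusters.isin(path).to_numpy()
        t, d = _project_onto_path(pca[on_lineage], path_pts)
        pt[on_lineage, li] = t
        dist[on_lineage, li] = d
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / np.maximum(dist, 1e-12) ** 2
    inv = np.where(np.isnan(dist), 0.0, inv)
    denom = inv.sum(axis=1, keepdims=True)
    weights = np.divide(inv, denom, out=np.zeros_like(inv), where=denom > 0)

    lineage_ids = [f"L{i}" for i in range(len(paths))]
    return TrajectorySet(
        lineages=paths,
        pseudotime=pd.DataFrame(pt, columns=lineage_ids),
        weights=pd.DataFrame(weights, columns=lineage_ids),
        reduced_space=pca,
        cell_clusters=clusters,
    )


def define_boundaries(
    traj: TrajectorySet, coverage: float = 0.78, min_cells: int = 20
) -> pd.DataFrame:
    """Per-(cluster, lineage) pseudotime intervals covering ~``coverage``.

    For each cluster on each lineage with at least ``min_cells`` assigned
    cells, ``floor(n * (1 - coverage) / 2)`` cells are dropped from each
    pseudotime tail and the interval is the [min, max] of the rest.  The
    boundary label is ``"<cluster>_to_<next cluster>"`` (``"<cluster>_to_end"``
    for the terminal cluster of a lineage).
    """
    rows = []
    for li, (lid, path) in enumerate(zip(traj.lineage_ids, traj.lineages)):
        pt = traj.pseudotime[lid]
        for s, cluster in enumerate(path):
            vals = pt[(traj.cell_clusters == cluster).to_numpy()].dropna().to_numpy()
            if len(vals) < min_cells:
                log.warning(
                    "define_boundaries: cluster %s on %s has %d cells (<%d); row omitted",
                    cluster, lid, len(vals), min_cells,
                )
                continue
            vals = np.sort(vals)
            # epsilon guards the floor against float error in n*(1-c)/2
            drop = int(np.floor(len(vals) * (1.0 - coverage) / 2.0 + 1e-9))
            kept = vals[drop: len(vals) - drop] if drop > 0 else vals
            nxt = path[s + 1] if s + 1 < len(path) else "end"
            rows.append({
                "lineage_id": lid,
                "cluster_label": cluster,
                "t_start": float(kept[0]),
                "t_end": float(kept[-1]),
                "boundary_label": f"{cluster}_to_{nxt}",
                "n_cells": len(vals),
                "coverage": len(kept) / len(vals),
            })
    return pd.DataFrame(rows)


def downsample_cells(counts: CellCounts, target: int = 10_000, seed: int = 0) -> CellCounts:
    """Uniform random subsample of cells without replacement (seeded)."""
    if target >= counts.n_cells:
        if target > counts.n_cells:
            log.warning(
                "downsample_cells: target %d > %d cells; returning input",
                target, counts.n_cells,
            )
        return counts
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(counts.n_cells, size=target, replace=False))
    return counts.subset_cells(idx)
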