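"""Signed weighted co-expression modules with iterative kME refinement.

Builds a signed adjacency ``((1 + r) / 2) ** beta`` over a cluster's
pseudobulk genes, converts it to topological overlap, detects modules by
average-linkage hierarchical clustering with a simplified dynamic tree cut,
and iteratively refines membership: genes whose correlation with their
module eigengene (kME) falls below ``min_kme_to_stay`` are dropped, modules
whose mean member kME falls below ``min_core_kme`` are disbanded, and the
residual pool is re-clustered until a fixed point.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .datatypes import ModulePartition

log = logging.getLogger(__name__)


def signed_adjacency(expr: pd.DataFrame, beta: float = 14) -> pd.DataFrame:
    """Signed adjacency ``a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta``.

    ``expr`` is genes x samples; correlation is Pearson across samples.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0][:5])
        raise ValueError(f"zero-variance gene(s): {bad}")
    r = np.corrcoef(X)
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_target: float = 0.85,
    default: float = 14,
    n_bins: int = 10,
) -> float:
    """Smallest power whose scale-free topology fit index reaches the target.

    The fit index is the R-squared of the log10(frequency) vs
    log10(connectivity) regression over connectivity bins, sign-flipped when
    the slope is positive.  Returns ``default`` when no power qualifies or
    the index is undefined (degenerate networks).
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    for beta in powers:
        a = signed_adjacency(expr, beta=beta).to_numpy()
        k = a.sum(axis=1) - 1.0
        if np.ptp(k) < 1e-12:
            log.warning("pick_soft_threshold: connectivity constant; returning default")
            return float(default)
        edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
        which = np.digitize(k, edges[1:-1])
        xs, ys = [], []
        for b in range(n_bins):
            sel = which == b
            if sel.sum() == 0:
                continue
            xs.append(np.log10(max(k[sel].mean(), 1e-12)))
            ys.append(np.log10(sel.mean()))
        if len(xs) < 3:
            continue
        slope, intercept = np.polyfit(xs, ys, 1)
        pred = np.polyval([slope, intercept], xs)
        ss_res = np.sum((np.array(ys) - pred) ** 2)
        ss_tot = np.sum((np.array(ys) - np.mean(ys)) ** 2)
        r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
        fit = -r2 if slope > 0 else r2
        if fit >= r2_target:
            return float(beta)
    return float(default)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap of a symmetric unit-diagonal adjacency.

    ``w_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for
    ``i != j`` with ``k_i`` the connectivity excluding the diagonal;
    ``w_ii = 1``.
    """
    A = adjacency.to_numpy(dtype=float)
    k = A.sum(axis=1) - 1.0
    # shared-neighbor sums excluding i and j themselves
    L = A @ A - A * 2.0  # removes a_ii*a_ij + a_ij*a_jj (diag is 1)
    num = L + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(w, 1.0)
    w = np.clip(w, 0.0, 1.0)
    return pd.DataFrame(w, index=adjacency.index, columns=adjacency.columns)


def module_eigengene(expr: pd.DataFrame, members: list[str]) -> pd.Series:
    """First principal component of standardized member expression.

    The eigengene is scaled to unit variance and sign-oriented so the mean
    member correlation with it is non-negative.
    """
    X = expr.loc[members].to_numpy(dtype=float)
    Xs = (X - X.mean(axis=1, keepdims=True)) / np.maximum(X.std(axis=1, keepdims=True), 1e-12)
    # samples x genes SVD; first right singular vector spans sample space
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = Vt[0]
    eig = eig / max(eig.std(), 1e-12)
    cors = np.array([np.corrcoef(row, eig)[0, 1] for row in Xs])
    if np.nanmean(cors) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns)


def _kme(expr: pd.DataFrame, genes: list[str], eig: pd.Series) -> pd.Series:
    X = expr.loc[genes].to_numpy(dtype=float)
    e = eig.to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    ec = e - e.mean()
    num = Xc @ ec
    den = np.sqrt((Xc**2).sum(axis=1) * (ec**2).sum())
    return pd.Series(np.divide(num, np.maximum(den, 1e-12)), index=genes)


def _cut_tree(Z, n_leaves: int, min_module_size: int, deep_split_gap: float):
    """Simplified dynamic tree cut: top-level cut at the 0.99 height
    quantile, then recursive splitting while both branches meet the size
    floor and the branch-height gap exceeds ``deep_split_gap``."""
    root = to_tree(Z)
    heights = Z[:, 2]
    cut = float(np.quantile(heights, 0.99))
    clusters: list[list[int]] = []

    def leaves(node):
        return node.pre_order(lambda x: x.id)

    def split(node):
        if node.is_leaf():
            clusters.append([node.id])
            return
        left, right = node.get_left(), node.get_right()
        child_h = max(left.dist, right.dist)
        gap = node.dist - child_h
        big_enough = (left.get_count() >= min_module_size
                      and right.get_count() >= min_module_size)
        if node.dist > cut or (big_enough and gap > deep_split_gap):
            split(left)
            split(right)
        else:
            clusters.append(leaves(node))

    split(root)
    return clusters


def detect_modules(
    tom: pd.DataFrame,
    expr: pd.DataFrame,
    min_module_size: int = 20,
    merge_cor: float = 0.85,
    deep_split_gap: float = 0.02,
    cluster_label: str = "",
    module_prefix: str = "M",
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a simplified dynamic cut.

    Clusters smaller than ``min_module_size`` go to the "unassigned" pool;
    modules whose eigengenes correlate above ``merge_cor`` are merged.
    """
    genes = list(tom.index)
    assignments = pd.Series("unassigned", index=genes, dtype=object)
    if len(genes) < min_module_size:
        return ModulePartition(cluster_label, assignments)
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    Z = linkage(squareform(diss, checks=False), method="average")
    clusters = _cut_tree(Z, len(genes), min_module_size, deep_split_gap)
    clusters = [c for c in clusters if len(c) >= min_module_size]
    clusters.sort(key=len, reverse=True)
    for mi, idxs in enumerate(clusters):
        for i in idxs:
            assignments.iloc[i] = f"{module_prefix}{mi + 1}"
    part = ModulePartition(cluster_label, assignments)
    _update_eigengenes(part, expr)
    _merge_similar(part, expr, merge_cor)
    return part


def _update_eigengenes(part: ModulePartition, expr: pd.DataFrame) -> None:
    eigs = {}
    kmes = []
    for m in part.modules():
        members = part.members(m)
        eig = module_eigengene(expr, members)
        eigs[m] = eig
        kmes.append(_kme(expr, members, eig))
    part.eigengenes = pd.DataFrame(eigs)
    part.kme = pd.concat(kmes) if kmes else pd.Series(dtype=float)


def _merge_similar(part: ModulePartition, expr: pd.DataFrame, merge_cor: float) -> None:
    changed = True
    while changed and len(part.modules()) > 1:
        changed = False
        mods = part.modules()
        E = part.eigengenes[mods]
        C = np.corrcoef(E.to_numpy().T)
        best, pair = -np.inf, None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                if C[i, j] > best:
                    best, pair = C[i, j], (mods[i], mods[j])
        if best > merge_cor and pair is not None:
            a, b = pair
            part.assignments[part.assignments == b] = a
            _update_eigengenes(part, expr)
            changed = True


def iterative_refine(
    partition: ModulePartition,
    expr: pd.DataFrame,
    min_kme_to_stay: float = 0.5,
    min_core_kme: float = 0.7,
    max_iter: int = 10,
    min_module_size: int = 20,
    beta: float = 14,
) -> ModulePartition:
    """Iteratively prune weak members and disband weak-core modules.

    Each pass recomputes eigengenes and kME, drops members with
    ``kME < min_kme_to_stay`` into the residual pool, disbands modules whose
    mean member kME is below ``min_core_kme``, then re-runs module detection
    on the residual pool and adopts any new modules.  Stops at a fixed point
    or after ``max_iter`` passes.
    """
    part = ModulePartition(
        partition.cluster_label, partition.assignments.copy(), params={
            "beta": beta, "min_module_size": min_module_size,
            "min_kme_to_stay": min_kme_to_stay, "min_core_kme": min_core_kme,
        },
    )
    counter = len(part.modules())
    for _ in range(max_iter):
        prev = part.assignments.copy()
        _update_eigengenes(part, expr)
        for m in part.modules():
            members = part.members(m)
            kme = part.kme.loc[members]
            weak = kme.index[kme < min_kme_to_stay]
            part.assignments[weak] = "unassigned"
            members = part.members(m)
            if len(members) < min_module_size or (
                len(members) and part.kme.loc[members].mean() < min_core_kme
            ):
                part.assignments[part.assignments == m] = "unassigned"
        pool = list(part.assignments.index[part.assignments == "unassigned"])
        if len(pool) >= min_module_size:
            sub = expr.loc[pool]
            sd = sub.to_numpy().std(axis=1)
            sub = sub.loc[np.array(sd) > 0]
            if sub.shape[0] >= min_module_size:
                adj = signed_adjacency(sub, beta=beta)
                tom = tom_similarity(adj)
                new = detect_modules(
                    tom, sub, min_module_size=min_module_size,
                    module_prefix=f"R{counter}_",
                )
                for m in new.modules():
                    counter += 1
                    part.assignments[new.members(m)] = f"M{counter}"
        if part.assignments.equals(prev):
            break
    # final enforcement pass (no re-detection): a module re-added from the
    # residual pool on the last iteration must still satisfy the kME floors
    _update_eigengenes(part, expr)
    for m in part.modules():
        members = part.members(m)
        kme = part.kme.loc[members]
        part.assignments[kme.index[kme < min_kme_to_stay]] = "unassigned"
        members = part.members(m)
        if len(members) < min_module_size or (
            len(members) and part.kme.loc[members].mean() < min_core_kme
        ):
            part.assignments[part.assignments == m] = "unassigned"
    _update_eigengenes(part, expr)
    return part


def detect_cluster_modules(
    expr: pd.DataFrame,
    beta: float = 14,
    min_module_size: int = 20,
    min_kme_to_stay: float = 0.5,
    min_core_kme: float = 0.7,
    cluster_label: str = "",
    refine: bool = True,
) -> ModulePartition:
    """Full module pipeline for one cluster's genes x samples pseudobulk."""
    sd = expr.to_numpy(dtype=float).std(axis=1)
    expr = expr.loc[np.array(sd) > 0]
    adj = signed_adjacency(expr, beta=beta)
    tom = tom_similarity(adj)
    part = detect_modules(tom, expr, min_module_size=min_module_size,
                          cluster_label=cluster_label)
    if refine:
        part = iterative_refine(
            part, expr, min_kme_to_stay=min_kme_to_stay,
            min_core_kme=min_core_kme, min_module_size=min_module_size, beta=beta,
        )
    part.cluster_label = cluster_label
    return part
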