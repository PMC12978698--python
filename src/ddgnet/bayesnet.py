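"""Bayesian network structure learning per co-expression module (MMHC).

The hybrid scheme follows the max-min hill-climbing recipe: a
constraint-based skeleton (max-min parents-children with Fisher-z partial
correlation tests, symmetrized by intersection) restricts the edges a
greedy Gaussian-BIC hill climb may add; deletions and reversals are
unrestricted.  Scores are decomposable per-node linear-regression BICs, so
move evaluation touches only the affected node(s).  All tie-breaks are
lexicographic, making the output deterministic for a fixed input.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import GeneDAG, ModulePartition

log = logging.getLogger(__name__)


def _partial_corr(C: np.ndarray, i: int, j: int, cond: tuple[int, ...]) -> float:
    """Partial correlation of variables i, j given ``cond`` from a
    correlation matrix, via the inverse of the relevant submatrix."""
    idx = [i, j, *cond]
    sub = C[np.ix_(idx, idx)]
    try:
        P = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        raise FloatingPointError("singular conditioning set")
    denom = np.sqrt(P[0, 0] * P[1, 1])
    if denom == 0 or not np.isfinite(denom):
        raise FloatingPointError("degenerate partial correlation")
    return float(-P[0, 1] / denom)


def _fisher_z_p(r: float, n: int, k: int) -> float:
    """Two-sided p-value of the Fisher-z transformed (partial) correlation
    with ``k`` conditioning variables."""
    df = n - k - 3
    if df <= 0:
        return 1.0
    r = np.clip(r, -0.999999, 0.999999)
    z = np.sqrt(df) * np.arctanh(r)
    return float(2 * norm.sf(abs(z)))


class _CITester:
    """Cached Fisher-z conditional-independence tests on one data matrix."""

    def __init__(self, X: np.ndarray, alpha: float, max_cond: int):
        self.C = np.corrcoef(X.T)
        self.n = X.shape[0]
        self.alpha = alpha
        self.max_cond = max_cond
        self.cache: dict[tuple, float] = {}

    def p_value(self, i: int, j: int, cond: tuple[int, ...]) -> float:
        key = (min(i, j), max(i, j), tuple(sorted(cond)))
        if key not in self.cache:
            try:
                r = _partial_corr(self.C, i, j, cond)
                p = _fisher_z_p(r, self.n, len(cond))
            except FloatingPointError:
                # collinear conditioning: treat the pair as dependent
                log.debug("CI test skipped (singular) for (%d, %d | %s)", i, j, cond)
                p = 0.0
            self.cache[key] = p
        return self.cache[key]

    def min_assoc(self, i: int, j: int, cpc: list[int]) -> float:
        """Max p-value (weakest association) over conditioning subsets of
        the CPC up to ``max_cond``; this is the max-min association metric."""
        worst = 0.0
        for size in range(0, min(self.max_cond, len(cpc)) + 1):
            for cond in combinations(cpc, size):
                p = self.p_value(i, j, cond)
                if p > worst:
                    worst = p
                if worst >= self.alpha:
                    return worst  # already independent somewhere
        return worst


def mmpc_skeleton(
    expr_module: pd.DataFrame,
    alpha: float = 0.05,
    max_cond_set: int = 3,
) -> set[tuple[str, str]]:
    """Max-min parents-children skeleton over module genes.

    ``expr_module`` is genes x samples.  For each target, candidates are
    grown by the max-min heuristic (add the variable whose weakest
    association over conditioning subsets of the current CPC is strongest),
    shrunk by a backward pass, and edges are kept only when both endpoints
    select each other.  Returns undirected edges as sorted name pairs.
    """
    genes = list(expr_module.index)
    if len(genes) < 2:
        return set()
    X = expr_module.to_numpy(dtype=float).T
    if X.shape[0] < 15:
        log.warning("mmpc_skeleton: only %d samples; tests will be weak", X.shape[0])
    tester = _CITester(X, alpha, max_cond_set)
    p_idx = range(len(genes))
    cpcs: dict[int, set[int]] = {}
    for t in p_idx:
        cpc: list[int] = []
        candidates = [v for v in p_idx if v != t]
        while True:
            best_v, best_p = None, None
            for v in candidates:
                p = tester.min_assoc(t, v, cpc)
                if p < tester.alpha and (best_p is None or p < best_p or
                                         (p == best_p and v < best_v)):
                    best_v, best_p = v, p
            if best_v is None:
                break
            cpc.append(best_v)
            candidates.remove(best_v)
        # backward shrink
        changed = True
        while changed:
            changed = False
            for v in sorted(cpc):
                others = [u for u in cpc if u != v]
                if tester.min_assoc(t, v, others) >= tester.alpha:
                    cpc.remove(v)
                    changed = True
        cpcs[t] = set(cpc)
    edges = set()
    for t in p_idx:
        for v in cpcs[t]:
            if t in cpcs[v]:
                a, b = sorted((genes[t], genes[v]))
                edges.add((a, b))
    return edges


def _node_bic(y: np.ndarray, X: np.ndarray | None) -> float:
    """Gaussian BIC contribution of one node given its parent matrix.

    ``BIC = -2 loglik + k log n`` with the Gaussian MLE variance; ``k``
    counts the regression coefficients, intercept and variance.
    """
    n = len(y)
    if X is None or X.shape[1] == 0:
        resid = y - y.mean()
        k = 2
    else:
        Z = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        k = Z.shape[1] + 1
    s2 = max(float(resid @ resid) / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * s2) + 1)
    return -2 * loglik + k * np.log(n)


class _HillClimbState:
    def __init__(self, expr: pd.DataFrame):
        self.genes = list(expr.index)
        self.X = expr.to_numpy(dtype=float).T  # samples x genes
        self.parents: dict[str, set[str]] = {g: set() for g in self.genes}
        self.node_bic: dict[str, float] = {
            g: _node_bic(self.X[:, i], None) for i, g in enumerate(self.genes)
        }
        self.col = {g: i for i, g in enumerate(self.genes)}

    def bic_with(self, child: str, parents: set[str]) -> float:
        y = self.X[:, self.col[child]]
        if parents:
            Xp = self.X[:, [self.col[p] for p in sorted(parents)]]
        else:
            Xp = None
        return _node_bic(y, Xp)

    def total(self) -> float:
        return sum(self.node_bic.values())

    def creates_cycle(self, parent: str, child: str) -> bool:
        # DFS from child following current parent->child direction
        stack, seen = [child], set()
        children = {g: set() for g in self.genes}
        for c, ps in self.parents.items():
            for p in ps:
                children[p].add(c)
        while stack:
            node = stack.pop()
            if node == parent:
                return True
            if node in seen:
                continue
            seen.add(node)
            stack.extend(children[node])
        return False


def hill_climb(
    expr_module: pd.DataFrame,
    skeleton: set[tuple[str, str]],
    max_iter: int = 200,
    cluster_label: str = "",
    module_id: str = "",
) -> GeneDAG:
    """Greedy add/delete/reverse search minimizing total Gaussian BIC.

    Edge additions are restricted to skeleton pairs; deletions and
    reversals are unrestricted.  Ties break lexicographically on
    (parent, child), so the result is deterministic.
    """
    state = _HillClimbState(expr_module)
    allowed = {tuple(sorted(e)) for e in skeleton}
    # score-equivalent moves (e.g. orienting the first edge either way) are
    # exact ties; resolve them lexicographically rather than by float noise
    tol = 1e-6

    def better(delta, key, best):
        if delta >= -tol:
            return False
        if best is None:
            return True
        if delta < best[0] - tol:
            return True
        return delta <= best[0] + tol and key < best[1]

    for _ in range(max_iter):
        best = None  # (delta, move_key, apply_payload)
        cur_edges = [(p, c) for c, ps in state.parents.items() for p in sorted(ps)]
        # additions
        for a, b in sorted(allowed):
            for parent, child in ((a, b), (b, a)):
                if parent in state.parents[child]:
                    continue
                if state.creates_cycle(parent, child):
                    continue
                new_bic = state.bic_with(child, state.parents[child] | {parent})
                delta = new_bic - state.node_bic[child]
                key = ("add", parent, child)
                if better(delta, key, best):
                    best = (delta, key, (child, state.parents[child] | {parent}, None, None))
        # deletions
        for parent, child in sorted(cur_edges):
            new_bic = state.bic_with(child, state.parents[child] - {parent})
            delta = new_bic - state.node_bic[child]
            key = ("del", parent, child)
            if better(delta, key, best):
                best = (delta, key, (child, state.parents[child] - {parent}, None, None))
        # reversals
        for parent, child in sorted(cur_edges):
            state.parents[child].discard(parent)
            cyc = state.creates_cycle(child, parent)
            state.parents[child].add(parent)
            if cyc:
                continue
            bic_child = state.bic_with(child, state.parents[child] - {parent})
            bic_parent = state.bic_with(parent, state.parents[parent] | {child})
            delta = (bic_child - state.node_bic[child]) + (bic_parent - state.node_bic[parent])
            key = ("rev", parent, child)
            if better(delta, key, best):
                best = (delta, key,
                        (child, state.parents[child] - {parent},
                         parent, state.parents[parent] | {child}))
        if best is None:
            break
        _, _, (c1, p1, c2, p2) = best
        state.parents[c1] = p1
        state.node_bic[c1] = state.bic_with(c1, p1)
        if c2 is not None:
            state.parents[c2] = p2
            state.node_bic[c2] = state.bic_with(c2, p2)
    edges = sorted((p, c) for c, ps in state.parents.items() for p in ps)
    return GeneDAG(cluster_label, module_id, state.genes, edges, score=state.total())


def learn_network(
    expr_module: pd.DataFrame,
    alpha: float = 0.05,
    max_cond_set: int = 3,
    cluster_label: str = "",
    module_id: str = "",
) -> GeneDAG:
    """MMHC: skeleton discovery followed by restricted hill climbing."""
    skel = mmpc_skeleton(expr_module, alpha=alpha, max_cond_set=max_cond_set)
    return hill_climb(expr_module, skel, cluster_label=cluster_label, module_id=module_id)


def learn_module_networks(
    partition: ModulePartition,
    expr: pd.DataFrame,
    alpha: float = 0.05,
    max_cond_set: int = 3,
    min_samples: int = 15,
    min_genes: int = 3,
) -> list[GeneDAG]:
    """One network per module of a partition (small modules skipped)."""
    dags = []
    for m in partition.modules():
        members = partition.members(m)
        if len(members) < min_genes or expr.shape[1] < min_samples:
            log.warning("learn_module_networks: module %s skipped (size/sample floor)", m)
            continue
        sub = expr.loc[[g for g in members if g in expr.index]]
        dags.append(learn_network(sub, alpha=alpha, max_cond_set=max_cond_set,
                                  cluster_label=partition.cluster_label, module_id=m))
    return dags
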