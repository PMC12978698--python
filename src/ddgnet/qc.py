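"""Cell/gene QC filters and per-cluster mean-expression pseudobulk.

The pseudobulk chain is: raw per-(cluster, sample) mean UMI (rounded to two
decimals), a low-expression gene filter, counts-per-million scaling, a
variance-stabilizing transform driven by a fitted mean-dispersion trend, and
quantile normalization across samples.  Stage tags on
:class:`~ddgnet.datatypes.PseudobulkSet` enforce the order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CellCounts, PseudobulkSet, SchemaError

log = logging.getLogger(__name__)


def filter_cells(
    counts: CellCounts,
    min_reads: int = 400,
    max_reads: int = 6200,
    max_mito: float = 0.10,
    max_rpl: float = 0.20,
    max_rps: float = 0.15,
    min_features: int = 200,
) -> CellCounts:
    """Drop cells outside the QC envelope.

    A cell is retained when its total UMI count lies in
    ``[min_reads, max_reads]`` (cells equal to either bound are kept), its
    mitochondrial fraction is <= ``max_mito``, its Rpl/Rps fractions are
    <= ``max_rpl``/``max_rps``, and it has at least ``min_features`` genes
    detected.  The gene set is unchanged.
    """
    for col in ("mito", "rpl", "rps"):
        if col not in counts.gene_meta.columns:
            raise SchemaError(f"gene_meta lacks required flag column {col!r}")
    m = counts.matrix
    total = np.asarray(m.sum(axis=0)).ravel()
    feats = np.asarray((m > 0).sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = {}
        for col in ("mito", "rpl", "rps"):
            flag = counts.gene_meta[col].to_numpy(dtype=bool)
            sub = np.asarray(m[flag, :].sum(axis=0)).ravel() if flag.any() else np.zeros_like(total)
            fracs[col] = np.where(total > 0, sub / np.maximum(total, 1), 0.0)
    keep = (
        (total >= min_reads)
        & (total <= max_reads)
        & (fracs["mito"] <= max_mito)
        & (fracs["rpl"] <= max_rpl)
        & (fracs["rps"] <= max_rps)
        & (feats >= min_features)
    )
    log.info("filter_cells: retained %d / %d cells", int(keep.sum()), counts.n_cells)
    return counts.subset_cells(keep)


def filter_genes_min_cells(counts: CellCounts, min_cells: int = 3) -> CellCounts:
    """Retain genes detected (count > 0) in at least ``min_cells`` cells."""
    ncells = np.asarray((counts.matrix > 0).sum(axis=1)).ravel()
    return counts.subset_genes(ncells >= min_cells)


def mean_expression(counts: CellCounts, min_cells: int = 5) -> PseudobulkSet:
    """Per-cluster, per-sample mean of raw UMI counts, rounded to 2 decimals.

    Samples contributing fewer than ``min_cells`` cells to a cluster are
    omitted from that cluster's matrix.  Rounding is round-half-to-even.
    """
    m = sp.csc_matrix(counts.matrix)
    meta = counts.cell_meta
    symbols = counts.symbols
    matrices: dict[str, pd.DataFrame] = {}
    contrib = []
    for cluster, sub in meta.groupby("cluster_label", sort=True, observed=True):
        cols = {}
        for sample, cells in sub.groupby("sample_id", sort=True):
            idx = cells.index.to_numpy()
            contrib.append({"cluster": cluster, "sample": sample, "n_cells": len(idx)})
            if len(idx) < min_cells:
                continue
            mean = np.asarray(m[:, idx].mean(axis=1)).ravel()
            cols[sample] = np.round(mean, 2)
        if not cols:
            log.warning("mean_expression: cluster %s has no qualifying samples", cluster)
            matrices[str(cluster)] = pd.DataFrame(index=symbols)
        else:
            matrices[str(cluster)] = pd.DataFrame(cols, index=symbols)
    return PseudobulkSet(matrices, "raw_mean", pd.DataFrame(contrib))


def filter_low_expressed(pb: PseudobulkSet, min_nonzero: int = 15) -> PseudobulkSet:
    """Per cluster, drop genes with nonzero values in fewer than ``min_nonzero`` samples."""
    pb.require_stage("raw_mean")
    out = {}
    for cluster, mat in pb.matrices.items():
        if mat.shape[1] == 0:
            out[cluster] = mat
            continue
        keep = (mat.to_numpy() > 0).sum(axis=1) >= min_nonzero
        out[cluster] = mat.loc[keep]
    return PseudobulkSet(out, "raw_mean", pb.contributing_cells)


def normalize_cpm(pb: PseudobulkSet) -> PseudobulkSet:
    """Scale each sample column to counts-per-million (no log)."""
    pb.require_stage("raw_mean")
    out = {}
    for cluster, mat in pb.matrices.items():
        if mat.shape[1] == 0:
            out[cluster] = mat
            continue
        sums = mat.sum(axis=0)
        zero = sums[sums == 0]
        if len(zero):
            raise ValueError(
                f"cluster {cluster}: zero column sum for sample(s) {list(zero.index)}"
            )
        out[cluster] = mat / sums * 1e6
    return pb.advance(out, "cpm")


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Fit the parametric dispersion trend alpha(mu) = a1/mu + a0.

    Two passes of gamma-style reweighted least squares on the regressors
    ``[1/mu, 1]``; falls back to ordinary least squares when the fit
    degenerates.
    """
    X = np.column_stack([1.0 / mu, np.ones_like(mu)])
    w = np.ones_like(alpha)
    coef = None
    for _ in range(2):
        Xw = X * w[:, None]
        coef, *_ = np.linalg.lstsq(Xw, alpha * w, rcond=None)
        pred = X @ coef
        pred = np.maximum(pred, 1e-8)
        w = 1.0 / pred  # gamma weighting: variance ~ mean^2
    a1, a0 = float(coef[0]), float(coef[1])
    if not np.isfinite(a0) or not np.isfinite(a1):
        coef, *_ = np.linalg.lstsq(X, alpha, rcond=None)
        a1, a0 = float(coef[0]), float(coef[1])
    if a0 <= 0:
        # least squares on log dispersions, constrained to a positive asymptote
        from scipy.optimize import curve_fit

        try:
            (a1, a0), _ = curve_fit(
                lambda m, b1, b0: np.log(b1 / m + b0),
                mu, np.log(alpha),
                p0=[max(a1, 1.0), 1e-3],
                bounds=([0.0, 1e-9], [np.inf, np.inf]),
                maxfev=2000,
            )
            a1, a0 = float(a1), float(a0)
        except Exception:  # pragma: no cover - degenerate trend
            pass
    return max(a1, 0.0), a0


def vst_transform_values(q: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """Closed-form variance-stabilizing transform for the trend a1/mu + a0."""
    q = np.asarray(q, dtype=float)
    inner = (1 + a1 + 2 * a0 * q + 2 * np.sqrt(a0 * q * (1 + a1 + a0 * q))) / (4 * a0)
    return np.log2(inner)


def vst(pb: PseudobulkSet) -> PseudobulkSet:
    """Variance-stabilizing transform of CPM pseudobulk.

    Size factors come from the median-of-ratios over all-positive gene rows;
    per-gene dispersions are method-of-moments estimates on size-factor
    normalized values; the trend ``alpha(mu) = a1/mu + a0`` is fitted by
    reweighted least squares and plugged into the closed-form transform.
    When the fitted asymptotic dispersion ``a0`` is not positive, the
    transform falls back to ``log2(q + 1)`` with a warning.
    """
    pb.require_stage("cpm")
    out = {}
    for cluster, mat in pb.matrices.items():
        X = mat.to_numpy(dtype=float)
        if X.shape[1] < 2:
            raise ValueError(f"cluster {cluster}: VST requires at least 2 samples")
        pos = (X > 0).all(axis=1)
        if pos.sum() < 2:
            log.warning("vst: cluster %s has <2 all-positive rows; using log2(q+1)", cluster)
            out[cluster] = pd.DataFrame(np.log2(X + 1), index=mat.index, columns=mat.columns)
            continue
        logX = np.log(X[pos])
        geomean = np.exp(logX.mean(axis=1))
        sf = np.median(X[pos] / geomean[:, None], axis=0)
        sf = np.maximum(sf, 1e-12)
        Q = X / sf[None, :]
        mu = Q.mean(axis=1)
        var = Q.var(axis=1, ddof=1)
        ok = mu > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            alpha = (var - mu) / mu**2
        alpha = np.clip(alpha, 1e-8, 100.0)
        use = ok & (var > mu)  # genes informative about overdispersion
        if use.sum() >= 10:
            a1, a0 = _fit_dispersion_trend(mu[use], alpha[use])
        else:
            a1, a0 = 1.0, float(np.median(alpha[ok])) if ok.any() else 0.1
        if a0 <= 0:
            log.warning("vst: cluster %s fitted a0 <= 0; falling back to log2(q+1)", cluster)
            out[cluster] = pd.DataFrame(np.log2(Q + 1), index=mat.index, columns=mat.columns)
            continue
        out[cluster] = pd.DataFrame(
            vst_transform_values(Q, a0, a1), index=mat.index, columns=mat.columns
        )
    return pb.advance(out, "vst")


def quantile_normalize_frame(mat: pd.DataFrame) -> pd.DataFrame:
    """Map each column onto the mean order-statistic reference distribution.

    Ties within a column receive the mean of the reference values their
    ranks span (average-rank interpolation).
    """
    X = mat.to_numpy(dtype=float)
    n, k = X.shape
    if n == 0 or k == 0:
        return mat.copy()
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    from scipy.stats import rankdata

    grid = np.arange(1, n + 1, dtype=float)
    for j in range(k):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


def quantile_normalize(pb: PseudobulkSet) -> PseudobulkSet:
    """Quantile-normalize each cluster matrix across samples."""
    pb.require_stage("vst")
    out = {c: quantile_normalize_frame(m) for c, m in pb.matrices.items()}
    return pb.advance(out, "quantile")


def pseudobulk_pipeline(
    counts: CellCounts,
    min_cells: int = 5,
    min_nonzero: int = 15,
    cell_qc: dict | None = None,
    min_gene_cells: int = 3,
) -> PseudobulkSet:
    """Full chain: cell QC -> gene filter -> mean -> CPM -> VST -> quantile."""
    filtered = filter_cells(counts, **(cell_qc or {}))
    filtered = filter_genes_min_cells(filtered, min_gene_cells)
    pb = mean_expression(filtered, min_cells=min_cells)
    pb = filter_low_expressed(pb, min_nonzero=min_nonzero)
    # clusters left without enough samples or genes cannot be normalized
    keep = {}
    for cluster, mat in pb.matrices.items():
        if mat.shape[0] < 2 or mat.shape[1] < 2:
            log.warning(
                "pseudobulk_pipeline: cluster %s dropped (%d genes x %d samples "
                "after filtering)", cluster, *mat.shape,
            )
            continue
        keep[cluster] = mat
    pb = PseudobulkSet(keep, "raw_mean", pb.contributing_cells)
    return quantile_normalize(vst(normalize_cpm(pb)))
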