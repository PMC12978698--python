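"""Founder-haplotype eQTL scanning with permutation LOD thresholds.

Expression of each gene (per-cluster pseudobulk) is regressed at every
marker on the 8 founder dosages plus covariates; the LOD score is
``(n/2) * log10(RSS0 / RSS1)`` against the covariates-only null.  Founder
effects are reported sum-to-zero.  Significance thresholds follow the
random-gene permutation recipe: a set of genes is permuted against the
genotypes, the genome-wide maximum LOD is recorded per permutation, each
gene contributes the 0.95 quantile of its max-LOD distribution, the
per-cluster threshold is the median over genes and the final threshold the
mean over clusters.  A cis call requires the peak marker within 1 Mbp of
the gene's TSS on the same chromosome.

An optional kinship random effect (founder-dosage GRM, single variance
component estimated under the null by profiled maximum likelihood) rotates
the problem into uncorrelated coordinates before the fixed-effect scan.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import FounderGenotypes

log = logging.getLogger(__name__)


def _covariate_matrix(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Design matrix from a covariate frame: numeric columns as-is,
    non-numeric dummy-coded; intercept prepended."""
    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
                names.append(c)
            else:
                d = pd.get_dummies(col, drop_first=True)
                for dc in d.columns:
                    cols.append(d[dc].to_numpy(dtype=float))
                    names.append(f"{c}[{dc}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient covariates: {X.shape[1]} columns, rank {rank} ({names})"
        )
    return X


class GenotypeScanner:
    """Precomputed per-marker projections for fast repeated LOD scans.

    Covariates are projected out of both expression and dosages once; the
    LOD at a marker then follows from the squared norm of the residualized
    expression against the marker's orthonormal dosage basis, which makes
    permutation scans a sequence of matrix products.
    """

    def __init__(
        self,
        genotypes: FounderGenotypes,
        covariates: pd.DataFrame | None = None,
        kinship: np.ndarray | None = None,
        variance_ratio: float | None = None,
    ):
        self.genotypes = genotypes
        n = len(genotypes.sample_ids)
        X0 = _covariate_matrix(covariates, n)
        if kinship is not None:
            lam = variance_ratio if variance_ratio is not None else 1.0
            vals, vecs = np.linalg.eigh(kinship)
            w = 1.0 / np.sqrt(np.maximum(lam * vals + 1.0, 1e-10))
            self.rotate = (vecs * w[None, :]).T  # decorrelating transform
            X0 = self.rotate @ X0
        else:
            self.rotate = None
        Q0, _ = np.linalg.qr(X0)
        self.Q0 = Q0
        self.n = n
        bases = []
        for mi in range(genotypes.n_markers):
            D = genotypes.dosage[:, mi, :].astype(float)
            if self.rotate is not None:
                D = self.rotate @ D
            Dr = D - Q0 @ (Q0.T @ D)
            Q, R = np.linalg.qr(Dr)
            keep = np.abs(np.diag(R)) > 1e-8 * max(1.0, np.abs(R).max())
            bases.append(Q[:, keep])
        self.bases = bases

    def residualize(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.rotate is not None:
            y = self.rotate @ y
        return y - self.Q0 @ (self.Q0.T @ y)

    def lod_curve(self, y: np.ndarray) -> np.ndarray:
        """Genome-wide LOD curve for one expression vector."""
        r = self.residualize(y)
        rss0 = float(r @ r)
        lods = np.empty(len(self.bases))
        for mi, Q in enumerate(self.bases):
            proj = Q.T @ r
            rss1 = max(rss0 - float(proj @ proj), 1e-300)
            lods[mi] = 0.5 * self.n * np.log10(rss0 / rss1)
        return lods

    def max_lods(self, Y: np.ndarray) -> np.ndarray:
        """Genome-wide maximum LOD for each column of ``Y`` (n x B)."""
        R = Y - self.Q0 @ (self.Q0.T @ Y)
        rss0 = (R**2).sum(axis=0)
        best = np.zeros(Y.shape[1])
        for Q in self.bases:
            proj = Q.T @ R
            rss1 = np.maximum(rss0 - (proj**2).sum(axis=0), 1e-300)
            best = np.maximum(best, 0.5 * self.n * np.log10(rss0 / rss1))
        return best


def dosage_kinship(genotypes: FounderGenotypes) -> np.ndarray:
    """Genome-wide founder-dosage GRM: centered dosage inner products."""
    n_s, n_m, n_f = genotypes.dosage.shape
    D = genotypes.dosage.reshape(n_s, n_m * n_f)
    D = D - D.mean(axis=0, keepdims=True)
    K = D @ D.T / n_m
    return K / max(np.diag(K).mean(), 1e-12)


def estimate_variance_ratio(
    y: np.ndarray,
    kinship: np.ndarray,
    covariates: pd.DataFrame | None = None,
    grid: np.ndarray | None = None,
) -> float:
    """Profiled-ML estimate of var_g/var_e under the covariates-only null.

    A coarse log-grid search over the ratio is ample for decorrelating the
    scan (the LOD is insensitive to small errors in the ratio).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X0 = _covariate_matrix(covariates, n)
    vals, vecs = np.linalg.eigh(kinship)
    yr = vecs.T @ y
    Xr = vecs.T @ X0
    if grid is None:
        grid = np.concatenate([[0.0], np.logspace(-2, 2, 25)])
    best_lam, best_ll = 0.0, -np.inf
    for lam in grid:
        d = lam * vals + 1.0
        w = 1.0 / d
        Xw = Xr * w[:, None]
        beta, *_ = np.linalg.lstsq(Xr * np.sqrt(w)[:, None], yr * np.sqrt(w), rcond=None)
        resid = yr - Xr @ beta
        rss = float(resid @ (resid * w))
        ll = -0.5 * (n * np.log(max(rss, 1e-300) / n) + np.sum(np.log(d)))
        if ll > best_ll:
            best_ll, best_lam = ll, float(lam)
    return best_lam


def scan_gene(
    expr_vector: pd.Series | np.ndarray,
    genotypes: FounderGenotypes,
    covariates: pd.DataFrame | None = None,
    scanner: GenotypeScanner | None = None,
) -> pd.DataFrame:
    """LOD curve for one gene: marker, chrom, pos, lod.

    The model at each marker is expression ~ covariates + 8 founder dosages
    (one dropped for identifiability) against the covariates-only null.
    """
    y = np.asarray(expr_vector, dtype=float)
    if len(y) < 20:
        raise ValueError("need at least 20 samples for the haplotype scan")
    if scanner is None:
        scanner = GenotypeScanner(genotypes, covariates)
    lods = scanner.lod_curve(y)
    out = genotypes.marker_map.copy()
    out["lod"] = lods
    return out


def founder_effects(
    expr_vector: np.ndarray,
    genotypes: FounderGenotypes,
    marker_index: int,
    covariates: pd.DataFrame | None = None,
) -> np.ndarray:
    """Sum-to-zero founder effect estimates at one marker."""
    y = np.asarray(expr_vector, dtype=float)
    n = len(y)
    X0 = _covariate_matrix(covariates, n)
    D = genotypes.dosage[:, marker_index, :].astype(float)
    X = np.column_stack([X0, D[:, :-1]])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    eff7 = beta[X0.shape[1]:]
    eff = np.append(eff7, 0.0)
    return eff - eff.mean()


def scan_cluster(
    expr: pd.DataFrame,
    genotypes: FounderGenotypes,
    covariates: pd.DataFrame | None = None,
    cluster_label: str = "",
    kinship: np.ndarray | None = None,
) -> pd.DataFrame:
    """Peak-marker scan for every gene of one cluster's pseudobulk.

    Columns of ``expr`` must align with ``genotypes.sample_ids`` (missing
    samples are dropped from the scan).
    """
    common = [s for s in genotypes.sample_ids if s in expr.columns]
    idx = [genotypes.sample_ids.index(s) for s in common]
    sub = FounderGenotypes(
        genotypes.dosage[idx], genotypes.marker_map, common, genotypes.founder_labels
    )
    cov = covariates.loc[common] if covariates is not None else None
    scanner = GenotypeScanner(sub, cov) if kinship is None else None
    rows = []
    for gene in expr.index:
        y = expr.loc[gene, common].to_numpy(dtype=float)
        if kinship is not None:
            lam = estimate_variance_ratio(y, kinship, cov)
            sc = GenotypeScanner(sub, cov, kinship=kinship, variance_ratio=lam)
        else:
            sc = scanner
        lods = sc.lod_curve(y)
        mi = int(np.argmax(lods))
        rows.append({
            "gene": gene, "cluster_label": cluster_label,
            "peak_marker": sub.marker_map["marker"].iloc[mi],
            "peak_chrom": str(sub.marker_map["chrom"].iloc[mi]),
            "peak_pos": int(sub.marker_map["pos"].iloc[mi]),
            "lod": float(lods[mi]),
            "founder_effects": founder_effects(y, sub, mi, cov),
        })
    return pd.DataFrame(rows)


def permutation_threshold(
    expr_by_cluster: dict[str, pd.DataFrame],
    genotypes: FounderGenotypes,
    covariates: pd.DataFrame | None = None,
    n_genes: int = 50,
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation LOD threshold per chromosome class ("A" autosomes, "X").

    Per cluster, ``n_genes`` random genes are each permuted ``n_perm``
    times against the genotypes (covariates refit per permutation); each
    gene contributes the ``quantile`` of its genome-wide max-LOD
    distribution, the cluster contributes the median over genes, and the
    returned threshold is the mean over clusters.
    """
    rng = np.random.default_rng(seed)
    chroms = genotypes.marker_map["chrom"].astype(str)
    classes = {"A": chroms != "X"}
    if (chroms == "X").any():
        classes["X"] = chroms == "X"
    out: dict[str, float] = {}
    for label, mmask in classes.items():
        midx = np.flatnonzero(mmask.to_numpy())
        cluster_medians = []
        for cluster, expr in expr_by_cluster.items():
            common = [s for s in genotypes.sample_ids if s in expr.columns]
            idx = [genotypes.sample_ids.index(s) for s in common]
            sub = FounderGenotypes(
                genotypes.dosage[idx][:, midx, :],
                genotypes.marker_map.iloc[midx].reset_index(drop=True),
                common, genotypes.founder_labels,
            )
            cov = covariates.loc[common] if covariates is not None else None
            scanner = GenotypeScanner(sub, cov)
            genes = list(expr.index)
            if len(genes) > n_genes:
                genes = list(rng.choice(genes, size=n_genes, replace=False))
            else:
                log.warning(
                    "permutation_threshold: cluster %s has %d genes (< %d); using all",
                    cluster, len(genes), n_genes,
                )
            gene_thresholds = []
            for gene in genes:
                y = expr.loc[gene, common].to_numpy(dtype=float)
                perms = np.empty((len(y), n_perm))
                for b in range(n_perm):
                    perms[:, b] = y[rng.permutation(len(y))]
                maxlod = scanner.max_lods(perms)
                gene_thresholds.append(float(np.quantile(maxlod, quantile)))
            cluster_medians.append(float(np.median(gene_thresholds)))
        out[label] = float(np.mean(cluster_medians))
    return out


def call_cis_eqtl(
    peaks: pd.DataFrame,
    threshold: float | dict[str, float],
    gene_annotation: pd.DataFrame,
    cis_window: int = 1_000_000,
) -> pd.DataFrame:
    """Retain peaks with LOD >= threshold within ``cis_window`` of the TSS.

    ``gene_annotation`` needs columns symbol/chrom/tss_pos.  Distance is
    ``|peak_pos - tss_pos|`` on 1-based positions, same chromosome; a peak
    at exactly the window edge is retained.
    """
    ann = gene_annotation.set_index("symbol")
    rows = []
    for _, r in peaks.iterrows():
        if r["gene"] not in ann.index:
            log.info("call_cis_eqtl: no TSS for %s; skipped", r["gene"])
            continue
        thr = threshold if np.isscalar(threshold) else threshold.get(
            "X" if str(r["peak_chrom"]) == "X" else "A"
        )
        a = ann.loc[r["gene"]]
        same_chrom = str(a["chrom"]) == str(r["peak_chrom"])
        dist = abs(int(a["tss_pos"]) - int(r["peak_pos"]))
        if r["lod"] >= thr and same_chrom and dist <= cis_window:
            row = dict(r)
            row["cis"] = True
            row["tss_dist"] = dist
            row["threshold_used"] = thr
            rows.append(row)
    return pd.DataFrame(rows)


def carrier_groups(
    genotypes: FounderGenotypes,
    marker: str,
    founder: int | str,
    dosage_min: float = 0.5,
) -> pd.Series:
    """Boolean carrier indicator per sample at one marker.

    A sample is a carrier when its dosage of ``founder`` at ``marker`` is at
    least ``dosage_min`` (dosage >= 0.5 approximates "at least one allele").
    """
    mi = genotypes.marker_index(marker)
    if isinstance(founder, str):
        founder = genotypes.founder_labels.index(founder)
    d = genotypes.dosage[:, mi, founder]
    carriers = d >= dosage_min
    if not carriers.any():
        log.warning("carrier_groups: founder %s absent at %s", founder, marker)
    return pd.Series(carriers, index=genotypes.sample_ids, name="carrier")
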