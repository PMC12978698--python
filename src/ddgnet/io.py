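"""Readers and writers for the pipeline's on-disk formats.

Counts travel as a 10x-style triplet (MatrixMarket ``matrix.mtx`` +
``genes.tsv`` + ``barcodes.tsv``) with cell metadata as CSV; genotypes as a
long-format dosage CSV plus a marker map; pseudobulk as one genes x samples
CSV per cluster with a stage suffix.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import CellCounts, FounderGenotypes, PseudobulkSet


def write_counts(counts: CellCounts, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(counts.matrix))
    counts.gene_meta.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    counts.cell_meta[["cell_id"]].to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    counts.cell_meta.to_csv(outdir / "cell_meta.csv", index=False)


def read_counts(indir) -> CellCounts:
    indir = Path(indir)
    matrix = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    gene_meta = pd.read_csv(indir / "genes.tsv", sep="\t")
    cell_meta = pd.read_csv(indir / "cell_meta.csv")
    return CellCounts(matrix, gene_meta, cell_meta)


def write_genotypes(genotypes: FounderGenotypes, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_s, n_m, n_f = genotypes.dosage.shape
    recs = []
    markers = genotypes.marker_map["marker"].tolist()
    for si, s in enumerate(genotypes.sample_ids):
        for mi in range(n_m):
            for fi in range(n_f):
                d = genotypes.dosage[si, mi, fi]
                if d != 0:
                    recs.append((s, markers[mi], genotypes.founder_labels[fi], d))
    pd.DataFrame(recs, columns=["sample", "marker", "founder", "dosage"]).to_csv(
        outdir / "genotypes.csv", index=False
    )
    genotypes.marker_map.to_csv(outdir / "marker_map.csv", index=False)


def read_genotypes(indir) -> FounderGenotypes:
    indir = Path(indir)
    long = pd.read_csv(indir / "genotypes.csv")
    marker_map = pd.read_csv(indir / "marker_map.csv")
    marker_map["chrom"] = marker_map["chrom"].astype(str)
    samples = sorted(long["sample"].unique())
    founders = ("A", "B", "C", "D", "E", "F", "G", "H")
    midx = {m: i for i, m in enumerate(marker_map["marker"])}
    sidx = {s: i for i, s in enumerate(samples)}
    fidx = {f: i for i, f in enumerate(founders)}
    dosage = np.zeros((len(samples), len(marker_map), len(founders)))
    dosage[
        long["sample"].map(sidx).to_numpy(),
        long["marker"].map(midx).to_numpy(),
        long["founder"].map(fidx).to_numpy(),
    ] = long["dosage"].to_numpy(dtype=float)
    return FounderGenotypes(dosage, marker_map, samples, founders)


def write_pseudobulk(pb: PseudobulkSet, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cluster, mat in pb.matrices.items():
        mat.to_csv(outdir / f"pseudobulk_{cluster}_{pb.stage}.csv")
    if pb.contributing_cells is not None:
        pb.contributing_cells.to_csv(outdir / "contributing_cells.csv", index=False)


def read_pseudobulk(indir, stage: str) -> PseudobulkSet:
    indir = Path(indir)
    matrices = {}
    for path in sorted(indir.glob(f"pseudobulk_*_{stage}.csv")):
        cluster = path.stem[len("pseudobulk_"): -len(f"_{stage}")]
        matrices[cluster] = pd.read_csv(path, index_col=0)
    pb = PseudobulkSet(matrices, "raw_mean")
    pb.stage = stage  # bypass transition check when loading from disk
    return pb
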