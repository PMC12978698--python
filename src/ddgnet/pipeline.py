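"""End-to-end orchestration: simulate -> QC -> pseudobulk -> trajectories ->
dynamic genes -> modules -> networks -> DDGs -> eQTL -> composition ->
prioritization, with a manifest recording parameters and stage outputs."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .sim import SimConfig, simulate_population
from .datatypes import CellCounts
from . import qc, trajectory, dynamic, coexpression, bayesnet, ddg as ddg_mod
from . import eqtl as eqtl_mod
from . import composition as comp_mod
from . import prioritize as pri_mod
from . import io as io_mod

log = logging.getLogger(__name__)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_all(
    out_dir,
    sim_config: SimConfig | None = None,
    seed: int = 0,
    coverage: float = 0.78,
    nknots: int = 10,
    l2fc: float = 0.5,
    alpha: float = 0.05,
    beta: float = 14,
    downsample_target: int = 10_000,
    n_perm: int = 100,
    n_perm_genes: int = 20,
    population_mode: str = "network",
    module_clusters: list[str] | None = None,
    write_outputs: bool = True,
) -> dict:
    """Run the full pipeline on a synthetic population; returns a result dict.

    ``module_clusters`` limits co-expression/network learning to the listed
    clusters (default: the bifurcation clusters LMP and OBP, where the
    boundary tests are most informative); permutations default to reduced
    counts so the whole run stays desk-scale.
    """
    t_start = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = sim_config or SimConfig(seed=seed)
    manifest: dict = {
        "version": __version__, "seed": seed, "sim_config": asdict(cfg),
        "params": {
            "coverage": coverage, "nknots": nknots, "l2fc": l2fc, "alpha": alpha,
            "beta": beta, "downsample_target": downsample_target,
            "n_perm": n_perm, "n_perm_genes": n_perm_genes,
            "population_mode": population_mode,
        },
        "stages": {},
    }

    def stage(name):
        log.info("pipeline stage: %s", name)
        manifest["stages"][name] = {"t": round(time.time() - t_start, 1)}

    stage("simulate")
    counts, samples, genotypes, truth = simulate_population(cfg)
    samples = samples.set_index("sample_id", drop=False)

    stage("qc")
    filtered = qc.filter_cells(counts)
    filtered = qc.filter_genes_min_cells(filtered)

    stage("pseudobulk")
    pb_raw = qc.filter_low_expressed(qc.mean_expression(filtered))
    pb = qc.quantile_normalize(qc.vst(qc.normalize_cpm(pb_raw)))

    stage("trajectory")
    pca = trajectory.compute_reduced_space(filtered, seed=seed)
    traj = trajectory.infer_lineages(pca, filtered.cell_meta["cluster_label"], cfg.root)
    boundaries = trajectory.define_boundaries(traj, coverage=coverage)

    stage("dynamic")
    down = trajectory.downsample_cells(filtered, target=downsample_target, seed=seed)
    down_idx = filtered.cell_meta["cell_id"].isin(down.cell_meta["cell_id"]).to_numpy()
    traj_down = trajectory.TrajectorySet(
        traj.lineages,
        traj.pseudotime[down_idx].reset_index(drop=True),
        traj.weights[down_idx].reset_index(drop=True),
        traj.reduced_space[down_idx],
        traj.cell_clusters[down_idx].reset_index(drop=True),
    )
    dyn_results = dynamic.test_boundaries(
        down, traj_down, boundaries, nknots=nknots, l2fc=l2fc, alpha=alpha,
    )
    dynamic_sets = {
        b: set(g.loc[g["significant"], "gene"])
        for b, g in dyn_results[dyn_results["test_type"] == "start_vs_end"]
        .groupby("boundary_label")
    }

    stage("modules")
    clusters_for_modules = module_clusters or ["LMP", "OBP"]
    partitions = {}
    for cluster in clusters_for_modules:
        if cluster not in pb.matrices:
            continue
        partitions[cluster] = coexpression.detect_cluster_modules(
            pb.matrices[cluster], beta=beta, cluster_label=cluster,
        )

    stage("networks")
    networks = []
    for cluster, part in partitions.items():
        networks += bayesnet.learn_module_networks(part, pb.matrices[cluster])

    stage("ddg")
    cluster_boundaries = {
        c: {b for b in dynamic_sets if b.startswith(f"{c}_to_")}
        for c in partitions
    }
    enrichments = []
    for net in networks:
        dsets = {b: dynamic_sets[b] for b in cluster_boundaries.get(net.cluster_label, [])
                 if dynamic_sets.get(b)}
        if not dsets:
            continue
        try:
            enrichments += ddg_mod.test_network_boundaries(
                net, dsets, population_mode=population_mode,
            )
        except ValueError as err:
            log.info("ddg: network %s skipped: %s", net.module_id, err)
    ddg_calls = ddg_mod.call_ddgs(enrichments, alpha=alpha)

    stage("eqtl")
    covariates = samples[["sex", "age_days", "weight", "length", "generation"]]
    thresholds = eqtl_mod.permutation_threshold(
        {c: pb.matrices[c] for c in clusters_for_modules if c in pb.matrices},
        genotypes, covariates, n_genes=n_perm_genes, n_perm=n_perm, seed=seed,
    )
    peaks = pd.concat([
        eqtl_mod.scan_cluster(pb.matrices[c], genotypes, covariates, cluster_label=c)
        for c in clusters_for_modules if c in pb.matrices
    ], ignore_index=True) if clusters_for_modules else pd.DataFrame()
    cis = eqtl_mod.call_cis_eqtl(peaks, thresholds["A"], counts.gene_meta) \
        if len(peaks) else pd.DataFrame()

    stage("composition")
    props = comp_mod.cluster_proportions(filtered.cell_meta)
    transformed = comp_mod.asin_sqrt_transform(props)
    traits = samples[[c for c in samples.columns if c.startswith("trait_")]]
    trait_cor = comp_mod.trait_correlation(transformed, traits)

    stage("prioritize")
    coloc = pd.DataFrame(truth.coloc_genes)
    prioritized = pri_mod.intersect_coloc(
        ddg_calls[ddg_calls.get("is_ddg", pd.Series(dtype=bool)) == True]  # noqa: E712
        if len(ddg_calls) else ddg_calls,
        coloc,
    ) if len(ddg_calls) and len(coloc) else pd.DataFrame()
    summary = pri_mod.summarize(prioritized)

    manifest["stages"]["done"] = {"t": round(time.time() - t_start, 1)}
    manifest["population_mode"] = population_mode
    results = {
        "counts": counts, "filtered": filtered, "samples": samples,
        "genotypes": genotypes, "truth": truth, "pseudobulk": pb,
        "trajectories": traj, "boundaries": boundaries,
        "dynamic_results": dyn_results, "dynamic_sets": dynamic_sets,
        "partitions": partitions, "networks": networks,
        "ddg_calls": ddg_calls, "eqtl_thresholds": thresholds,
        "eqtl_peaks": peaks, "cis_eqtl": cis,
        "proportions": props, "trait_correlations": trait_cor,
        "prioritized": prioritized, "summary": summary, "manifest": manifest,
    }

    if write_outputs:
        io_mod.write_counts(counts, out_dir / "counts")
        io_mod.write_genotypes(genotypes, out_dir / "genotypes")
        samples.to_csv(out_dir / "samples.csv", index=False)
        truth.to_json(out_dir / "ground_truth.json")
        io_mod.write_pseudobulk(pb, out_dir / "pseudobulk")
        traj.pseudotime.to_csv(out_dir / "pseudotime.csv", index=False)
        boundaries.to_csv(out_dir / "boundaries.csv", index=False)
        dyn_results.to_csv(out_dir / "dynamic_results.csv", index=False)
        for net in networks:
            pd.DataFrame(net.edges, columns=["parent", "child"]).to_csv(
                out_dir / f"network_{net.cluster_label}_{net.module_id}.csv", index=False
            )
        if len(ddg_calls):
            ddg_calls.to_csv(out_dir / "ddg_calls.csv", index=False)
        if len(peaks):
            peaks.drop(columns=["founder_effects"]).to_csv(
                out_dir / "eqtl_peaks.csv", index=False
            )
        if len(prioritized):
            prioritized.to_csv(out_dir / "prioritized.csv", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        manifest["checksums"] = {
            p.name: _checksum(p) for p in sorted(out_dir.glob("*.csv"))
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return results
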