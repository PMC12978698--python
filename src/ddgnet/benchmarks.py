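"""Recovery and calibration experiments on planted synthetic data.

Each function runs a self-contained experiment at the study's conditions
(desk-scale population, cohort-scale genotype panels, structure-learning
scale SEM draws) and returns the measured quantity: planted-module ARI,
network-skeleton F1, driver-gene recovery rates, dynamic-test error rates,
eQTL power against a permutation threshold.  Both the test suite and the
reproduction script are thin callers of this module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sim import (
    SimConfig,
    _random_module_dag,
    _sem_weights,
    simulate_driver_network,
    simulate_genotypes,
    simulate_population,
    simulate_sem,
)


def trajectory_recovery(seed: int = 1, coverage: float = 0.78) -> dict:
    """Lineage-count, pseudotime-correlation and boundary-coverage summary."""
    from scipy.stats import spearmanr

    from . import qc
    from .trajectory import compute_reduced_space, define_boundaries, infer_lineages

    counts, _, _, truth = simulate_population(SimConfig(seed=seed))
    filtered = qc.filter_genes_min_cells(qc.filter_cells(counts))
    pca = compute_reduced_space(filtered, seed=seed)
    traj = infer_lineages(pca, filtered.cell_meta["cluster_label"], "MPC")
    kept = filtered.cell_meta["cell_id"].str.replace("cell", "").astype(int) - 1
    true_pt = truth.pseudotime_frame().iloc[kept.to_numpy()].reset_index(drop=True)
    rhos = []
    for lid, path in zip(traj.lineage_ids, traj.lineages):
        match = [i for i, p in enumerate(truth.lineage_paths) if p[-1] == path[-1]]
        if not match:
            rhos.append(0.0)
            continue
        tcol = true_pt[f"L{match[0]}"]
        mask = tcol.notna() & traj.pseudotime[lid].notna()
        rhos.append(float(spearmanr(tcol[mask], traj.pseudotime[lid][mask]).statistic))
    rows = define_boundaries(traj, coverage=coverage)
    big = rows[rows["n_cells"] >= 500]
    return {
        "n_lineages": len(traj.lineages),
        "n_true_lineages": len(truth.lineage_paths),
        "min_pseudotime_spearman": min(rhos),
        "mean_boundary_coverage": float(big["coverage"].mean()),
        "n_boundaries": int(len(rows)),
    }


def module_recovery_ari(seed: int = 1, cluster: str = "LMP") -> float:
    """Adjusted Rand index between detected modules and the planted map."""
    from sklearn.metrics import adjusted_rand_score

    from .coexpression import detect_cluster_modules
    from .qc import pseudobulk_pipeline

    counts, _, _, truth = simulate_population(SimConfig(seed=seed))
    pb = pseudobulk_pipeline(counts)
    part = detect_cluster_modules(pb.matrices[cluster], cluster_label=cluster)
    genes = list(truth.module_membership)
    pred = part.assignments.reindex(genes).fillna("unassigned")
    return float(adjusted_rand_score(
        [truth.module_membership[g] for g in genes], list(pred)
    ))


def bn_skeleton_f1(n_nodes: int = 20, n_samples: int = 500,
                   n_seeds: int = 3, seed0: int = 0) -> float:
    """Mean skeleton F1 of MMHC on random linear-Gaussian SEM modules."""
    from .bayesnet import learn_network

    f1s = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed0 + s)
        genes = [f"g{i}" for i in range(n_nodes)]
        edges = _random_module_dag(genes, rng)
        w = _sem_weights(edges, rng, (0.5, 1.0), neg_prob=0.5)
        expr = simulate_sem(genes, edges, w, n_samples, rng).T
        dag = learn_network(expr)
        truth = {tuple(sorted(e)) for e in edges}
        learned = {tuple(sorted(e)) for e in dag.edges}
        tp = len(truth & learned)
        prec = tp / max(len(learned), 1)
        rec = tp / max(len(truth), 1)
        f1s.append(2 * prec * rec / max(prec + rec, 1e-9))
    return float(np.mean(f1s))


def ddg_driver_recovery(n_seeds: int = 20, seed0: int = 0) -> dict:
    """Planted-driver recovery through network learning + enrichment.

    Per seed: simulate one driver-planted module at the structure-learning
    scale, learn the network with MMHC, call DDGs, and record whether the
    driver is called (BH-adjusted p < 0.05) and whether it has the smallest
    enrichment p in its network.
    """
    from .bayesnet import learn_network
    from .ddg import call_ddgs, test_network_boundaries

    called = top = 0
    for s in range(n_seeds):
        expr, truth = simulate_driver_network(seed=seed0 + s)
        dag = learn_network(expr, cluster_label="LMP", module_id="M1")
        calls = call_ddgs(test_network_boundaries(
            dag, {"LMP_to_OBP": set(truth["dynamic_genes"])},
            population_mode="network",
        ))
        if calls.empty:
            continue
        drv = calls[calls["focal_gene"] == truth["driver"]]
        if len(drv) and bool(drv["is_ddg"].iloc[0]):
            called += 1
            if drv["p"].iloc[0] <= calls["p"].min() + 1e-15:
                top += 1
    return {"recovery_rate": called / n_seeds, "top_rank_rate": top / n_seeds,
            "n_seeds": n_seeds}


def ddg_null_call_rate(n_seeds: int = 20, seed0: int = 300) -> dict:
    """Fraction of DDG calls on networks with no planted enrichment."""
    from .bayesnet import learn_network
    from .ddg import call_ddgs, test_network_boundaries

    fp = total = 0
    for s in range(n_seeds):
        expr, truth = simulate_driver_network(seed=seed0 + s)
        rng = np.random.default_rng(seed0 + s)
        dag = learn_network(expr)
        dyn = set(rng.choice(truth["nodes"], size=6, replace=False))
        calls = call_ddgs(test_network_boundaries(
            dag, {"B": dyn}, population_mode="network",
        ))
        if calls.empty:
            continue
        fp += int(calls["is_ddg"].sum())
        total += len(calls)
    return {"null_call_fraction": fp / max(total, 1), "n_tests": total}


def dynamic_test_calibration(
    n_null: int = 1000,
    n_signal: int = 100,
    n_cells: int = 500,
    l2fc_planted: float = 2.0,
    dispersion: float = 0.4,
    seed: int = 0,
) -> dict:
    """Type-I error at nominal 0.05 and FDR-controlled sensitivity.

    Null genes are NB noise with no pseudotime trend; signal genes carry a
    logistic sigmoid with the generator's planted log2 fold change.
    """
    from .dynamic import LN2, adjust_and_call, fit_nb_spline, start_vs_end_test

    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 1, n_cells)
    pt = pd.DataFrame({"L0": t})
    w = pd.DataFrame({"L0": np.ones(n_cells)})
    boundary = {"lineage_id": "L0", "boundary_label": "B",
                "t_start": 0.05, "t_end": 0.95, "cluster_label": "A"}

    def gene(l2fc):
        eta = np.log(5.0) + l2fc * LN2 / (1 + np.exp(-(t - 0.5) / 0.1))
        mu = np.exp(eta)
        r = 1 / dispersion
        return rng.negative_binomial(r, r / (r + mu))

    rows = []
    for i in range(n_null):
        fit = fit_nb_spline(gene(0.0), pt, w, gene=f"null{i}")
        rows.append({**start_vs_end_test(fit, boundary), "truth": False})
    for i in range(n_signal):
        fit = fit_nb_spline(gene(l2fc_planted), pt, w, gene=f"sig{i}")
        rows.append({**start_vs_end_test(fit, boundary), "truth": True})
    df = adjust_and_call(pd.DataFrame(rows))
    null_p = df.loc[~df["truth"], "p"].to_numpy()
    return {
        "type1_error": float((null_p < 0.05).mean()),
        "sensitivity": float(df.loc[df["truth"], "significant"].mean()),
        "n_null": n_null, "n_signal": n_signal,
    }


def eqtl_power_experiment(
    n_mice: int = 80,
    n_perm: int = 200,
    n_perm_genes: int = 50,
    n_power_sims: int = 30,
    n_null_sims: int = 30,
    effect_sd: float = 1.0,
    seed: int = 0,
) -> dict:
    """Detection power for a planted one-founder allele-substitution effect
    of ``effect_sd`` residual SD against the permutation LOD threshold, and
    the genome-wide null false-positive rate at that threshold."""
    from .eqtl import GenotypeScanner, permutation_threshold

    cfg = SimConfig(n_mice=n_mice, seed=seed)
    geno = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)
    cov = pd.DataFrame({
        "sex": rng.choice(["M", "F"], n_mice),
        "age_days": rng.normal(70, 8, n_mice),
    }, index=geno.sample_ids)
    null_expr = pd.DataFrame(
        rng.normal(size=(n_perm_genes + 10, n_mice)),
        columns=geno.sample_ids,
        index=[f"g{i}" for i in range(n_perm_genes + 10)],
    )
    thresholds = permutation_threshold(
        {"C": null_expr}, geno, cov,
        n_genes=n_perm_genes, n_perm=n_perm, seed=seed + 2,
    )
    thr = thresholds["A"]
    scanner = GenotypeScanner(geno, cov)
    hits = 0
    for s in range(n_power_sims):
        r = np.random.default_rng(seed + 1000 + s)
        mi = int(r.integers(0, geno.n_markers))
        founder = int(r.integers(0, 8))
        beta = np.zeros(8)
        beta[founder] = effect_sd
        beta -= beta.mean()
        y = geno.dosage[:, mi, :] @ beta + r.normal(size=n_mice)
        if scanner.lod_curve(y).max() >= thr:
            hits += 1
    fp = 0
    for s in range(n_null_sims):
        r = np.random.default_rng(seed + 2000 + s)
        if scanner.lod_curve(r.normal(size=n_mice)).max() >= thr:
            fp += 1
    return {
        "threshold": float(thr),
        "power": hits / n_power_sims,
        "null_fpr": fp / n_null_sims,
        "n_power_sims": n_power_sims, "n_null_sims": n_null_sims,
    }
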