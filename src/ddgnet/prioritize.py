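"""DDG prioritization against a GWAS-colocalization gene table.

DDG calls are intersected (case-insensitively, with an optional
human-mouse symbol mapping) with a table of genes whose GWAS associations
colocalize with eQTL/sQTL; each retained (boundary, gene) row is annotated
with the best-scoring tissue per modality and optionally flagged against a
knockout-phenotype gene list.  A small reference table of 26 prioritized
driver-gene rows ships with the package as a worked example.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd


def load_reference_table() -> pd.DataFrame:
    """The packaged worked-example prioritization table (26 rows)."""
    with resources.files("ddgnet.data").joinpath("prioritized_reference.csv").open() as fh:
        return pd.read_csv(fh)


def reference_coloc_table() -> pd.DataFrame:
    """Long-format coloc table (gene, modality, tissue, score) from the
    packaged reference rows."""
    ref = load_reference_table()
    rows = []
    for _, r in ref.iterrows():
        if isinstance(r.get("eqtl_tissue"), str) and r["eqtl_tissue"]:
            rows.append({"gene": r["gene"], "modality": "eQTL",
                         "tissue": r["eqtl_tissue"], "score": float(r["eqtl_rcp"])})
        if isinstance(r.get("sqtl_tissue"), str) and r["sqtl_tissue"]:
            rows.append({"gene": r["gene"], "modality": "sQTL",
                         "tissue": r["sqtl_tissue"], "score": float(r["sqtl_h4pp"])})
    return pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)


def _best_per_modality(coloc: pd.DataFrame) -> pd.DataFrame:
    """One best row per (gene, modality): max score, ties broken
    alphabetically by tissue."""
    if {"gene", "modality", "tissue", "score"} - set(coloc.columns):
        raise ValueError("coloc table needs columns gene, modality, tissue, score")
    if ((coloc["score"] < 0) | (coloc["score"] > 1)).any():
        raise ValueError("coloc scores must lie in [0, 1]")
    c = coloc.copy()
    c["gene_key"] = c["gene"].str.lower()
    c = c.sort_values(["gene_key", "modality", "score", "tissue"],
                      ascending=[True, True, False, True])
    return c.groupby(["gene_key", "modality"], as_index=False).first()


def intersect_coloc(
    ddgs: pd.DataFrame,
    coloc: pd.DataFrame,
    symbol_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One prioritized row per (boundary, DDG) present in the coloc table.

    ``ddgs`` needs columns focal_gene / boundary_label (plus optional
    cluster_label, module_id, trajectory).  ``symbol_map`` is an optional
    two-column frame mapping DDG symbols to coloc-table symbols; the
    default match is case-insensitive symbol identity.
    """
    if ddgs.empty or coloc.empty:
        return pd.DataFrame(columns=[
            "trajectory", "boundary_label", "gene", "eqtl_tissue", "eqtl_score",
            "sqtl_tissue", "sqtl_score", "impc_flag", "local_egene_flag",
        ])
    best = _best_per_modality(coloc)
    mapping = None
    if symbol_map is not None:
        a, b = symbol_map.columns[:2]
        mapping = dict(zip(symbol_map[a].str.lower(), symbol_map[b].str.lower()))
    calls = ddgs[ddgs.get("is_ddg", True) != False]  # noqa: E712 - keep NaN rows
    rows = []
    seen = set()
    for _, r in calls.iterrows():
        gene = str(r["focal_gene"])
        key = mapping.get(gene.lower(), gene.lower()) if mapping else gene.lower()
        hit = best[best["gene_key"] == key]
        if hit.empty:
            continue
        dedup_key = (r["boundary_label"], gene)
        if dedup_key in seen:
            continue
        seen.add(dedup_key)
        row = {
            "trajectory": r.get("trajectory", r.get("lineage_id", "")),
            "boundary_label": r["boundary_label"],
            "gene": gene,
            "eqtl_tissue": None, "eqtl_score": np.nan,
            "sqtl_tissue": None, "sqtl_score": np.nan,
            "impc_flag": False,
            "local_egene_flag": bool(r.get("local_egene_flag", False)),
        }
        for _, h in hit.iterrows():
            if h["modality"].lower() == "eqtl":
                row["eqtl_tissue"], row["eqtl_score"] = h["tissue"], float(h["score"])
            else:
                row["sqtl_tissue"], row["sqtl_score"] = h["tissue"], float(h["score"])
        rows.append(row)
    return pd.DataFrame(rows)


def flag_impc(rows: pd.DataFrame, impc_genes) -> pd.DataFrame:
    """Set impc_flag where the gene is in the knockout-phenotype list."""
    out = rows.copy()
    genes = {str(g).lower() for g in impc_genes}
    if len(out):
        out["impc_flag"] = out["gene"].str.lower().isin(genes)
    return out


def summarize(rows: pd.DataFrame) -> dict:
    """Row/distinct-gene totals and per-boundary counts."""
    if rows.empty:
        return {"rows_total": 0, "distinct_genes": 0, "per_boundary": {}}
    return {
        "rows_total": int(len(rows)),
        "distinct_genes": int(rows["gene"].str.lower().nunique()),
        "per_boundary": {
            str(k): int(v) for k, v in
            rows["boundary_label"].value_counts().sort_index().items()
        },
    }
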