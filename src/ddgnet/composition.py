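"""Cell-type composition tests on arcsine-square-root transformed proportions.

Per-sample cell-type proportions are variance-stabilized with
``asin(sqrt(p))`` and compared between groups (e.g. founder-haplotype
carriers vs the rest) by a linear model with covariates; two groups give a
two-sided t-test on the group coefficient, more give an ANOVA F-test.
Trait correlations are plain Pearson tests, BH-adjusted per trait.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def cluster_proportions(cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Samples x clusters proportion table (rows sum to 1)."""
    tab = pd.crosstab(cell_meta["sample_id"], cell_meta["cluster_label"])
    return tab.div(tab.sum(axis=1), axis=0)


def asin_sqrt_transform(proportions: pd.DataFrame | np.ndarray):
    """Arcsine-square-root transform, elementwise; domain [0, 1]."""
    arr = np.asarray(proportions, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    if isinstance(proportions, pd.DataFrame):
        return pd.DataFrame(out, index=proportions.index, columns=proportions.columns)
    if isinstance(proportions, pd.Series):
        return pd.Series(out, index=proportions.index)
    return out


def composition_test(
    transformed: pd.Series,
    grouping: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Covariate-adjusted group test on transformed proportions of one cluster.

    ``grouping`` is a per-sample label (two groups: t-test on the group
    coefficient; more: ANOVA F comparing the full model against
    covariates-only).
    """
    import statsmodels.api as sm

    idx = transformed.index
    g = grouping.loc[idx]
    levels = sorted(g.unique())
    if len(levels) < 2:
        raise ValueError("grouping must have at least 2 levels")
    counts = g.value_counts()
    if (counts < 3).any() and len(levels) == 2:
        log.warning("composition_test: a group has <3 samples; t-test unreliable")
    parts = [pd.get_dummies(g, drop_first=True).astype(float)]
    if covariates is not None:
        cov = covariates.loc[idx]
        for c in cov.columns:
            if pd.api.types.is_numeric_dtype(cov[c]):
                parts.append(cov[[c]].astype(float))
            else:
                parts.append(pd.get_dummies(cov[c], prefix=c, drop_first=True).astype(float))
    X = pd.concat(parts, axis=1)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("grouping is confounded with covariates (rank-deficient design)")
    fit = sm.OLS(transformed.astype(float), X).fit()
    group_cols = [c for c in X.columns if c in pd.get_dummies(g, drop_first=True).columns]
    if len(levels) == 2:
        col = group_cols[0]
        stat = float(fit.tvalues[col])
        p = float(fit.pvalues[col])
        kind = "t"
    else:
        contrast = np.zeros((len(group_cols), X.shape[1]))
        for i, c in enumerate(group_cols):
            contrast[i, list(X.columns).index(c)] = 1.0
        f = fit.f_test(contrast)
        stat, p, kind = float(f.fvalue), float(f.pvalue), "F"
    return {"statistic": stat, "p": p, "test": kind,
            "n_groups": len(levels), "group_sizes": counts.to_dict()}


def trait_correlation(
    transformed: pd.DataFrame,
    traits: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r and p per (cluster, trait), BH-adjusted per trait family."""
    from statsmodels.stats.multitest import multipletests

    rows = []
    common = transformed.index.intersection(traits.index)
    for trait in traits.columns:
        tv = traits.loc[common, trait].astype(float)
        if tv.nunique() <= 1:
            log.info("trait_correlation: trait %s constant; skipped", trait)
            continue
        fam = []
        for cluster in transformed.columns:
            x = transformed.loc[common, cluster].astype(float)
            ok = x.notna() & tv.notna()
            if ok.sum() < 3:
                log.info("trait_correlation: <3 samples for (%s, %s); skipped",
                         cluster, trait)
                continue
            r, p = stats.pearsonr(x[ok], tv[ok])
            fam.append({"cluster_label": cluster, "trait": trait,
                        "r": float(r), "p": float(p), "n": int(ok.sum())})
        if fam:
            padj = multipletests([f["p"] for f in fam], method="fdr_bh")[1]
            for f, q in zip(fam, padj):
                f["p_adj"] = float(q)
            rows.extend(fam)
    return pd.DataFrame(rows)
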