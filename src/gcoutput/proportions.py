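"""Cluster-proportion permutation testing and the DEG threshold rule.

The proportion test compares, per cluster, the log2 fold difference of
cluster proportions between two groups against a permutation null built by
re-drawing group labels with group sizes fixed; significance requires both
FDR < 0.05 and |log2FD| > 0.58.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FDR_ALPHA = 0.05
LOG2FD_CUTOFF = 0.58
DEG_LOG2FC_CUTOFF = 0.6


def _proportions(counts: np.ndarray, n: int, pseudo: float) -> np.ndarray:
    """Cluster proportions with a pseudo-proportion substituted for zeros."""
    p = counts / n
    return np.where(counts == 0, pseudo, p)


def proportion_test(cells: pd.DataFrame, group_a: str, group_b: str,
                    n_perm: int = 1000, n_boot: int = 1000,
                    seed: int = 0) -> pd.DataFrame:
    """Permutation test of per-cluster composition differences between groups.

    Per cluster c: log2FD = log2(prop_b(c) / prop_a(c)).  The null permutes
    group labels over the pooled cells keeping group sizes fixed (drawn as a
    multivariate hypergeometric split of per-cluster totals, which is the
    exact label-permutation distribution).  p = (1 + #{|perm| >= |obs|}) /
    (1 + n_perm); bootstrap percentile CI resamples cells within group;
    Benjamini-Hochberg across clusters; a cluster is significant when
    FDR < 0.05 and |log2FD| > 0.58.  Zero-count clusters get a
    pseudo-proportion of 1/(2 n_group) and are flagged.
    """
    for col in ("cluster", "group"):
        if col not in cells.columns:
            raise KeyError(f"cell table missing column {col!r}")
    sub = cells[cells["group"].isin([group_a, group_b])]
    clusters = np.sort(sub["cluster"].unique())
    a = sub[sub["group"] == group_a]["cluster"].to_numpy()
    b = sub[sub["group"] == group_b]["cluster"].to_numpy()
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")

    idx = {c: i for i, c in enumerate(clusters)}
    ca = np.bincount([idx[c] for c in a], minlength=len(clusters))
    cb = np.bincount([idx[c] for c in b], minlength=len(clusters))

    pseudo_a = 1.0 / (2 * n_a)
    pseudo_b = 1.0 / (2 * n_b)
    pa = _proportions(ca, n_a, pseudo_a)
    pb = _proportions(cb, n_b, pseudo_b)
    obs = np.log2(pb / pa)

    rng = np.random.default_rng(seed)
    totals = ca + cb
    perm_b = rng.multivariate_hypergeometric(totals, n_b, size=n_perm)
    perm_a = totals[None, :] - perm_b
    lfd_perm = np.log2(
        _proportions(perm_b, n_b, pseudo_b) / _proportions(perm_a, n_a, pseudo_a)
    )
    p = (1 + (np.abs(lfd_perm) >= np.abs(obs)[None, :]).sum(axis=0)) / (1 + n_perm)

    if n_boot > 0:
        boot_a = rng.multinomial(n_a, ca / n_a, size=n_boot)
        boot_b = rng.multinomial(n_b, cb / n_b, size=n_boot)
        lfd_boot = np.log2(
            _proportions(boot_b, n_b, pseudo_b) / _proportions(boot_a, n_a, pseudo_a)
        )
        ci_low, ci_high = np.percentile(lfd_boot, [2.5, 97.5], axis=0)
    else:
        ci_low = ci_high = obs.copy()

    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "cluster": clusters,
        "n_a": ca, "n_b": cb,
        "prop_a": ca / n_a, "prop_b": cb / n_b,
        "log2fd": obs,
        "p_perm": p,
        "ci_low": ci_low, "ci_high": ci_high,
        "fdr": fdr,
        "zero_substituted": (ca == 0) | (cb == 0),
        "significant": (fdr < FDR_ALPHA) & (np.abs(obs) > LOG2FD_CUTOFF),
    })


def find_degs(expr_a: pd.DataFrame, expr_b: pd.DataFrame,
              alpha: float = FDR_ALPHA,
              log2fc_cutoff: float = DEG_LOG2FC_CUTOFF) -> pd.DataFrame:
    """Rank-sum differential expression with the dual threshold rule.

    Inputs are cells x genes frames over the same gene universe.  Per gene:
    Wilcoxon rank-sum p (1.0 when the gene is constant across both groups),
    BH adjustment, and average log2 fold change log2((mean_a+1)/(mean_b+1)).
    A gene is a DEG when adjusted p < alpha and log2FC > cutoff (one-sided,
    higher in group A).
    """
    if list(expr_a.columns) != list(expr_b.columns):
        raise ValueError("expression frames must share the same gene universe")
    a = expr_a.to_numpy(dtype=float)
    b = expr_b.to_numpy(dtype=float)
    genes = list(expr_a.columns)

    pooled_sd = np.concatenate([a, b], axis=0).std(axis=0)
    constant = pooled_sd == 0
    pvals = np.ones(len(genes))
    if (~constant).any():
        res = stats.mannwhitneyu(a[:, ~constant], b[:, ~constant],
                                 alternative="two-sided", axis=0)
        pvals[~constant] = res.pvalue
    log2fc = np.log2((a.mean(axis=0) + 1.0) / (b.mean(axis=0) + 1.0))
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame({
        "gene": genes,
        "p": pvals,
        "p_adj": adj,
        "log2fc": log2fc,
        "deg": (adj < alpha) & (log2fc > log2fc_cutoff),
    })
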