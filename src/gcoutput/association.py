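"""Covariate-adjusted regressions and nonparametric group comparisons.

``ols_fit`` is ordinary least squares with reference-level dummy coding for
categorical predictors, optional interaction term, and optional
cluster-robust standard errors (used for the longitudinal timepoint-by-group
model).  ``group_compare`` runs Kruskal-Wallis with Dunn's pairwise z tests
(unpaired) or the Wilcoxon signed-rank test (paired).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


def _design_matrix(data: pd.DataFrame, predictors: list[str],
                   interaction: tuple[str, str] | None) -> pd.DataFrame:
    cols = {}
    for name in predictors:
        s = data[name]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=name, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c]
        else:
            cols[name] = s.astype(float)
    X = pd.DataFrame(cols, index=data.index)
    if interaction is not None:
        left, right = interaction
        lcols = [c for c in X.columns if c == left or c.startswith(f"{left}_")]
        rcols = [c for c in X.columns if c == right or c.startswith(f"{right}_")]
        if not lcols or not rcols:
            raise KeyError(f"interaction terms {interaction} not among predictors")
        for lc, rc in itertools.product(lcols, rcols):
            X[f"{lc}:{rc}"] = X[lc] * X[rc]
    return sm.add_constant(X, has_constant="add")


def ols_fit(data: pd.DataFrame, response: str, predictors: list[str],
            interaction: tuple[str, str] | None = None,
            cluster: str | None = None) -> pd.DataFrame:
    """Least-squares fit; returns a tidy coefficient table.

    Categorical predictors are expanded by reference-level dummy coding.
    ``interaction=(a, b)`` adds all a x b product terms.  ``cluster`` names
    a column for cluster-robust standard errors.  Rank deficiency raises
    ``CollinearityError`` naming the offending columns.  The result frame
    carries ``r_squared`` and ``nobs`` in ``attrs``.
    """
    X = _design_matrix(data, list(predictors), interaction)
    y = data[response].astype(float)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        for col in X.columns:
            if col == "const":
                continue
            sub = X.drop(columns=[col])
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                bad.append(col)
        raise CollinearityError(f"design matrix rank deficient; collinear columns: {bad}")
    model = sm.OLS(y, X)
    if cluster is not None:
        res = model.fit(cov_type="cluster",
                        cov_kwds={"groups": data[cluster]})
    else:
        res = model.fit()
    out = pd.DataFrame({
        "term": X.columns,
        "coef": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "t": res.tvalues.to_numpy(),
        "p": res.pvalues.to_numpy(),
    })
    out.attrs["r_squared"] = float(res.rsquared)
    out.attrs["nobs"] = int(res.nobs)
    return out


@dataclass
class GroupCompareResult:
    test: str                      # "kruskal-wallis" | "wilcoxon-signed-rank"
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None  # Dunn's table for the unpaired case
    warnings: list

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def dunn_posthoc(groups: dict, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks with tie correction."""
    labels = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in labels]
    pooled = np.concatenate(values)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term for the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    mean_ranks = {}
    start = 0
    for lab, v in zip(labels, values):
        mean_ranks[lab] = ranks[start:start + v.size].mean()
        start += v.size

    rows = []
    pairs = list(itertools.combinations(labels, 2))
    for a, b in pairs:
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    out = pd.DataFrame(rows)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * len(pairs), 1.0)
    elif adjust == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def group_compare(groups, paired: bool = False,
                  adjust: str = "bonferroni") -> GroupCompareResult:
    """Kruskal-Wallis + Dunn's (unpaired) or Wilcoxon signed-rank (paired).

    ``groups`` is a mapping label -> values (unpaired) or a pair of
    equal-length arrays (paired).  All-tied inputs return p = 1 with a tie
    warning rather than an error.
    """
    warns: list[str] = []
    if paired:
        x, y = (np.asarray(v, dtype=float) for v in groups)
        if x.shape != y.shape:
            raise ValueError("paired comparison needs equal-length arrays")
        if np.all(x == y):
            warns.append("all paired differences are zero")
            return GroupCompareResult("wilcoxon-signed-rank", 0.0, 1.0, None, warns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = stats.wilcoxon(x, y, alternative="two-sided")
        return GroupCompareResult("wilcoxon-signed-rank", float(stat), float(p), None, warns)

    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        warns.append("all values tied across groups")
        return GroupCompareResult("kruskal-wallis", 0.0, 1.0, None, warns)
    stat, p = stats.kruskal(*values)
    pairwise = dunn_posthoc(dict(groups), adjust=adjust)
    return GroupCompareResult("kruskal-wallis", float(stat), float(p), pairwise, warns)
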