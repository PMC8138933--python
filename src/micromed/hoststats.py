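"""Host-phenotype statistics.

Two-group comparisons use a permutation Wilcoxon rank-sum test (exact
enumeration when the number of label splits is small), variance homogeneity is
screened with Levene's test, factorial effects of diet and microbial community
are assessed by two-way ANOVA with Type II sums of squares, and correlations
are Pearson with the exact t reference distribution.  Multiplicity is handled
with Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "perm_wilcoxon",
    "levene",
    "two_way_anova",
    "pearson_corr_test",
    "bh_adjust",
    "phenotype_tests",
]

_EXACT_LIMIT = 20_000


def perm_wilcoxon(a, b, n_perm: int = 9_999, seed: int = 0):
    """Two-sided permutation Wilcoxon rank-sum test.

    The statistic is the rank sum W of group ``a`` on pooled average ranks;
    the two-sided P compares |W - E0[W]| against the permutation distribution.
    All C(n, n_a) splits are enumerated when there are at most 20,000 of them,
    otherwise ``n_perm`` random splits are drawn and the add-one Monte-Carlo
    estimator is used.

    Returns ``(W, P)``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:na].sum()
    mu = na * (n + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    if comb(n, na) <= _EXACT_LIMIT:
        devs = np.array([
            abs(ranks[list(idx)].sum() - mu) for idx in combinations(range(n), na)
        ])
        # exact two-sided tail; tiny epsilon guards float ties at the observed value
        p = np.mean(devs >= dev_obs - 1e-9)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            idx = rng.choice(n, size=na, replace=False)
            if abs(ranks[idx].sum() - mu) >= dev_obs - 1e-9:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
    return float(w_obs), float(p)


def levene(groups, center: str = "mean"):
    """Levene's homogeneity-of-variance test (classical, mean-centered).

    One-way ANOVA F on the absolute deviations from each group's center.
    Returns ``(W, P)``.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    center_fn = np.mean if center == "mean" else np.median
    devs = np.concatenate([np.abs(g - center_fn(g)) for g in groups])
    if np.ptp(devs) == 0:
        return 0.0, 1.0  # identical dispersion in every group
    w, p = stats.levene(*groups, center=center)
    return float(w), float(p)


def two_way_anova(y, factor_a, factor_b) -> pd.DataFrame:
    """Two-way ANOVA with interaction, Type II sums of squares.

    Main effects are each adjusted for the other; the interaction enters last
    and every F is tested against the residual mean square.  Returns a tidy
    frame with one row per term (A, B, A:B) holding sum_sq, df, F and P.
    """
    df = pd.DataFrame({
        "y": np.asarray(y, float),
        "A": pd.Categorical(factor_a),
        "B": pd.Categorical(factor_b),
    })
    cells = df.groupby(["A", "B"], observed=False).size()
    empty = cells[cells == 0]
    if len(empty):
        raise ValueError(f"empty design cell(s): {list(empty.index)}")
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index={"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"})
    return table


def pearson_corr_test(x, y):
    """Pearson correlation with the two-sided t test (df = n - 2).

    Returns ``(r, P)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("P values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def phenotype_tests(pheno: pd.DataFrame, phenotypes, group_col: str = "community",
                    within_col: str = "diet", n_perm: int = 9_999,
                    seed: int = 0) -> pd.DataFrame:
    """Community-vs-community comparisons per diet plus a two-way ANOVA per phenotype.

    Mirrors the standard workflow: within each diet group, a permutation
    Wilcoxon rank-sum test between the two communities; across the full design,
    Levene's screen followed by the factorial ANOVA.  P values of the Wilcoxon
    family are BH adjusted.
    """
    rows = []
    communities = sorted(pheno[group_col].unique())
    for ph in phenotypes:
        for diet in sorted(pheno[within_col].unique()):
            sub = pheno[pheno[within_col] == diet]
            a = sub.loc[sub[group_col] == communities[0], ph]
            b = sub.loc[sub[group_col] == communities[1], ph]
            w, p = perm_wilcoxon(a, b, n_perm=n_perm, seed=seed)
            rows.append({"test": "perm_wilcoxon", "phenotype": ph,
                         "groups": f"{within_col}={diet}", "statistic": w, "P": p})
        lev_w, lev_p = levene([g[ph].to_numpy() for _, g in
                               pheno.groupby([group_col, within_col], observed=False)])
        rows.append({"test": "levene", "phenotype": ph, "groups": "all cells",
                     "statistic": lev_w, "P": lev_p})
        aov = two_way_anova(pheno[ph], pheno[group_col], pheno[within_col])
        for term in ("A", "B", "A:B"):
            rows.append({"test": f"anova[{term}]", "phenotype": ph, "groups": "factorial",
                         "statistic": aov.loc[term, "F"], "P": aov.loc[term, "PR(>F)"]})
    out = pd.DataFrame(rows)
    mask = out["test"] == "perm_wilcoxon"
    out["P_adj"] = np.nan
    out.loc[mask, "P_adj"] = bh_adjust(out.loc[mask, "P"].to_numpy())
    return out
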