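"""Weighted-correlation-network module detection for metabolome/transcriptome.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta with the soft
power beta chosen as the smallest power whose scale-free topology fit reaches
the R^2 cut (0.90 by convention).  Similarity between features is the
topological overlap measure (TOM); modules are branches of an average-linkage
dendrogram on 1 - TOM, cut with a simplified deterministic tree variant of the
dynamic cut (static cut at a high height quantile, branches below the minimum
module size merged into "grey").  Each module is summarized by its eigenvalue
(eigengene): the first principal-component sample scores of the standardized
module matrix, sign-aligned so the mean correlation with the module's own
features is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .hoststats import bh_adjust

__all__ = [
    "ModuleAssignment",
    "pick_soft_power",
    "tom",
    "cut_modules",
    "module_eigenvalue",
    "module_trait_corr",
    "fisher_enrichment",
]

# WGCNA's conventional color order for module labels, largest module first
PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)
GREY = "grey"


@dataclass
class ModuleAssignment:
    """Feature -> module colors plus eigenvalues and module membership (kME)."""

    labels: pd.Series
    eigenvalues: pd.DataFrame
    kme: pd.DataFrame
    soft_power: int

    @property
    def modules(self):
        return [c for c in self.eigenvalues.columns]

    def features_in(self, module: str):
        return list(self.labels.index[self.labels == module])


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) vs log10 k over equal-width connectivity bins."""
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    ok = counts > 0
    if ok.sum() < 3:
        return 0.0
    x = np.log10(centers[ok])
    y = np.log10(counts[ok] / counts.sum())
    r = np.corrcoef(x, y)[0, 1]
    return float(r ** 2)


def pick_soft_power(matrix: pd.DataFrame, powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
                                                  12, 14, 16, 18, 20),
                    r2_cut: float = 0.90) -> int:
    """Smallest soft-thresholding power reaching the scale-free fit cut.

    Falls back (with a warning) to the power maximizing R^2 when no candidate
    reaches the cut.
    """
    x = np.asarray(matrix, float)
    if x.shape[1] < 20:
        raise ValueError("need >= 20 features")
    with np.errstate(invalid="raise"):
        try:
            cor = np.corrcoef(x, rowvar=False)
        except FloatingPointError as err:
            raise ValueError("degenerate correlation matrix") from err
    np.fill_diagonal(cor, 0.0)
    acor = np.abs(cor)
    r2s = []
    for beta in powers:
        k = (acor ** beta).sum(axis=1)
        r2s.append(_scale_free_r2(k))
    for beta, r2 in zip(powers, r2s):
        if r2 >= r2_cut:
            return int(beta)
    best = int(powers[int(np.argmax(r2s))])
    warnings.warn(
        f"no power reached scale-free R^2 {r2_cut}; using power {best} "
        f"(best R^2 = {max(r2s):.3f})"
    )
    return best


def adjacency(matrix: pd.DataFrame, power: int) -> np.ndarray:
    """Unsigned adjacency |cor|^power with zero diagonal."""
    cor = np.corrcoef(np.asarray(matrix, float), rowvar=False)
    a = np.abs(cor) ** power
    np.fill_diagonal(a, 0.0)
    return a


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    The diagonal of the input is treated as zero; TOM_ii = 1.
    """
    a = np.asarray(adj, float).copy()
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValueError("adjacency values must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (shared + a) / denom
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def _pc1_excess(x: np.ndarray) -> float:
    """Variance fraction of PC1 relative to the Marchenko-Pastur noise edge.

    For an n x m standardized pure-noise block the leading sample eigenvalue
    sits near (1 + sqrt(m/n))^2, i.e. a PC1 variance fraction of about
    (1 + sqrt(m/n))^2 / m.  A genuine co-abundance branch exceeds that edge
    severalfold; branches carved out of noise by the clustering stay close
    to it at any soft power.
    """
    n, m = x.shape
    sd = x.std(axis=0)
    x = x[:, sd > 0]
    if x.shape[1] < 2:
        return 0.0
    std = (x - x.mean(axis=0)) / x.std(axis=0)
    s = np.linalg.svd(std, compute_uv=False)
    frac = float(s[0] ** 2 / np.sum(s ** 2))
    edge = (1.0 + np.sqrt(m / n)) ** 2 / m
    return frac / edge


def cut_modules(tom_dissim: np.ndarray, min_size: int = 20,
                feature_ids=None, height_quantile: float = 0.99,
                data: np.ndarray | None = None,
                min_pc1_excess: float = 2.0) -> pd.Series:
    """Branch modules from average-linkage clustering of a TOM dissimilarity.

    Deterministic simplified dynamic cut: a static cut at the given quantile
    of the dendrogram merge heights; branches smaller than ``min_size`` go to
    grey.  When the underlying samples x features matrix is supplied via
    ``data``, branches whose first principal component does not exceed
    ``min_pc1_excess`` times the Marchenko-Pastur noise edge are also greyed
    (the distinctness screen that keeps pure-noise branches out of the module
    set).  Labels are colors assigned largest-module-first.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    d = np.asarray(tom_dissim, float)
    p = d.shape[0]
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(p)]
    if p < min_size:
        return pd.Series(GREY, index=feature_ids, name="module")
    dd = d.copy()
    np.fill_diagonal(dd, 0.0)
    z = linkage(squareform((dd + dd.T) / 2, checks=False), method="average")
    cut = np.quantile(z[:, 2], height_quantile)
    clusters = fcluster(z, t=cut, criterion="distance")
    sizes = pd.Series(clusters).value_counts()
    distinct = {
        c: (True if data is None else
            _pc1_excess(np.asarray(data, float)[:, clusters == c]) >= min_pc1_excess)
        for c in sizes.index
    }
    big = sizes[(sizes >= min_size)
                & np.array([distinct[c] for c in sizes.index])]
    # deterministic order: size descending, then first-feature position
    first_pos = {c: int(np.argmax(clusters == c)) for c in big.index}
    ordered = sorted(big.index, key=lambda c: (-big[c], first_pos[c]))
    color_of = {c: PALETTE[i % len(PALETTE)] for i, c in enumerate(ordered)}
    labels = [color_of.get(c, GREY) for c in clusters]
    return pd.Series(labels, index=feature_ids, name="module")


def module_eigenvalue(matrix: pd.DataFrame, labels: pd.Series) -> ModuleAssignment:
    """Eigenvalue (first PC sample scores) per non-grey module, plus kME.

    Features are standardized; the first right-singular direction gives the
    sample scores, scaled to unit variance and sign-aligned so that the mean
    correlation with the module's own features is positive.  Constant features
    are excluded with a warning.
    """
    x = np.asarray(matrix, float)
    eigs = {}
    modules = [m for m in labels.unique() if m != GREY]
    # stable order: module size descending then palette order
    modules.sort(key=lambda m: (-(labels == m).sum(),
                                PALETTE.index(m) if m in PALETTE else 99))
    for m in modules:
        cols = np.flatnonzero((labels == m).to_numpy())
        sub = x[:, cols]
        sd = sub.std(axis=0)
        if np.any(sd == 0):
            warnings.warn(f"constant feature(s) in module {m} excluded")
            sub = sub[:, sd > 0]
            sd = sd[sd > 0]
        std = (sub - sub.mean(axis=0)) / sd
        u, s, _ = np.linalg.svd(std, full_matrices=False)
        scores = u[:, 0]
        scores = scores / scores.std(ddof=1)
        mean_cor = np.mean([stats.pearsonr(scores, std[:, j])[0]
                            for j in range(std.shape[1])])
        if mean_cor < 0:
            scores = -scores
        eigs[m] = scores
    eig_frame = pd.DataFrame(eigs, index=matrix.index)
    kme = pd.DataFrame(index=matrix.columns, columns=eig_frame.columns, dtype=float)
    for m in eig_frame.columns:
        e = eig_frame[m].to_numpy()
        for f in matrix.columns:
            v = matrix[f].to_numpy()
            kme.loc[f, m] = (np.corrcoef(e, v)[0, 1]
                             if v.std() > 0 else np.nan)
    return ModuleAssignment(labels=labels, eigenvalues=eig_frame, kme=kme,
                            soft_power=0)


def detect_modules(matrix: pd.DataFrame, min_size: int = 20,
                   r2_cut: float = 0.90, power: int | None = None) -> ModuleAssignment:
    """Full pipeline: soft power -> adjacency -> TOM -> cut -> eigenvalues."""
    if power is None:
        power = pick_soft_power(matrix, r2_cut=r2_cut)
    a = adjacency(matrix, power)
    t = tom(a)
    labels = cut_modules(1.0 - t, min_size=min_size, feature_ids=matrix.columns,
                         data=np.asarray(matrix, float))
    out = module_eigenvalue(matrix, labels)
    out.soft_power = power
    return out


def module_trait_corr(eigs: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r / P / BH-FDR for every module x trait cell.

    The BH adjustment spans the full module-by-trait grid jointly.
    """
    if not eigs.index.equals(traits.index):
        raise ValueError("eigenvalues and traits must share sample index")
    n = eigs.shape[0]
    if n < 4:
        raise ValueError("need n >= 4")
    rows = []
    for m in eigs.columns:
        for t in traits.columns:
            r, p = stats.pearsonr(eigs[m], traits[t])
            rows.append({"module": m, "trait": t, "r": r, "P": p})
    out = pd.DataFrame(rows)
    out["FDR"] = bh_adjust(out["P"].to_numpy())
    return out


def fisher_enrichment(module_features, annotation: pd.Series,
                      background) -> pd.DataFrame:
    """One-sided (upper-tail hypergeometric) pathway enrichment with BH FDR.

    ``annotation`` maps feature -> pathway label over the background set.
    """
    module = set(module_features)
    bg = set(background)
    if not module <= bg:
        raise ValueError("module features must be a subset of the background")
    ann = annotation[annotation.index.isin(bg)]
    rows = []
    for pathway, members in ann.groupby(ann).groups.items():
        k_bg = len(set(members))
        if k_bg == 0:
            continue
        k_mod = len(module & set(members))
        p = stats.hypergeom.sf(k_mod - 1, len(bg), k_bg, len(module))
        odds_denom = (len(module) - k_mod) * (k_bg - k_mod)
        odds = (k_mod * (len(bg) - len(module) - k_bg + k_mod) / odds_denom
                if odds_denom > 0 else np.inf)
        rows.append({"pathway": pathway, "hits": k_mod, "pathway_size": k_bg,
                     "odds_ratio": odds, "P": float(p)})
    out = pd.DataFrame(rows).sort_values("P", kind="stable").reset_index(drop=True)
    out["FDR"] = bh_adjust(out["P"].to_numpy())
    return out
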