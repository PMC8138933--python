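"""Alpha/beta diversity, ordination, rarefaction, and PERMANOVA.

Shannon diversity is reported in bits (base-2 logs, the QIIME 2 convention);
Faith's phylogenetic diversity includes the path to the root.  UniFrac
distances (unweighted, and the normalized weighted variant) and Faith PD are
computed through scikit-bio.  PCoA uses the Gower-centered eigendecomposition
with axis signs fixed so the largest-magnitude loading on each axis is
positive.  PERMANOVA uses the pseudo-F on squared distances with a seeded
permutation null and the add-one P estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

__all__ = [
    "DistanceMatrix",
    "rarefy",
    "shannon",
    "faith_pd",
    "beta_distance",
    "pcoa",
    "permanova",
]

METRICS = ("bray_curtis", "jaccard", "unifrac_unweighted", "unifrac_weighted")


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distances with the metric recorded."""

    ids: list
    data: np.ndarray
    metric: str

    def __post_init__(self):
        d = np.asarray(self.data, float)
        if d.shape[0] != d.shape[1] or len(self.ids) != d.shape[0]:
            raise ValueError("distance matrix must be square over ids")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValueError("nonzero diagonal")
        if np.max(np.abs(d - d.T)) > 1e-12:
            raise ValueError("asymmetric distance matrix")
        if np.any(d < -1e-12):
            raise ValueError("negative distances")
        self.data = (d + d.T) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


def rarefy(table: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a warning.
    Uses the multivariate hypergeometric draw, so the expected post-rarefaction
    count of a taxon with count c out of N is c * depth / N.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sum(axis=1)
    shallow = totals[totals < depth].index
    if len(shallow):
        warnings.warn(f"dropping {len(shallow)} sample(s) below depth {depth}")
    kept = table.drop(index=shallow)
    out = np.vstack([
        rng.multivariate_hypergeometric(row.astype(np.int64), depth)
        for row in kept.to_numpy()
    ])
    return pd.DataFrame(out, index=kept.index, columns=kept.columns)


def shannon(counts) -> float:
    """Shannon diversity in bits: -sum p_i log2 p_i over nonzero proportions."""
    x = np.asarray(counts, float)
    if np.any(x < 0) or x.sum() == 0:
        raise ValueError("counts must be nonnegative and not all zero")
    p = x[x > 0] / x.sum()
    return float(-(p * np.log2(p)).sum())


def faith_pd(presence, tree: TreeNode) -> float:
    """Faith's PD: branch length of the minimal subtree spanning present leaves + root."""
    present = list(presence)
    leaves = {t.name for t in tree.tips()}
    unknown = [t for t in present if t not in leaves]
    if unknown:
        raise ValueError(f"taxa not in tree: {unknown}")
    taxa = sorted(leaves)
    vec = np.array([1 if t in set(present) else 0 for t in taxa])
    return float(_skbio_faith_pd(vec, taxa, tree, validate=False))


def _bray_curtis(x, y):
    s = x + y
    return float(np.abs(x - y).sum() / s.sum()) if s.sum() else 0.0


def _jaccard(x, y):
    a, b = x > 0, y > 0
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(1.0 - np.logical_and(a, b).sum() / union)


def _branch_matrix(tree: TreeNode, taxa):
    """(branch lengths, branch x taxon descendant-indicator matrix).

    One row per node with a branch length (the root's unlabelled stem is
    excluded); entry 1 when the taxon's leaf lies below that branch.
    """
    col = {t: k for k, t in enumerate(taxa)}
    rows, lengths = [], []
    for node in tree.postorder(include_self=False):
        if node.length is None:
            continue
        leaves = [t.name for t in node.tips()] if node.children else [node.name]
        ind = np.zeros(len(taxa))
        for l in leaves:
            if l in col:
                ind[col[l]] = 1.0
        rows.append(ind)
        lengths.append(float(node.length))
    return np.asarray(lengths), np.asarray(rows)


def _unifrac_matrix(x: np.ndarray, lengths: np.ndarray, branch: np.ndarray,
                    weighted: bool) -> np.ndarray:
    n = x.shape[0]
    if weighted:
        # per-sample subtree abundance fractions
        rel = x / x.sum(axis=1, keepdims=True)
        p = rel @ branch.T  # n x branches
        num = np.abs(p[:, None] - p[None]) @ lengths
        den = (p[:, None] + p[None]) @ lengths
    else:
        present = ((x > 0).astype(float) @ branch.T) > 0
        both = (present[:, None] & present[None]) @ lengths
        either = (present[:, None] | present[None]) @ lengths
        num = either - both  # unique branch length
        den = either  # total observed branch length
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def beta_distance(table: pd.DataFrame, metric: str,
                  tree: TreeNode | None = None) -> DistanceMatrix:
    """Pairwise beta-diversity distances.

    ``bray_curtis`` on abundances, ``jaccard`` on presence/absence,
    ``unifrac_unweighted`` (unique / observed branch length) and
    ``unifrac_weighted`` (normalized variant, sum b|pA-pB| / sum b(pA+pB) over
    branches) on a taxonomy tree covering all taxa in the table.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    x = np.asarray(table, float)
    n = x.shape[0]
    if metric.startswith("unifrac"):
        if tree is None:
            raise ValueError("UniFrac requires a tree")
        leaves = {t.name for t in tree.tips()}
        missing = [t for t in table.columns if t not in leaves]
        if missing:
            raise ValueError(f"taxa missing from tree: {missing}")
        lengths, branch = _branch_matrix(tree, list(table.columns))
        d = _unifrac_matrix(x, lengths, branch,
                            weighted=(metric == "unifrac_weighted"))
    else:
        d = np.zeros((n, n))
        fn = _bray_curtis if metric == "bray_curtis" else _jaccard
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = fn(x[i], x[j])
    return DistanceMatrix(list(table.index), d, metric)


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-10):
    """Principal coordinates analysis (classical MDS).

    Eigendecomposition of the Gower-centered matrix -0.5 * J D^2 J; axes with
    eigenvalue > ``eig_tol`` are kept and scaled by sqrt(lambda).  Axis signs
    are fixed so the largest-magnitude loading on each axis is positive.
    Returns ``(coordinates DataFrame, eigenvalues, negative_fraction)``.
    """
    d = dm.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > eig_tol
    neg = vals[vals < 0]
    neg_fraction = float(np.abs(neg).sum() / np.abs(vals).sum()) if vals.size else 0.0
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] *= -1
    frame = pd.DataFrame(coords, index=dm.ids,
                         columns=[f"PC{k + 1}" for k in range(coords.shape[1])])
    return frame, vals[keep], neg_fraction


def _ss_within(d2: np.ndarray, groups: np.ndarray, labels) -> float:
    ss = 0.0
    for g in labels:
        idx = groups == g
        ss += d2[idx][:, idx].sum() / (2 * idx.sum())
    return ss


def _pseudo_f(d2: np.ndarray, groups: np.ndarray) -> float:
    n = d2.shape[0]
    labels = np.unique(groups)
    a = labels.size
    ss_total = d2.sum() / (2 * n)
    ss_within = _ss_within(d2, groups, labels)
    return float(((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a)))


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0):
    """PERMANOVA pseudo-F with a seeded permutation P (add-one estimator).

    Returns ``(F, P)``.
    """
    groups = np.asarray(groups)
    labels, sizes = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need >= 2 groups")
    if np.any(sizes < 2):
        raise ValueError(f"singleton group(s): {labels[sizes < 2]}")
    d2 = dm.data ** 2
    f_obs = _pseudo_f(d2, groups)
    # F is monotone decreasing in SS_within for a fixed SS_total, so the
    # permutation comparison can be done on SS_within alone
    ssw_obs = _ss_within(d2, groups, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _ss_within(d2, perm, labels) <= ssw_obs + 1e-12:
            hits += 1
    return f_obs, (1 + hits) / (1 + n_perm)
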