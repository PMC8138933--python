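"""Causal mediation analysis for microbiome and omics mediators.

Three flavours, all with a binary exposure (microbial community), a continuous
phenotype outcome, and confounders (batch) entering every model:

* distance-based: does overall community structure (a beta-diversity distance
  matrix) transmit the exposure effect?  The statistic aggregates, over
  principal coordinates of the distance matrix, the product of the
  exposure->axis and axis->outcome correlations weighted by the axis
  eigenvalue; the null distribution is obtained by jointly permuting the rows
  of the coordinate matrix.
* tree-based: for every high-rank internal node (phylum through family) of the
  taxonomy, the node's child subcomposition (rare children pruned, zeros
  replaced by 0.5, ALR-transformed against the most abundant child) enters a
  multivariate linear mediation model; the node scan localizes mediating
  clades.
* module-based: co-abundance module eigenvalues (plus standardized unclustered
  features) act as multiple mediators in one joint model.

Linear mediation uses the product-of-coefficients estimator (indirect =
sum_k alpha_k beta_k, which equals total - direct exactly in the linear
model); inference is by nonparametric case-resampling bootstrap with a
percentile two-sided P floored at 1/B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .preprocess import zero_replace

__all__ = [
    "MediationResult",
    "distance_mediation_test",
    "node_subcomposition",
    "alr_transform",
    "mediate_multivariate",
    "tree_mediation_scan",
    "module_mediation",
]

log = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """One mediation test: mediator id, effect decomposition, resampling P."""

    mediator: str
    mediator_type: str  # "distance" | "tree_node" | "modules"
    indirect: float
    direct: float
    total: float
    p_value: float
    n_resamples: int
    confounders: tuple = ()
    components: dict = field(default_factory=dict)
    ci: tuple | None = None

    def as_row(self) -> dict:
        return {
            "mediator_type": self.mediator_type, "mediator": self.mediator,
            "indirect": self.indirect, "direct": self.direct,
            "total": self.total, "P": self.p_value, "B": self.n_resamples,
            "confounders": ",".join(self.confounders),
        }


def _design(covariates, n) -> np.ndarray:
    """Covariates (DataFrame/array/None) -> dense design without intercept.

    Categorical columns are dummy-coded (first level dropped).
    """
    if covariates is None:
        return np.empty((n, 0))
    if isinstance(covariates, pd.DataFrame):
        mat = pd.get_dummies(covariates, drop_first=True).to_numpy(float)
    elif isinstance(covariates, pd.Series):
        mat = pd.get_dummies(covariates.to_frame(), drop_first=True).to_numpy(float)
    else:
        mat = np.asarray(covariates, float)
        if mat.ndim == 1:
            mat = mat[:, None]
    if mat.shape[0] != n:
        raise ValueError("covariates do not align with samples")
    return mat


def _residualize(mat: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``mat`` on [1, cov]."""
    n = mat.shape[0]
    x = np.column_stack([np.ones(n), cov])
    coef, *_ = np.linalg.lstsq(x, mat, rcond=None)
    return mat - x @ coef


def distance_mediation_test(dm, x, y, covariates=None, n_perm: int = 999,
                            seed: int = 0) -> MediationResult:
    """Distance-based test of microbiome mediation of a binary exposure effect.

    The distance matrix is Gower-centered and eigendecomposed; for each
    positive axis j the statistic accumulates w_j |cor(x, PC_j) cor(PC_j, y)|
    with eigenvalue weights w_j.  The null jointly permutes the sample rows of
    the coordinate matrix; P uses the add-one estimator.
    """
    d = dm.data if hasattr(dm, "data") else np.asarray(dm, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = d.shape[0]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant exposure or outcome")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    keep = vals > 1e-10
    vals, pcs = vals[keep], vecs[:, keep]
    w = vals / vals.sum()

    cov = _design(covariates, n)
    xr = _residualize(x[:, None], cov)[:, 0]
    yr = _residualize(y[:, None], cov)[:, 0]
    pcr = _residualize(pcs, cov)

    pcr_c = pcr - pcr.mean(axis=0)
    pc_std = pcr_c.std(axis=0)
    ok = pc_std > 0
    pcs_n = pcr_c[:, ok] / (n * pc_std[ok])  # so xr @ pcs_n = cov/ (sd_pc)
    wk = w[ok]
    sx, sy = xr.std(), yr.std()

    def _stat(xv, yv):
        a = (xv @ pcs_n) / sx
        bb = (yv @ pcs_n) / sy
        return np.sum(wk * np.abs(a * bb), axis=-1)

    t_obs = float(_stat(xr, yr))
    # permuting the PC rows jointly is equivalent to applying the inverse
    # permutation to (x, y) together; batch all permutations as one matmul
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    t_perm = _stat(xr[perms], yr[perms])
    hits = int(np.sum(t_perm >= t_obs - 1e-15))
    p = (1 + hits) / (1 + n_perm)
    return MediationResult(
        mediator=getattr(dm, "metric", "distance"), mediator_type="distance",
        indirect=t_obs, direct=np.nan, total=np.nan, p_value=p,
        n_resamples=n_perm,
        confounders=tuple(covariates.columns) if isinstance(covariates, pd.DataFrame) else (),
    )


def node_subcomposition(table: pd.DataFrame, tree: TreeNode, node,
                        min_detection: float = 0.10) -> pd.DataFrame:
    """Child subcomposition of one internal node.

    Child abundances are sums of descendant genus counts; children detected in
    ``min_detection`` of the samples or fewer are pruned; zeros are replaced by
    0.5 and rows renormalized.  Raises ``ValueError`` when fewer than two
    children survive (callers may skip the node).
    """
    if isinstance(node, str):
        node = tree.find(node)
    children = list(node.children)
    if len(children) < 2:
        raise ValueError(f"node {node.name} has < 2 children")
    cols = {}
    for child in children:
        leaves = [t.name for t in child.tips()] if child.children else [child.name]
        present = [l for l in leaves if l in table.columns]
        if present:
            cols[child.name] = table[present].sum(axis=1)
    sub = pd.DataFrame(cols)
    detection = (sub > 0).mean(axis=0)
    sub = sub.loc[:, detection > min_detection]
    if sub.shape[1] < 2:
        raise ValueError(f"node {node.name}: < 2 children after pruning")
    return zero_replace(sub)


def alr_transform(subcomposition: pd.DataFrame, reference: str | None = None)\
        -> pd.DataFrame:
    """Additive log-ratio transform against the most abundant child.

    Requires strictly positive entries (run zero replacement first); the
    reference defaults to the child with the largest mean relative abundance.
    """
    x = np.asarray(subcomposition, float)
    if np.any(x <= 0):
        raise ValueError("zero entries: apply zero replacement before ALR")
    if reference is None:
        reference = subcomposition.columns[int(np.argmax(x.mean(axis=0)))]
    ref = subcomposition[reference].to_numpy()
    others = [c for c in subcomposition.columns if c != reference]
    out = np.log(subcomposition[others].to_numpy() / ref[:, None])
    return pd.DataFrame(out, index=subcomposition.index,
                        columns=[f"log({c}/{reference})" for c in others])


def mediate_multivariate(x, M, y, covariates=None, B: int = 999,
                         seed: int = 0, mediator_id: str = "mediators",
                         mediator_type: str = "modules") -> MediationResult:
    """Linear causal mediation with multiple mediators, bootstrap inference.

    Mediator models M_k ~ x + covariates give alpha_k; the outcome model
    y ~ x + M + covariates gives the direct effect and beta_k; indirect =
    sum_k alpha_k beta_k (= total - direct in the linear case, asserted).
    Nonparametric bootstrap of cases with percentile CI; two-sided P =
    2 * min(P(indirect* <= 0), P(indirect* >= 0)), floored at 1/B.
    """
    x = np.asarray(x, float)
    m = np.asarray(M, float)
    if m.ndim == 1:
        m = m[:, None]
    y = np.asarray(y, float)
    n = len(y)
    if B < 199:
        raise ValueError("B must be >= 199")
    if m.shape[1] >= n / 2:
        raise ValueError("too many mediators for the sample size")
    cov = _design(covariates, n)
    med_names = list(M.columns) if isinstance(M, pd.DataFrame) else [
        f"m{k + 1}" for k in range(m.shape[1])]

    def _effects(xb, mb, yb, covb):
        ones = np.ones(len(yb))
        xm = np.column_stack([ones, xb, covb])
        full = np.column_stack([ones, xb, mb, covb])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient design")
        alphas = np.linalg.lstsq(xm, mb, rcond=None)[0][1]
        coef_full = np.linalg.lstsq(full, yb, rcond=None)[0]
        direct = coef_full[1]
        betas = coef_full[2:2 + mb.shape[1]]
        total = np.linalg.lstsq(xm, yb, rcond=None)[0][1]
        indirect = float(alphas @ betas)
        return indirect, float(direct), float(total), alphas, betas

    try:
        indirect, direct, total, alphas, betas = _effects(x, m, y, cov)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"rank-deficient mediation design ({err}); "
                         f"mediators: {med_names}") from err
    scale = max(1.0, abs(total))
    if abs(total - direct - indirect) > 1e-8 * scale:
        raise AssertionError("linear decomposition total = direct + indirect failed")

    rng = np.random.default_rng(seed)
    boot = np.empty(B)
    for b in range(B):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            try:
                boot[b] = _effects(x[idx], m[idx], y[idx], cov[idx])[0]
                break
            except np.linalg.LinAlgError:
                continue
        else:
            raise RuntimeError("bootstrap resamples persistently rank-deficient")
    p = 2.0 * min(np.mean(boot <= 0.0), np.mean(boot >= 0.0))
    p = float(min(1.0, max(p, 1.0 / B)))
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return MediationResult(
        mediator=mediator_id, mediator_type=mediator_type, indirect=indirect,
        direct=direct, total=total, p_value=p, n_resamples=B,
        confounders=tuple(covariates.columns) if isinstance(covariates, pd.DataFrame) else (),
        components={name: float(a * bb)
                    for name, a, bb in zip(med_names, alphas, betas)},
        ci=ci,
    )


SCAN_RANK_PREFIXES = ("p__", "c__", "o__", "f__")


def _scan_nodes(tree: TreeNode):
    """Internal nodes from phylum through family (root excluded)."""
    for node in tree.preorder(include_self=True):
        if node.children:
            name = node.name or ""
            if name == "root" or name[:3] in SCAN_RANK_PREFIXES:
                yield node


def tree_mediation_scan(table: pd.DataFrame, tree: TreeNode, x, y,
                        covariates=None, B: int = 199, seed: int = 0,
                        min_detection: float = 0.10) -> pd.DataFrame:
    """Causal mediation model on every high-rank internal node of the taxonomy.

    Each eligible node's pruned, zero-replaced, ALR-transformed child
    subcomposition enters a multivariate mediation model.  Returns a frame
    sorted by raw P (BH column included); skipped nodes are logged.
    """
    rng = np.random.default_rng(seed)
    results = []
    for node in _scan_nodes(tree):
        try:
            sub = node_subcomposition(table, tree, node, min_detection)
            mediators = alr_transform(sub)
            res = mediate_multivariate(
                x, mediators, y, covariates=covariates, B=B,
                seed=int(rng.integers(2 ** 31)),
                mediator_id=node.name, mediator_type="tree_node")
        except ValueError as err:
            log.info("node %s skipped: %s", node.name, err)
            continue
        results.append(res.as_row())
    out = pd.DataFrame(results).sort_values("P", kind="stable").reset_index(drop=True)
    if len(out):
        from .hoststats import bh_adjust
        out["P_BH"] = bh_adjust(out["P"].to_numpy())
    return out


def module_mediation(eigs: pd.DataFrame, x, y, covariates=None,
                     unclustered: pd.DataFrame | None = None, B: int = 999,
                     seed: int = 0) -> MediationResult:
    """Joint mediation through module eigenvalues (+ standardized grey features).

    All module eigenvalues, together with the standardized unclustered
    features, enter one multivariate mediation model; per-mediator component
    indirect effects alpha_k beta_k are reported in ``components``.
    """
    mats = [eigs]
    if unclustered is not None and unclustered.shape[1]:
        std = (unclustered - unclustered.mean()) / unclustered.std(ddof=1)
        mats.append(std)
    m = pd.concat(mats, axis=1)
    return mediate_multivariate(x, m, y, covariates=covariates, B=B, seed=seed,
                                mediator_id="modules", mediator_type="modules")
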