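"""Sparse linear log-contrast regression on compositional taxa.

The model regresses a host feature y on the log relative abundances Z of p
taxa under the zero-sum constraint sum(beta) = 0, which makes the fit
invariant to per-sample compositional rescaling and avoids an arbitrary
reference taxon::

    minimize (1/2n) ||y - b0 - Z beta||^2 + lambda ||beta||_1
    subject to sum(beta) = 0

The solver is pairwise coordinate descent: each update moves mass along a
direction e_i - e_j (which preserves the constraint exactly) using the closed
form of the two-variable L1 problem; kink points yield exact zeros.  Model
selection follows the study protocol: 10-fold cross-validation over a
50-point lambda path for the tuning parameter, selection probabilities from
100 bootstrap resamples (bcv_prob) and from 100 half-size subsamples
(stability selection, stab_prob), an unpenalized constrained refit on the
stable support, and a network filter keeping taxa with stab_prob > 0.85 and
|refitted coefficient| >= 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "LogContrastProblem",
    "fit_logcontrast",
    "lambda_max",
    "lambda_path",
    "cv_lambda",
    "bootstrap_selection",
    "stability_selection",
    "refit_and_filter",
    "selection_protocol",
    "build_network",
]

SELECT_TOL = 1e-8  # coordinate descent yields exact zeros; anything above is selected


@dataclass
class LogContrastProblem:
    """Log relative abundances Z (samples x taxa), response y, taxon ids."""

    Z: np.ndarray
    y: np.ndarray
    taxa: list

    def __post_init__(self):
        self.Z = np.asarray(self.Z, float)
        self.y = np.asarray(self.y, float)
        if not (np.all(np.isfinite(self.Z)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite values in Z or y")
        if self.Z.shape[0] != self.y.shape[0]:
            raise ValueError("Z and y lengths differ")
        if self.Z.shape != (len(self.y), len(self.taxa)):
            raise ValueError("taxa ids must align with Z columns")
        closure = np.abs(np.exp(self.Z).sum(axis=1) - 1.0)
        if np.max(closure) > 1e-8:
            raise ValueError("rows of exp(Z) must sum to 1 (zero-replaced "
                             "relative abundances expected)")

    @classmethod
    def from_relative_abundance(cls, rel: pd.DataFrame, y) -> "LogContrastProblem":
        return cls(np.log(np.asarray(rel, float)), np.asarray(y, float),
                   list(rel.columns))

    def subset(self, idx) -> "LogContrastProblem":
        prob = object.__new__(LogContrastProblem)
        prob.Z, prob.y, prob.taxa = self.Z[idx], self.y[idx], self.taxa
        return prob


@njit(cache=True)
def _piece_obj(a, c, lam, bi, bj, t):
    return 0.5 * a * t * t - c * t + lam * (abs(bi + t) + abs(bj - t))


@njit(cache=True)
def _pair_step(a, c, lam, bi, bj):
    """Exact minimizer of 0.5*a*t^2 - c*t + lam*(|bi+t| + |bj-t|).

    Convex piecewise quadratic in t: the optimum is either a stationary point
    of one of the three smooth pieces (L1 slope in {-2 lam, 0, 2 lam}) or a
    kink (t = -bi or t = bj, where a coefficient hits exactly zero).
    Returns ``(t, gain)``; t = 0 unless the move strictly improves the
    objective (monotone descent rules out cycling across flat valleys).
    """
    g0 = _piece_obj(a, c, lam, bi, bj, 0.0)
    best_t = 0.0
    best_v = g0
    for delta in (-2.0 * lam, 0.0, 2.0 * lam):
        t = (c - delta) / a
        v = _piece_obj(a, c, lam, bi, bj, t)
        if v < best_v - 1e-15:
            best_v = v
            best_t = t
    for t in (-bi, bj):
        v = _piece_obj(a, c, lam, bi, bj, t)
        # prefer kinks on ties so coefficients land exactly on zero
        if v <= best_v + 1e-15:
            best_v = v
            best_t = t
    gain = g0 - best_v
    if gain <= 1e-15 * (1.0 + abs(g0)):
        return 0.0, 0.0
    return best_t, gain


@njit(cache=True)
def _cd_solve(G, q, beta, lam, tol, max_sweeps):
    """Pairwise coordinate descent; returns sweeps used or -1 on non-convergence."""
    p = G.shape[0]
    gb = np.zeros(p)
    for u in range(p):
        acc = 0.0
        for v in range(p):
            acc += G[u, v] * beta[v]
        gb[u] = acc
    total_gain = 0.0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        sweep_gain = 0.0
        for i in range(p - 1):
            for j in range(i + 1, p):
                a = G[i, i] + G[j, j] - 2.0 * G[i, j]
                if a <= 1e-12 * (G[i, i] + G[j, j] + 1e-300):
                    continue  # numerically identical columns
                c = (q[i] - q[j]) - (gb[i] - gb[j])
                t, gain = _pair_step(a, c, lam, beta[i], beta[j])
                if t != 0.0:
                    beta[i] += t
                    beta[j] -= t
                    for u in range(p):
                        gb[u] += t * (G[u, i] - G[u, j])
                    sweep_gain += gain
                    at = abs(t)
                    if at > max_delta:
                        max_delta = at
        total_gain += sweep_gain
        # converged when coefficients settle, or when a whole sweep no longer
        # improves the objective measurably (flat valley, p > n)
        if max_delta < tol or sweep_gain <= 1e-13 * (1.0 + total_gain):
            return sweep + 1
    return -1


@njit(cache=True)
def _prox_zerosum_l1(v, tau):
    """argmin_b 0.5||b - v||^2 + tau ||b||_1 subject to sum(b) = 0.

    Dual form: b = soft(v - nu, tau) with nu the root of the decreasing
    piecewise-linear h(nu) = sum_k soft(v_k - nu, tau); located exactly by
    bisection over the 2p breakpoints plus linear interpolation.
    """
    p = v.shape[0]
    bps = np.empty(2 * p)
    for k in range(p):
        bps[2 * k] = v[k] - tau
        bps[2 * k + 1] = v[k] + tau
    bps = np.sort(bps)
    a, b = 0, 2 * p - 1
    while b - a > 1:
        m = (a + b) // 2
        nu = bps[m]
        h = 0.0
        for k in range(p):
            d = v[k] - nu
            if d > tau:
                h += d - tau
            elif d < -tau:
                h += d + tau
        if h > 0:
            a = m
        else:
            b = m
    nu0, nu1 = bps[a], bps[b]
    h0 = 0.0
    h1 = 0.0
    for k in range(p):
        d = v[k] - nu0
        if d > tau:
            h0 += d - tau
        elif d < -tau:
            h0 += d + tau
        d = v[k] - nu1
        if d > tau:
            h1 += d - tau
        elif d < -tau:
            h1 += d + tau
    nu = nu0 if h0 == h1 else nu0 + (nu1 - nu0) * h0 / (h0 - h1)
    out = np.empty(p)
    for k in range(p):
        d = v[k] - nu
        if d > tau:
            out[k] = d - tau
        elif d < -tau:
            out[k] = d + tau
        else:
            out[k] = 0.0
    return out


@njit(cache=True)
def _fista_solve(G, q, beta, lam, L, tol, max_iter):
    """Accelerated proximal gradient with exact zero-sum+L1 prox.

    Gradient-restart variant; every iterate satisfies the constraint exactly
    and soft-thresholding yields exact zeros.  Returns iterations used or -1.
    """
    p = G.shape[0]
    x = _prox_zerosum_l1(beta - (G @ beta - q) / L, lam / L)
    z = x.copy()
    tk = 1.0
    for it in range(max_iter):
        grad = G @ z - q
        x_new = _prox_zerosum_l1(z - grad / L, lam / L)
        if np.dot(z - x_new, x_new - x) > 0:  # momentum points uphill: restart
            tk = 1.0
            z = x.copy()
            grad = G @ z - q
            x_new = _prox_zerosum_l1(z - grad / L, lam / L)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        z = x_new + ((tk - 1.0) / t_next) * (x_new - x)
        d = np.abs(x_new - x).max()
        x = x_new
        tk = t_next
        if d < tol:
            for k in range(p):
                beta[k] = x[k]
            return it + 1
    for k in range(p):
        beta[k] = x[k]
    return -1


def _lipschitz(G: np.ndarray) -> float:
    return float(np.linalg.eigvalsh(G)[-1]) * 1.0001 + 1e-12


@njit(cache=True)
def _solve_one(G, q, beta, lam, L, tol, max_iter, polish_sweeps):
    """FISTA to tolerance, then pairwise-CD sweeps to settle kinks exactly."""
    it = _fista_solve(G, q, beta, lam, L, tol, max_iter)
    _cd_solve(G, q, beta, lam, tol, polish_sweeps)
    return it


def _centered(problem: LogContrastProblem):
    zc = problem.Z - problem.Z.mean(axis=0)
    yc = problem.y - problem.y.mean()
    return zc, yc


def lambda_max(problem: LogContrastProblem) -> float:
    """Smallest lambda with beta = 0: half the range of the centered gradient."""
    zc, yc = _centered(problem)
    q = zc.T @ yc / len(yc)
    return float((q.max() - q.min()) / 2.0)


def lambda_path(problem: LogContrastProblem, n_lambda: int = 50,
                decades: float = 3.0) -> np.ndarray:
    lmax = max(lambda_max(problem), 1e-12)
    return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_lambda)


def fit_logcontrast(problem: LogContrastProblem, lam: float,
                    beta0: np.ndarray | None = None, tol: float = 1e-7,
                    max_sweeps: int = 20_000):
    """Solve the zero-sum L1 problem at one lambda.

    Returns ``(beta, intercept)``; ``beta`` sums to zero to within 1e-8 by
    construction (pairwise updates preserve the constraint exactly).
    """
    n, p = problem.Z.shape
    if n < 3 or p < 2:
        raise ValueError("need n >= 3 and p >= 2")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    zc, yc = _centered(problem)
    G = zc.T @ zc / n
    q = zc.T @ yc / n
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    # solve well below the nominal tolerance so independent runs of the same
    # problem (e.g. under compositional rescaling) agree to < 1e-8
    it = _solve_one(G, q, beta, float(lam), _lipschitz(G), 0.01 * tol,
                    max_sweeps * 10, 100)
    if it < 0:
        raise RuntimeError(
            f"solver did not converge in {max_sweeps * 10} iterations "
            f"(lambda={lam:.3g}, n={n}, p={p})"
        )
    intercept = float(problem.y.mean() - problem.Z.mean(axis=0) @ beta)
    return beta, intercept


def _path_fit(problem: LogContrastProblem, lambdas: np.ndarray,
              tol: float = 1e-6, max_iter: int = 300) -> np.ndarray:
    """Warm-started coefficients along a descending lambda path (p x L).

    Path fits feed model selection (CV prediction error), so they run on a
    capped iteration budget with a model-selection tolerance; the fit at the
    chosen lambda is always re-solved to full tolerance by the caller.  The
    solver iterates are deterministic and compositionally invariant either
    way.
    """
    n, p = problem.Z.shape
    zc, yc = _centered(problem)
    G = zc.T @ zc / n
    q = zc.T @ yc / n
    L = _lipschitz(G)
    betas = np.zeros((p, len(lambdas)))
    beta = np.zeros(p)
    for l, lam in enumerate(lambdas):
        _solve_one(G, q, beta, float(lam), L, tol, max_iter, 10)
        betas[:, l] = beta
    return betas


def cv_lambda(problem: LogContrastProblem, n_folds: int = 10, seed: int = 0,
              n_lambda: int = 50, decades: float = 3.0):
    """Choose lambda by K-fold cross-validation on the squared error.

    Returns ``(lambda, curve)`` where ``curve`` is a DataFrame with the lambda
    grid and mean CV MSE.  Ties prefer the larger lambda (sparser model).
    """
    n = len(problem.y)
    if not 2 <= n_folds <= n:
        raise ValueError("need 2 <= n_folds <= n")
    lambdas = lambda_path(problem, n_lambda=n_lambda, decades=decades)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    mse = np.zeros((n_folds, len(lambdas)))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        train = problem.subset(train_idx)
        betas = _path_fit(train, lambdas)
        b0 = train.y.mean() - train.Z.mean(axis=0) @ betas
        pred = problem.Z[test_idx] @ betas + b0
        mse[f] = ((problem.y[test_idx, None] - pred) ** 2).mean(axis=0)
    mean_mse = mse.mean(axis=0)
    best = int(np.argmin(mean_mse))  # first (largest) lambda wins ties
    curve = pd.DataFrame({"lambda": lambdas, "cv_mse": mean_mse})
    return float(lambdas[best]), curve


def _resample_selection(problem: LogContrastProblem, B: int, seed: int,
                        draw, n_folds: int) -> np.ndarray:
    """Shared engine: selection frequencies over B resamples of the CV+fit."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    p = problem.Z.shape[1]
    hits = np.zeros(p)
    for b in range(B):
        for attempt in range(100):
            idx = draw(rng)
            sub = problem.subset(idx)
            if np.std(sub.y) > 0:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate resample")
        lam, _ = cv_lambda(sub, n_folds=min(n_folds, len(idx)),
                           seed=int(rng.integers(2 ** 31)))
        beta, _ = fit_logcontrast(sub, lam)
        hits += np.abs(beta) > SELECT_TOL
    return hits / B


def bootstrap_selection(problem: LogContrastProblem, B: int = 100,
                        seed: int = 0, n_folds: int = 10) -> np.ndarray:
    """bcv_prob: selection frequency over B bootstrap resamples (with replacement)."""
    n = len(problem.y)
    return _resample_selection(
        problem, B, seed, lambda rng: rng.integers(0, n, size=n), n_folds)


def stability_selection(problem: LogContrastProblem, B: int = 100,
                        frac: float = 0.5, seed: int = 0,
                        n_folds: int = 10) -> np.ndarray:
    """stab_prob: selection frequency over B subsamples without replacement."""
    if not 0 < frac < 1:
        raise ValueError("frac must lie in (0, 1)")
    n = len(problem.y)
    m = int(np.floor(frac * n))
    if m < 6:
        raise ValueError("subsample size too small (< 6)")
    return _resample_selection(
        problem, B, seed, lambda rng: rng.choice(n, size=m, replace=False), n_folds)


def constrained_refit(problem: LogContrastProblem, support: np.ndarray) -> np.ndarray:
    """Unpenalized least squares on the support under the zero-sum constraint."""
    p = problem.Z.shape[1]
    beta = np.zeros(p)
    s = np.flatnonzero(support)
    if s.size <= 1:
        return beta  # a single taxon is forced to zero by the constraint
    zc, yc = _centered(problem)
    zs = zc[:, s]
    k = s.size
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = zs.T @ zs
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([zs.T @ yc, [0.0]])
    sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    b = sol[:k]
    b -= b.mean()  # enforce the constraint exactly against round-off
    beta[s] = b
    return beta


def refit_and_filter(problem: LogContrastProblem, stab_prob: np.ndarray,
                     stab_cut: float = 0.85, coef_cut: float = 0.1,
                     bcv_prob: np.ndarray | None = None) -> pd.DataFrame:
    """SelectionResult: refit on the stable support and apply the network filter.

    Support = {stab_prob > stab_cut} (strict); the refitted coefficients are
    the constrained least squares on that support; taxa with
    |refitted_coef| < coef_cut are excluded from the network (``in_network``
    False) but all taxa remain in the report.
    """
    if not (0 <= stab_cut < 1 and coef_cut >= 0):
        raise ValueError("cuts must satisfy 0 <= stab_cut < 1 and coef_cut >= 0")
    stab_prob = np.asarray(stab_prob, float)
    support = stab_prob > stab_cut
    beta = constrained_refit(problem, support)
    out = pd.DataFrame({
        "taxon": problem.taxa,
        "stab_prob": stab_prob,
        "refitted_coef": beta,
        "in_support": support,
        "in_network": support & (np.abs(beta) >= coef_cut),
    }).set_index("taxon")
    if bcv_prob is not None:
        out.insert(0, "bcv_prob", np.asarray(bcv_prob, float))
    return out


def selection_protocol(problem: LogContrastProblem, B: int = 100,
                       frac: float = 0.5, seed: int = 0, stab_cut: float = 0.85,
                       coef_cut: float = 0.1, with_bootstrap: bool = True)\
        -> pd.DataFrame:
    """Full study protocol for one response: bcv_prob, stab_prob, refit, filter."""
    bcv = bootstrap_selection(problem, B=B, seed=seed) if with_bootstrap else None
    stab = stability_selection(problem, B=B, frac=frac, seed=seed + 1)
    return refit_and_filter(problem, stab, stab_cut=stab_cut, coef_cut=coef_cut,
                            bcv_prob=bcv)


def build_network(results: dict, response_annotations: dict | None = None)\
        -> pd.DataFrame:
    """Bipartite taxon <-> response edge list from per-response SelectionResults.

    Edge weight = |refitted_coef|, with the sign recorded; only taxa passing
    the network filter contribute edges.
    """
    rows = []
    for response, table in results.items():
        sel = table[table["in_network"]]
        for taxon, row in sel.iterrows():
            rows.append({
                "taxon": taxon,
                "response": response,
                "weight": abs(row["refitted_coef"]),
                "sign": int(np.sign(row["refitted_coef"])),
                "refitted_coef": row["refitted_coef"],
                "stab_prob": row["stab_prob"],
                "bcv_prob": row.get("bcv_prob", np.nan),
                "annotation": (response_annotations or {}).get(response, ""),
            })
    cols = ["taxon", "response", "weight", "sign", "refitted_coef",
            "stab_prob", "bcv_prob", "annotation"]
    return pd.DataFrame(rows, columns=cols)


def network_to_graph(edges: pd.DataFrame):
    """Edge list -> networkx bipartite graph (for GML/graph-text export)."""
    import networkx as nx

    g = nx.Graph()
    for _, e in edges.iterrows():
        g.add_node(e["taxon"], kind="taxon")
        g.add_node(e["response"], kind="response", annotation=e["annotation"])
        g.add_edge(e["taxon"], e["response"], weight=float(e["weight"]),
                   sign=int(e["sign"]))
    return g
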