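"""Sparse Gaussian graphical model inference over all modalities.

The conditional-dependence network is estimated by L1-penalized maximum
likelihood (graphical LASSO) on a covariance matrix computed from all
pairwise-complete observations, with the penalty selected by the extended
BIC.  A zero entry in the precision matrix Ω means the two features are
conditionally independent given the rest; nonzero entries become network
edges weighted by the partial correlation

    r_ab = −ω_ab / sqrt(ω_aa · ω_bb).

Solver: block coordinate descent over columns of W = Ω⁻¹ with a
coordinate-descent lasso inner solver (diagonal unpenalized), warm-started
along a decreasing λ path.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .core_data import FeatureTable

__all__ = [
    "CovarianceEstimate",
    "PrecisionNetwork",
    "pairwise_covariance",
    "nearest_psd",
    "graphical_lasso",
    "ebic",
    "default_lambda_grid",
    "lambda_path",
    "to_partial_correlations",
    "export_network",
    "kkt_violation",
    "edge_density_percent",
]

#: entries of Ω smaller than this in absolute value count as structural zeros
EDGE_TOL = 1e-10


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CovarianceEstimate:
    """Pairwise-complete sample covariance with bookkeeping.

    ``n_effective[a, b]`` is the number of subjects observed on both a and b
    (diagonal: per-feature observed counts); ``psd_repaired`` records whether
    eigenvalue clipping was applied to make S usable by the solver.
    """

    feature_ids: list
    S: np.ndarray
    n_effective: np.ndarray
    n_nominal: int
    psd_repaired: bool = False

    def __post_init__(self) -> None:
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")


@dataclass
class PrecisionNetwork:
    """Sparse precision estimate expressed as a partial-correlation network."""

    feature_ids: list
    omega: np.ndarray
    lambda_star: float
    gamma: float
    edges: list  # of (a, b, partial_correlation, modality_a, modality_b)
    ebic_path: list = field(default_factory=list)  # of (lambda, ebic, n_edges)
    n: int = 0

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# covariance

def pairwise_covariance(table: FeatureTable, min_pairs: int = 3) -> CovarianceEstimate:
    """Sample covariance over pairwise-complete observations.

    For each feature pair the mean is recomputed on the subjects observed on
    both features (n−1 denominator).  Pairs with fewer than ``min_pairs``
    joint observations get covariance 0 with a warning; a feature observed
    fewer than ``min_pairs`` times is an error.
    """
    if table.scale_state != "standardized":
        raise ValueError("pairwise covariance expects standardized input")
    vals = table.values
    obs = vals.notna().to_numpy().astype(np.int64)
    n_eff = obs.T @ obs
    counts = np.diag(n_eff)
    few = [f for f, c in zip(table.feature_ids, counts) if c < min_pairs]
    if few:
        raise ValueError(f"features with < {min_pairs} observations: {few}")
    S = vals.cov(min_periods=min_pairs).to_numpy()
    thin = np.isnan(S)
    if thin.any():
        warnings.warn(
            f"{int(thin.sum()) // 2} feature pairs have < {min_pairs} joint "
            "observations; their covariance entries are set to 0"
        )
        S[thin] = 0.0
    S = (S + S.T) / 2.0
    return CovarianceEstimate(
        feature_ids=table.feature_ids,
        S=S,
        n_effective=n_eff,
        n_nominal=vals.shape[0],
    )


def nearest_psd(cov: CovarianceEstimate, eps: float = 1e-6) -> CovarianceEstimate:
    """Clip eigenvalues below ``eps`` so the matrix is safely positive definite.

    Pairwise-complete covariances need not be PSD; the repair leaves PSD
    inputs untouched (``psd_repaired`` stays False).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    w, V = np.linalg.eigh(cov.S)
    if w.min() >= eps:
        return cov
    S = (V * np.maximum(w, eps)) @ V.T
    S = (S + S.T) / 2.0
    return CovarianceEstimate(
        feature_ids=cov.feature_ids,
        S=S,
        n_effective=cov.n_effective,
        n_nominal=cov.n_nominal,
        psd_repaired=True,
    )


# ---------------------------------------------------------------------------
# graphical lasso

@njit(cache=True)
def _lasso_cd(V, u, beta, lam, tol, max_iter):
    """Coordinate descent for min_b 0.5 b'Vb − u'b + lam·||b||₁ (warm start)."""
    p = beta.shape[0]
    r = u - V @ beta
    for _ in range(max_iter):
        dmax = 0.0
        for j in range(p):
            bj = beta[j]
            z = r[j] + V[j, j] * bj
            if z > lam:
                bn = (z - lam) / V[j, j]
            elif z < -lam:
                bn = (z + lam) / V[j, j]
            else:
                bn = 0.0
            d = bn - bj
            if d != 0.0:
                beta[j] = bn
                for i in range(p):
                    r[i] -= V[i, j] * d
                if abs(d) > dmax:
                    dmax = abs(d)
        if dmax < tol:
            break
    return beta


@njit(cache=True)
def _glasso_sweeps(S, W, B, lam, tol, max_iter, inner_tol, inner_iter):
    """Block coordinate descent over columns of W; returns iterations used."""
    p = S.shape[0]
    idx_buf = np.empty(p - 1, np.int64)
    for it in range(max_iter):
        delta = 0.0
        cnt = 0
        for j in range(p):
            k = 0
            for i in range(p):
                if i != j:
                    idx_buf[k] = i
                    k += 1
            V = np.empty((p - 1, p - 1))
            for a in range(p - 1):
                for b in range(p - 1):
                    V[a, b] = W[idx_buf[a], idx_buf[b]]
            u = np.empty(p - 1)
            for a in range(p - 1):
                u[a] = S[idx_buf[a], j]
            beta = np.empty(p - 1)
            for a in range(p - 1):
                beta[a] = B[idx_buf[a], j]
            beta = _lasso_cd(V, u, beta, lam, inner_tol, inner_iter)
            w12 = V @ beta
            for a in range(p - 1):
                i = idx_buf[a]
                delta += abs(W[i, j] - w12[a])
                cnt += 1
                W[i, j] = w12[a]
                W[j, i] = w12[a]
                B[i, j] = beta[a]
        if delta / cnt < tol:
            return it + 1
    return -(max_iter)


def graphical_lasso(
    cov,
    lam: float,
    tol: float = 1e-5,
    max_iter: int = 200,
    init: tuple | None = None,
    return_state: bool = False,
):
    """L1-penalized precision estimate, diagonal unpenalized.

    Maximizes log det Ω − tr(SΩ) − λ·Σ_{a≠b}|Ω_ab|.  At λ = 0 this is the
    unpenalized MLE, returned as the direct (Cholesky) inverse of S.  For
    λ > 0, block coordinate descent on W = Ω⁻¹ with soft-thresholded inner
    lasso solves; ``init=(W, B)`` warm-starts a path sweep.

    Returns Ω, or ``(Ω, (W, B))`` when ``return_state`` is true.
    """
    S = cov.S if isinstance(cov, CovarianceEstimate) else np.asarray(cov, float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = S.shape[0]
    if lam == 0.0:
        w = np.linalg.eigvalsh(S)
        if w.min() <= 0:
            raise ValueError("S must be positive definite for the unpenalized MLE")
        omega = np.linalg.inv(S)
        omega = (omega + omega.T) / 2.0
        state = (S.copy(), -omega / np.maximum(np.diag(omega), EDGE_TOL))
        return (omega, state) if return_state else omega

    if init is not None:
        W = init[0].copy()
        B = init[1].copy()
        np.fill_diagonal(W, np.diag(S))
    else:
        W = S.copy()
        B = np.zeros((p, p))
    n_it = _glasso_sweeps(
        S, W, B, lam, tol, max_iter, inner_tol=tol * 1e-2, inner_iter=1000
    )
    omega = _recover_omega(S, W, B)
    if n_it < 0:
        gap = _duality_gap(S, omega, lam)
        raise ConvergenceError(
            f"graphical lasso did not converge in {max_iter} sweeps "
            f"(duality gap {gap:.3e})"
        )
    return (omega, (W, B)) if return_state else omega


def _recover_omega(S, W, B) -> np.ndarray:
    p = S.shape[0]
    omega = np.zeros((p, p))
    for j in range(p):
        idx = np.arange(p) != j
        beta = B[idx, j]
        denom = W[j, j] - W[idx, j] @ beta
        o22 = 1.0 / denom
        omega[j, j] = o22
        omega[idx, j] += -beta * o22 / 2.0
        omega[j, idx] += -beta * o22 / 2.0
    # symmetrized by construction; enforce structural zeros where both
    # column solutions agree on zero
    zero = (np.abs(B) < EDGE_TOL) & (np.abs(B.T) < EDGE_TOL)
    np.fill_diagonal(zero, False)
    omega[zero] = 0.0
    return (omega + omega.T) / 2.0


def _duality_gap(S, omega, lam) -> float:
    off = np.abs(omega).sum() - np.abs(np.diag(omega)).sum()
    return float(np.trace(S @ omega) - S.shape[0] + lam * off)


def kkt_violation(omega: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Maximal off-diagonal violation of the stationarity conditions.

    For the penalized log-likelihood the gradient condition reads
    Ω⁻¹ − S = λ·Γ with Γ_ab ∈ ∂|Ω_ab|: equality to λ·sign(Ω_ab) on active
    entries, magnitude ≤ λ elsewhere.  Returns the largest excess.
    """
    R = np.linalg.inv(omega) - S
    p = S.shape[0]
    off = ~np.eye(p, dtype=bool)
    active = (np.abs(omega) > EDGE_TOL) & off
    inactive = ~active & off
    v = 0.0
    if inactive.any():
        v = max(v, float((np.abs(R[inactive]) - lam).max()))
    if active.any():
        v = max(v, float(np.abs(R[active] - lam * np.sign(omega[active])).max()))
    return v


# ---------------------------------------------------------------------------
# model selection

def ebic(omega: np.ndarray, cov, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a precision estimate.

    n·(tr(SΩ) − log det Ω) + E·log n + 4·E·γ·log p, with E the number of
    nonzero upper-triangle off-diagonal entries. γ = 0 recovers ordinary BIC.
    """
    S = cov.S if isinstance(cov, CovarianceEstimate) else np.asarray(cov, float)
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must be in [0, 1]")
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    p = omega.shape[0]
    E = int((np.abs(np.triu(omega, 1)) > EDGE_TOL).sum())
    return float(n * (np.trace(S @ omega) - logdet) + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def default_lambda_grid(cov, n_lambdas: int = 30, ratio: float = 0.01) -> np.ndarray:
    """Log-spaced grid from λ_max = max off-diagonal |S| down to ratio·λ_max."""
    S = cov.S if isinstance(cov, CovarianceEstimate) else np.asarray(cov, float)
    lam_max = float(np.abs(S - np.diag(np.diag(S))).max())
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, ratio * lam_max, n_lambdas)


def lambda_path(
    cov: CovarianceEstimate,
    n: int,
    gamma: float = 0.5,
    grid=None,
    tol: float = 1e-5,
    max_iter: int = 200,
):
    """Sweep the λ grid (decreasing, warm-started) and select by lowest eBIC.

    Returns ``(ebic_path, lambda_star, omega_star)``; ties in eBIC break
    toward the larger λ (sparser network).
    """
    if grid is None:
        grid = default_lambda_grid(cov)
    grid = np.asarray(sorted(grid, reverse=True), float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    path = []
    omegas = []
    state = None
    for lam in grid:
        omega, state = graphical_lasso(
            cov, float(lam), tol=tol, max_iter=max_iter, init=state, return_state=True
        )
        n_edges = int((np.abs(np.triu(omega, 1)) > EDGE_TOL).sum())
        path.append((float(lam), ebic(omega, cov, n, gamma), n_edges))
        omegas.append(omega)
    best = min(range(len(path)), key=lambda i: (path[i][1], i))
    return path, float(grid[best]), omegas[best]


# ---------------------------------------------------------------------------
# partial correlations / export

def to_partial_correlations(
    omega: np.ndarray,
    feature_ids,
    modality: pd.Series,
    lambda_star: float = np.nan,
    gamma: float = np.nan,
    ebic_path=None,
    n: int = 0,
) -> PrecisionNetwork:
    """Express a precision matrix as a partial-correlation edge list.

    Edge (a, b) exists iff ω_ab ≠ 0 (a < b in feature order), with weight
    r_ab = −ω_ab / sqrt(ω_aa·ω_bb); a positive precision entry therefore
    gives a *negative* partial correlation.
    """
    omega = np.asarray(omega, float)
    d = np.sqrt(np.diag(omega))
    edges = []
    p = omega.shape[0]
    feature_ids = list(feature_ids)
    for i in range(p):
        for j in range(i + 1, p):
            if abs(omega[i, j]) > EDGE_TOL:
                r = -omega[i, j] / (d[i] * d[j])
                a, b = feature_ids[i], feature_ids[j]
                edges.append((a, b, float(r), modality[a], modality[b]))
    return PrecisionNetwork(
        feature_ids=feature_ids,
        omega=omega,
        lambda_star=lambda_star,
        gamma=gamma,
        edges=edges,
        ebic_path=list(ebic_path or []),
        n=n,
    )


def infer_network(
    table: FeatureTable,
    gamma: float = 0.5,
    grid=None,
    lam: float | None = None,
    psd_eps: float = 1e-6,
) -> PrecisionNetwork:
    """Standardized table → eBIC-selected partial-correlation network.

    ``lam`` bypasses model selection and fits at a single penalty.
    """
    cov = nearest_psd(pairwise_covariance(table), eps=psd_eps)
    n = cov.n_nominal
    if lam is not None:
        omega = graphical_lasso(cov, lam)
        path = [(lam, ebic(omega, cov, n, gamma), int((np.abs(np.triu(omega, 1)) > EDGE_TOL).sum()))]
        lam_star = lam
    else:
        path, lam_star, omega = lambda_path(cov, n, gamma=gamma, grid=grid)
    return to_partial_correlations(
        omega, table.feature_ids, table.modality,
        lambda_star=lam_star, gamma=gamma, ebic_path=path, n=n,
    )


def edge_density_percent(n_edges: int, n_nodes: int) -> float:
    """Edge count as a percentage of all possible node pairs."""
    return 100.0 * n_edges / (n_nodes * (n_nodes - 1) / 2.0)


def export_network(network: PrecisionNetwork, path) -> dict:
    """Write the network as edge TSV, Cytoscape SIF, and JSON metadata.

    Returns the paths written (keys: edges, sif, meta).
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    edges_path = out / "edges.tsv"
    df = pd.DataFrame(
        network.edges,
        columns=["node_a", "node_b", "partial_correlation", "modality_a", "modality_b"],
    )
    df.insert(3, "sign", np.sign(df["partial_correlation"]).astype(int) if len(df) else [])
    df.to_csv(edges_path, sep="\t", index=False)
    sif_path = out / "network.sif"
    with open(sif_path, "w") as fh:
        for a, b, r, *_ in network.edges:
            rel = "pp" if r > 0 else "pn"
            fh.write(f"{a}\t{rel}\t{b}\n")
    meta_path = out / "network.json"
    meta = {
        "lambda_star": network.lambda_star,
        "gamma": network.gamma,
        "n": network.n,
        "n_features": len(network.feature_ids),
        "n_edges": network.n_edges,
        "density_percent": edge_density_percent(network.n_edges, len(network.feature_ids))
        if len(network.feature_ids) > 1 else 0.0,
        "ebic_path": [
            {"lambda": l, "ebic": e, "n_edges": k} for l, e, k in network.ebic_path
        ],
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"edges": edges_path, "sif": sif_path, "meta": meta_path}


def read_edge_list(path) -> pd.DataFrame:
    """Round-trip reader for the edge TSV written by :func:`export_network`."""
    return pd.read_csv(path, sep="\t")
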