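"""Plaid-model biclustering with permutation-based layer retention.

The plaid model represents an expression matrix as a sum of layers, each
contributing ``theta_ij = mu + alpha_i + beta_j`` to a subset of genes
(rows, indicator rho) and samples (columns, indicator kappa).  Layers are
fitted greedily on the running residual; a fitted layer is kept only if its
sum of squares beats the best layer found on row-wise permuted copies of
the same residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BiclusterLayer",
    "PlaidParams",
    "preprocess_counts",
    "fit_layer",
    "layer_significance",
    "fit_plaid",
]


@dataclass
class BiclusterLayer:
    """One fitted plaid layer.

    ``alpha``/``beta`` are dense arrays aligned with ``gene_members`` /
    ``sample_members`` (NaN outside the membership); within the members they
    are least-squares row/column effects constrained to sum to zero.
    """

    gene_members: np.ndarray   # bool, per gene (rho)
    sample_members: np.ndarray  # bool, per sample (kappa)
    mu: float
    alpha: np.ndarray
    beta: np.ndarray
    layer_ss: float

    @property
    def n_genes(self) -> int:
        return int(self.gene_members.sum())

    @property
    def n_samples(self) -> int:
        return int(self.sample_members.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_genes < 2 or self.n_samples < 2

    def fitted_values(self) -> np.ndarray:
        """Dense matrix of theta over the full shape (zero outside members)."""
        G, S = self.alpha.shape[0], self.beta.shape[0]
        out = np.zeros((G, S))
        if self.is_empty:
            return out
        r = self.gene_members
        k = self.sample_members
        a = np.where(r, np.nan_to_num(self.alpha), 0.0)
        b = np.where(k, np.nan_to_num(self.beta), 0.0)
        out[np.ix_(r, k)] = self.mu + a[r][:, None] + b[k][None, :]
        return out

    def to_dict(self, gene_ids=None, sample_ids=None) -> dict:
        gi = np.flatnonzero(self.gene_members)
        si = np.flatnonzero(self.sample_members)
        return {
            "genes": [str(gene_ids[i]) if gene_ids is not None else int(i) for i in gi],
            "samples": [str(sample_ids[j]) if sample_ids is not None else int(j) for j in si],
            "mu": float(self.mu),
            "alpha": [float(self.alpha[i]) for i in gi],
            "beta": [float(self.beta[j]) for j in si],
            "layer_ss": float(self.layer_ss),
        }


@dataclass
class PlaidParams:
    """Tuning parameters for plaid fitting.

    ``row_release``/``col_release`` prune members whose individual fitted
    contribution falls below that fraction of the layer's mean member
    contribution.  ``n_shuffles`` controls the permutation retention test.
    """

    max_layers: int = 10
    backfit_iters: int = 3
    inner_iters: int = 10
    n_shuffles: int = 10
    row_release: float = 0.7
    col_release: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_layers < 1 or self.backfit_iters < 1 or self.inner_iters < 1:
            raise ValueError("iteration counts must be >= 1")
        for name in ("row_release", "col_release"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def preprocess_counts(counts, size_factors=None):
    """Counts -> plaid input: median-of-ratios normalize, log2(x+1), gene-center.

    ``counts`` is a genes x samples DataFrame (or array).  Returns an array
    (or DataFrame, matching the input) on the additive scale plaid assumes.
    """
    import pandas as pd

    from .de import estimate_size_factors

    is_df = isinstance(counts, pd.DataFrame)
    arr = counts.to_numpy(dtype=float) if is_df else np.asarray(counts, dtype=float)
    if size_factors is None:
        size_factors = estimate_size_factors(arr)
    norm = arr / np.asarray(size_factors)[None, :]
    logx = np.log2(norm + 1.0)
    centered = logx - logx.mean(axis=1, keepdims=True)
    if is_df:
        return pd.DataFrame(centered, index=counts.index, columns=counts.columns)
    return centered


def _empty_layer(G: int, S: int) -> BiclusterLayer:
    return BiclusterLayer(
        gene_members=np.zeros(G, bool),
        sample_members=np.zeros(S, bool),
        mu=0.0,
        alpha=np.full(G, np.nan),
        beta=np.full(S, np.nan),
        layer_ss=0.0,
    )


def _effects(Z: np.ndarray, rho: np.ndarray, kappa: np.ndarray):
    """Least-squares (mu, alpha, beta) on the member block; alpha/beta sum to 0."""
    B = Z[np.ix_(rho, kappa)]
    mu = B.mean()
    alpha_m = B.mean(axis=1) - mu
    beta_m = B.mean(axis=0) - mu
    alpha = np.full(Z.shape[0], np.nan)
    beta = np.full(Z.shape[1], np.nan)
    alpha[rho] = alpha_m
    beta[kappa] = beta_m
    return mu, alpha, beta


def _seed_memberships(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Initial rho/kappa from the leading singular vectors.

    Top- and bottom-quartile loading cuts of u1 and v1 give four candidate
    blocks (the sign of a singular vector is arbitrary and a layer shift may
    be negative); the candidate with the largest absolute block mean wins.
    Deterministic.
    """
    u, _, vt = np.linalg.svd(Z, full_matrices=False)
    u1, v1 = u[:, 0], vt[0, :]
    cuts_u = (u1 >= np.quantile(u1, 0.75), u1 <= np.quantile(u1, 0.25))
    cuts_v = (v1 >= np.quantile(v1, 0.75), v1 <= np.quantile(v1, 0.25))
    best = None
    for rho in cuts_u:
        for kappa in cuts_v:
            if rho.sum() < 2 or kappa.sum() < 2:
                continue
            m = abs(Z[np.ix_(rho, kappa)].mean())
            if best is None or m > best[0]:
                best = (m, rho, kappa)
    if best is None:  # degenerate; fall back to magnitude cut
        rho = np.abs(u1) >= np.quantile(np.abs(u1), 0.75)
        kappa = np.abs(v1) >= np.quantile(np.abs(v1), 0.75)
        return rho, kappa
    return best[1], best[2]


def _update_gene_members(Z, kappa, mu, beta):
    """rho_i = 1 iff including gene i (with its own LS alpha) reduces residual SS."""
    b = beta[kappa]
    Zk = Z[:, kappa]
    alpha_all = (Zk - mu - b[None, :]).mean(axis=1)
    theta = mu + alpha_all[:, None] + b[None, :]
    delta = (2.0 * Zk * theta - theta**2).sum(axis=1)
    return delta > 0.0, alpha_all


def _update_sample_members(Z, rho, mu, alpha):
    a = alpha[rho]
    Zr = Z[rho, :]
    beta_all = (Zr - mu - a[:, None]).mean(axis=0)
    theta = mu + a[:, None] + beta_all[None, :]
    delta = (2.0 * Zr * theta - theta**2).sum(axis=0)
    return delta > 0.0, beta_all


def _layer_ss(Z, rho, kappa, mu, alpha, beta) -> float:
    theta = mu + alpha[rho][:, None] + beta[kappa][None, :]
    return float((theta**2).sum())


def fit_layer(residual_matrix: np.ndarray, params: PlaidParams) -> BiclusterLayer:
    """Fit a single plaid layer to a residual matrix.

    Alternates least-squares effect estimation with membership updates
    (a row/column is a member iff its inclusion reduces residual SS; an
    exactly-zero change excludes), then releases weak members whose fitted
    contribution falls below ``release * mean contribution``.  Returns a
    possibly-empty layer.
    """
    Z = np.asarray(residual_matrix, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2 or Z.shape[1] < 2:
        raise ValueError("matrix must be 2-D with at least 2 rows and 2 columns")
    if not np.all(np.isfinite(Z)):
        raise ValueError("matrix contains non-finite entries")
    G, S = Z.shape
    if (Z**2).sum() == 0.0:
        return _empty_layer(G, S)

    rho, kappa = _seed_memberships(Z)
    if rho.sum() < 2 or kappa.sum() < 2:
        return _empty_layer(G, S)
    mu, alpha, beta = _effects(Z, rho, kappa)

    for _ in range(params.inner_iters):
        rho_prev, kappa_prev = rho, kappa
        rho, _ = _update_gene_members(Z, kappa, mu, beta)
        if rho.sum() < 2:
            return _empty_layer(G, S)
        mu, alpha, beta = _effects(Z, rho, kappa)

        kappa, _ = _update_sample_members(Z, rho, mu, alpha)
        if kappa.sum() < 2:
            return _empty_layer(G, S)
        mu, alpha, beta = _effects(Z, rho, kappa)
        if np.array_equal(rho, rho_prev) and np.array_equal(kappa, kappa_prev):
            break

    # release pruning: drop members contributing little fitted SS
    theta = mu + alpha[rho][:, None] + beta[kappa][None, :]
    gene_contrib = (theta**2).sum(axis=1)
    keep_g = gene_contrib >= params.row_release * gene_contrib.mean()
    samp_contrib = (theta**2).sum(axis=0)
    keep_s = samp_contrib >= params.col_release * samp_contrib.mean()
    if keep_g.sum() < 2 or keep_s.sum() < 2:
        return _empty_layer(G, S)
    if not (keep_g.all() and keep_s.all()):
        gi = np.flatnonzero(rho)[keep_g]
        si = np.flatnonzero(kappa)[keep_s]
        rho = np.zeros(G, bool)
        rho[gi] = True
        kappa = np.zeros(S, bool)
        kappa[si] = True
        mu, alpha, beta = _effects(Z, rho, kappa)

    ss = _layer_ss(Z, rho, kappa, mu, alpha, beta)
    alpha = np.where(rho, alpha, np.nan)
    beta = np.where(kappa, beta, np.nan)
    return BiclusterLayer(rho, kappa, float(mu), alpha, beta, ss)


def layer_significance(
    layer: BiclusterLayer,
    matrix: np.ndarray,
    params: PlaidParams,
    rng: np.random.Generator | None = None,
    null_matrix: np.ndarray | None = None,
) -> bool:
    """Permutation retention test for a fitted layer.

    Refits a layer on ``n_shuffles`` permuted copies: every row of the null
    matrix is independently shuffled and truncated to the fitted matrix's
    width.  The layer is retained iff its sum of squares strictly exceeds
    every permuted fit's.

    ``null_matrix`` defaults to ``matrix``; sequential clustering passes the
    full cohort matrix instead, so the null is exchangeability of each
    gene's values across the whole cohort.  That matters once the remaining
    samples form a single homogeneous group: a within-subset shuffle would
    leave a full-width layer untouched and the test would have no power.
    """
    if params.n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if layer.is_empty:
        return False
    if rng is None:
        rng = np.random.default_rng(params.seed)
    Z = np.asarray(matrix, dtype=float)
    null = Z if null_matrix is None else np.asarray(null_matrix, dtype=float)
    width = Z.shape[1]
    best_perm = 0.0
    for _ in range(params.n_shuffles):
        perm = np.empty((null.shape[0], width))
        for i in range(null.shape[0]):
            perm[i] = rng.permutation(null[i])[:width]
        pl = fit_layer(perm, params)
        best_perm = max(best_perm, pl.layer_ss)
    return layer.layer_ss > best_perm


def fit_plaid(matrix: np.ndarray, params: PlaidParams) -> list[BiclusterLayer]:
    """Sequentially fit retained plaid layers to a matrix.

    Each round fits a layer on the running residual, applies the permutation
    retention test, subtracts the fitted values, and backfits the effect
    parameters of all retained layers (memberships fixed).  Stops at
    ``max_layers`` or the first rejected layer.
    """
    Z = np.asarray(matrix, dtype=float)
    rng = np.random.default_rng(params.seed)
    residual = Z.copy()
    layers: list[BiclusterLayer] = []
    for _ in range(params.max_layers):
        layer = fit_layer(residual, params)
        if layer.is_empty or not layer_significance(layer, residual, params, rng):
            break
        residual -= layer.fitted_values()
        layers.append(layer)
        for _ in range(params.backfit_iters):
            for lay in layers:
                residual += lay.fitted_values()
                mu, alpha, beta = _effects(residual, lay.gene_members, lay.sample_members)
                lay.mu = float(mu)
                lay.alpha = np.where(lay.gene_members, alpha, np.nan)
                lay.beta = np.where(lay.sample_members, beta, np.nan)
                lay.layer_ss = _layer_ss(
                    residual, lay.gene_members, lay.sample_members, lay.mu, lay.alpha, lay.beta
                )
                residual -= lay.fitted_values()
    return layers
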