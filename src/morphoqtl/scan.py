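"""Single-QTL genome scans by multivariate Haley-Knott regression.

Shape (a q-dimensional PC-score matrix) is regressed on covariates plus the
P(HET) genotype probability at each grid position; the position's evidence
is Pillai's trace V = tr[H (H + E)^-1] converted through its approximate F
statistic to logP = -log10(p), the multivariate analog of the LOD score.
Scalar traits (log centroid size) use the classical RSS-based LOD.

Computation exploits the nesting structure: with the covariate design fixed,
H + E equals the covariate-only residual cross-product matrix at every
position, so a whole-genome scan reduces to one Cholesky factorization and
one matrix product.  Genome-wide significance comes from permutations that
reshuffle phenotype and covariates jointly against fixed genotypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, qr, solve_triangular

from .genetics import GenotypeProbabilities
from .morphometrics import ShapeSpace

logger = logging.getLogger("morphoqtl")

_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Covariates and the scan data bundle
# ---------------------------------------------------------------------------

@dataclass
class CovariateTable:
    """Per-individual covariates; the design matrix always has an intercept."""

    table: pd.DataFrame  # index: individuals; numeric columns

    def __post_init__(self) -> None:
        missing = self.table.isna().any(axis=1)
        if missing.any():
            dropped = list(self.table.index[missing])
            logger.warning("dropping %d individuals with missing covariates: %s",
                           len(dropped), dropped[:10])
            self.table = self.table.loc[~missing]

    @property
    def individuals(self) -> list[str]:
        return list(self.table.index)

    def design(self) -> tuple[np.ndarray, list[str]]:
        X = np.column_stack([np.ones(len(self.table)), self.table.to_numpy(dtype=float)])
        return X, ["intercept", *self.table.columns]


def check_full_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    """Raise naming the collinear columns if X is rank deficient."""
    names = names or [f"col{i}" for i in range(X.shape[1])]
    _, Rm, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rm))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[piv[i]] for i in range(rank, X.shape[1])]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


@dataclass
class QTLScanData:
    """Aligned inputs of a genome scan: grid, genotype regressors, phenotype, design."""

    grid: pd.DataFrame           # chrom, pos_cM, is_marker, marker
    G: np.ndarray                # (n, P) P(HET) at each grid position
    Y: np.ndarray                # (n, q) response scores (q=1 column for scalar traits)
    X: np.ndarray                # (n, c) covariate design including intercept
    covariate_names: list[str]
    individuals: list[str] | None = None

    def __post_init__(self) -> None:
        n = self.G.shape[0]
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if not (self.Y.shape[0] == n == self.X.shape[0]):
            raise ValueError("genotypes, phenotypes and covariates are not aligned")
        if self.G.shape[1] != len(self.grid):
            raise ValueError("genotype regressor matrix does not match the grid")
        check_full_rank(self.X, self.covariate_names)

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    def locus_index(self, chrom, pos_cm: float) -> int:
        sel = (self.grid["chrom"].astype(str) == str(chrom)) & np.isclose(
            self.grid["pos_cM"], pos_cm, atol=1e-9
        )
        idx = np.flatnonzero(sel.to_numpy())
        if idx.size != 1:
            raise KeyError(f"no unique grid position ({chrom}, {pos_cm})")
        return int(idx[0])


def make_scan_data(
    probs: GenotypeProbabilities,
    shape: ShapeSpace | np.ndarray,
    covars: CovariateTable,
) -> QTLScanData:
    """Assemble a scan bundle from genotype probabilities, shape scores and covariates.

    Individuals are intersected by id (order taken from the genotype data).
    """
    Y = shape.scores if isinstance(shape, ShapeSpace) else np.asarray(shape, dtype=float)
    ids = probs.individuals
    cov_ids = covars.individuals
    if isinstance(shape, ShapeSpace):
        shape_ids = shape.specimens
    else:
        shape_ids = ids
    keep = [i for i in ids if i in set(cov_ids) and i in set(shape_ids)]
    if len(keep) < len(ids):
        logger.warning("scan restricted to %d/%d individuals present in all inputs",
                       len(keep), len(ids))
    gsel = [ids.index(i) for i in keep]
    ysel = [shape_ids.index(i) for i in keep]
    csel = [cov_ids.index(i) for i in keep]
    X, names = covars.design()
    return QTLScanData(
        grid=probs.grid.copy(),
        G=probs.het[gsel],
        Y=Y[ysel],
        X=X[csel],
        covariate_names=names,
        individuals=keep,
    )


# ---------------------------------------------------------------------------
# Pillai trace test
# ---------------------------------------------------------------------------

@dataclass
class PillaiResult:
    V: float
    F: float
    df1: float
    df2: float
    p: float
    logP: float


def _residual_crossprod(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual SSCP of Y after least-squares projection on X, plus rank(X)."""
    Q, Rm = np.linalg.qr(X)
    diag = np.abs(np.diag(Rm))
    rank = int(np.sum(diag > diag.max() * max(X.shape) * np.finfo(float).eps))
    resid = Y - Q @ (Q.T @ Y)
    return resid.T @ resid, rank


def pillai_f_approx(V: float, q: int, h: int, df_e: int) -> tuple[float, float, float]:
    """Pillai's approximate F and its degrees of freedom.

    With s = min(q, h), m = (|q - h| - 1)/2, n' = (df_e - q - 1)/2:
    F = ((2n' + s + 1)/(2m + s + 1)) * V/(s - V), df1 = s(2m + s + 1),
    df2 = s(2n' + s + 1).  Exact when s = 1.
    """
    s = min(q, h)
    m = (abs(q - h) - 1) / 2.0
    nprime = (df_e - q - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nprime + s + 1)
    denom = s - V
    F = ((2 * nprime + s + 1) / (2 * m + s + 1)) * (V / denom) if denom > 0 else np.inf
    return F, df1, df2


def _logp_from_f(F, df1, df2):
    """-log10 p of an F statistic, safe for very small p."""
    with np.errstate(over="ignore"):
        return -stats.f.logsf(F, df1, df2) / _LN10


def pillai_test(Y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray,
                full_names: list[str] | None = None) -> PillaiResult:
    """Pillai-trace test of the terms in X_full that are absent from X_reduced.

    X_reduced must be nested within X_full (its columns spanned by X_full).
    V = tr[H (H + E)^-1] with H and E the hypothesis and error SSCP matrices
    of the nested least-squares fits; p from the approximate F.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Y.shape
    check_full_rank(X_full, full_names)
    E_red, rank_red = _residual_crossprod(Y, X_reduced)
    E_full, rank_full = _residual_crossprod(Y, X_full)
    h = rank_full - rank_red
    df_e = n - rank_full
    if h <= 0:
        raise ValueError("full design adds no terms beyond the reduced design")
    if df_e < q:
        raise ValueError(
            f"error df ({df_e}) below response dimension ({q}); reduce the response first"
        )
    H = E_red - E_full
    try:
        V = float(np.trace(np.linalg.solve(E_red, H)))
    except np.linalg.LinAlgError:
        # degenerate (noiseless) responses: H + E singular, use the pseudoinverse
        V = float(np.trace(np.linalg.pinv(E_red) @ H))
    V = min(max(V, 0.0), min(q, h))
    F, df1, df2 = pillai_f_approx(V, q, h, df_e)
    p = float(stats.f.sf(F, df1, df2))
    return PillaiResult(V, float(F), df1, df2, p, float(_logp_from_f(F, df1, df2)))


# ---------------------------------------------------------------------------
# Vectorized genome scans
# ---------------------------------------------------------------------------

def _scan_pillai_V(
    G: np.ndarray, Y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, int, np.ndarray]:
    """Pillai V of adding each column of G to the design X, vectorized.

    Because H + E equals the X-only residual SSCP T at every position,
    V_j = b_j^T T^-1 b_j with b_j = G~_j^T Y~ / ||G~_j||.  Monomorphic
    (zero-variance) regressors get V = 0.  Returns (V per position, rank X,
    informative-position mask).
    """
    n = Y.shape[0]
    Q, Rm = np.linalg.qr(X)
    diag = np.abs(np.diag(Rm))
    rank = int(np.sum(diag > diag.max() * max(X.shape) * np.finfo(float).eps))
    Yt = Y - Q @ (Q.T @ Y)
    Gt = G - Q @ (Q.T @ G)
    norms2 = (Gt**2).sum(axis=0)
    T = Yt.T @ Yt
    L = cholesky(T, lower=True)
    ok = norms2 > 1e-12 * n
    B = Gt.T @ Yt  # (P, q)
    V = np.zeros(G.shape[1])
    if ok.any():
        bs = B[ok] / np.sqrt(norms2[ok])[:, None]
        Z = solve_triangular(L, bs.T, lower=True)
        V[ok] = (Z**2).sum(axis=0)
    np.clip(V, 0.0, 1.0 - 1e-15, out=V)
    return V, rank, ok


def scan_shape(data: QTLScanData, warn_monomorphic: bool = True) -> pd.DataFrame:
    """Multivariate Haley-Knott genome scan scored by Pillai logP.

    At each grid position the additive backcross regressor P(HET) is tested
    against the covariate-only model.  Returns the grid with V, F, df1, df2
    and score = logP columns.
    """
    n, q = data.n, data.q
    V, rank, ok = _scan_pillai_V(data.G, data.Y, data.X)
    if not ok.all() and warn_monomorphic:
        warnings.warn("monomorphic genotype regressor at some positions; score set to 0")
    df_e = n - rank - 1
    if df_e < q + 2:
        raise ValueError(
            f"error df ({df_e}) must be at least q + 2 = {q + 2}; truncate the PC scores"
        )
    # vectorized F for h=1: F = ((df_e - q + 1)/q) * V/(1 - V)
    df1 = float(q)
    df2 = float(df_e - q + 1)
    F = (df2 / df1) * V / (1.0 - V)
    logP = _logp_from_f(F, df1, df2)
    out = data.grid.copy()
    out["V"] = V
    out["F"] = F
    out["df1"] = df1
    out["df2"] = df2
    out["score"] = logP
    return out


def scan_scalar(data: QTLScanData) -> pd.DataFrame:
    """RSS-based LOD scan of a scalar trait (Haley-Knott regression).

    LOD = (n/2) log10(RSS_reduced / RSS_full) at each grid position.
    """
    if data.q != 1:
        raise ValueError("scan_scalar expects a single-column response")
    n = data.n
    y = data.Y[:, 0]
    Q, _ = np.linalg.qr(data.X)
    yt = y - Q @ (Q.T @ y)
    Gt = data.G - Q @ (Q.T @ data.G)
    rss_red = float(yt @ yt)
    norms2 = (Gt**2).sum(axis=0)
    ok = norms2 > 1e-12 * n
    gain = np.zeros(data.G.shape[1])
    gain[ok] = (Gt[:, ok].T @ yt) ** 2 / norms2[ok]
    if not ok.all():
        warnings.warn("monomorphic genotype regressor at some positions; score set to 0")
    rss_full = np.maximum(rss_red - gain, np.finfo(float).tiny)
    lod = (n / 2.0) * np.log10(rss_red / rss_full)
    out = data.grid.copy()
    out["score"] = lod
    return out


# ---------------------------------------------------------------------------
# Permutation genome-wide threshold
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Null distribution of genome-wide maximum scores and its quantile threshold."""

    maxima: np.ndarray
    alpha: float
    n_perm: int
    seed: int | None

    @property
    def threshold(self) -> float:
        return self.quantile_threshold(self.alpha)

    def quantile_threshold(self, alpha: float) -> float:
        """Empirical (1 - alpha) quantile of the stored maxima (linear interpolation)."""
        return float(np.quantile(self.maxima, 1.0 - alpha, method="linear"))


def _max_scan_score(G, Y, X, kind: str) -> float:
    """Genome-wide maximum score for one (possibly permuted) dataset.

    For fixed degrees of freedom both logP (shape) and LOD (scalar) are
    monotone in the per-position statistic, so only the maximizer needs the
    tail transform.
    """
    n = Y.shape[0]
    if kind == "shape":
        V, rank, _ = _scan_pillai_V(G, Y, X)
        q = Y.shape[1]
        df_e = n - rank - 1
        v = V.max()
        df1, df2 = float(q), float(df_e - q + 1)
        F = (df2 / df1) * v / (1.0 - v)
        return float(_logp_from_f(F, df1, df2))
    Q, _ = np.linalg.qr(X)
    y = Y[:, 0]
    yt = y - Q @ (Q.T @ y)
    Gt = G - Q @ (Q.T @ G)
    rss_red = float(yt @ yt)
    norms2 = (Gt**2).sum(axis=0)
    ok = norms2 > 1e-12 * n
    gain = np.zeros(G.shape[1])
    gain[ok] = (Gt[:, ok].T @ yt) ** 2 / norms2[ok]
    rss_full = max(rss_red - gain.max(), np.finfo(float).tiny)
    return float((n / 2.0) * np.log10(rss_red / rss_full))


def genome_wide_threshold(
    data: QTLScanData,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    kind: str = "shape",
) -> PermutationResult:
    """Permutation genome-wide threshold for the maximum scan score.

    Phenotype rows and covariate rows are permuted jointly by one random
    permutation per iteration while the genotype probabilities stay fixed,
    so the phenotype-covariate linkage is preserved and only the genotype
    association is destroyed.  The threshold is the empirical (1 - alpha)
    quantile of the genome-wide maxima (linear interpolation of order
    statistics).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be at least 2")
    if kind not in ("shape", "scalar"):
        raise ValueError("kind must be 'shape' or 'scalar'")
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(data.n)
        maxima[b] = _max_scan_score(data.G, data.Y[perm], data.X[perm], kind)
    return PermutationResult(maxima=maxima, alpha=alpha, n_perm=n_perm, seed=seed)
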