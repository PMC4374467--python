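"""Geometric morphometrics: Procrustes superimposition with object symmetry.

The shape phenotype mapped by this package is the symmetric component of
3D landmark configurations.  A structure with object symmetry (a skull) is
analyzed by superimposing each configuration together with its reflected,
relabeled copy; the per-specimen average of the two aligned copies is the
symmetric component and the half-difference the asymmetric one.  Shapes are
then orthogonally projected onto the tangent space at the consensus and a
PCA restricted to non-zero-variance directions gives the q-dimensional
score matrix used in QTL mapping.

For p bilateral landmark pairs and l midline landmarks (k = 2p + l), the
symmetric component varies in exactly 3p + 2l - 4 dimensions: 3p + 2l free
coordinates of a mirror-symmetric configuration minus 2 in-plane
translations, 1 in-plane rotation, and scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Per-specimen k x 3 landmark coordinates (mm)."""

    specimens: list[str]
    landmarks: list[str]
    coords: np.ndarray  # (n, k, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.specimens), len(self.landmarks), 3):
            raise ValueError("coordinate array must be (n_specimens, n_landmarks, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite landmark coordinates")

    @property
    def n(self) -> int:
        return len(self.specimens)

    @property
    def k(self) -> int:
        return len(self.landmarks)


@dataclass
class SymmetryMap:
    """Bilateral pairing of landmarks: (left, right) index pairs + midline."""

    pairs: list[tuple[int, int]]
    midline: list[int]

    def __post_init__(self) -> None:
        self.pairs = [tuple(p) for p in self.pairs]
        seen: list[int] = [i for pair in self.pairs for i in pair] + list(self.midline)
        if len(set(seen)) != len(seen):
            raise ValueError("a landmark appears more than once in the symmetry map")

    @property
    def k(self) -> int:
        return 2 * len(self.pairs) + len(self.midline)

    def validate_for(self, k: int) -> None:
        idx = set(i for pair in self.pairs for i in pair) | set(self.midline)
        if idx != set(range(k)):
            raise ValueError("symmetry map does not cover all landmark indices exactly once")

    def relabel_permutation(self, k: int) -> np.ndarray:
        """Index permutation swapping each (left, right) pair."""
        self.validate_for(k)
        perm = np.arange(k)
        for left, right in self.pairs:
            perm[left], perm[right] = right, left
        return perm


@dataclass
class RegionMap:
    """Anatomical region assignment; a landmark may belong to several regions."""

    regions: dict[int, tuple[str, ...]]  # landmark index -> region names

    def __post_init__(self) -> None:
        clean = {}
        for lm, regs in self.regions.items():
            regs = tuple(regs)
            if len(regs) == 0:
                raise ValueError(f"landmark {lm} assigned to no region")
            clean[int(lm)] = regs
        self.regions = clean

    @property
    def region_names(self) -> list[str]:
        names: list[str] = []
        for regs in self.regions.values():
            for r in regs:
                if r not in names:
                    names.append(r)
        return names

    def validate_for(self, k: int) -> None:
        if set(self.regions) != set(range(k)):
            raise ValueError("region map does not cover all landmark indices")


def read_symmetry_metadata(path) -> tuple[SymmetryMap, RegionMap | None]:
    """Read the {pairs, midline, regions} JSON metadata file (0-based indices)."""
    with open(path) as fh:
        meta = json.load(fh)
    sym = SymmetryMap([tuple(p) for p in meta["pairs"]], list(meta["midline"]))
    region = None
    if "regions" in meta and meta["regions"]:
        region = RegionMap({int(i): tuple(v) for i, v in meta["regions"].items()})
    return sym, region


@dataclass
class ShapeSpace:
    """Symmetric shape space: consensus, non-zero PC basis, scores, sizes.

    ``basis`` rows are orthonormal directions in flattened (3k) landmark
    space; ``scores @ basis + mean_tangent`` reproduces the tangent-space
    coordinates of the symmetric components.
    """

    specimens: list[str]
    landmarks: list[str]
    consensus: np.ndarray          # (k, 3), unit centroid size
    basis: np.ndarray              # (q, 3k)
    eigenvalues: np.ndarray        # (q,)
    scores: np.ndarray             # (n, q)
    centroid_sizes: np.ndarray     # (n,)
    mean_tangent: np.ndarray       # (3k,)
    symmetric: np.ndarray          # (n, k, 3) aligned symmetric components
    asymmetric: np.ndarray         # (n, k, 3)

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def q(self) -> int:
        return self.scores.shape[1]

    @property
    def k(self) -> int:
        return self.consensus.shape[0]

    @property
    def total_procrustes_ss(self) -> float:
        """Total sum of squares of the tangent coordinates about their mean."""
        return float(self.eigenvalues.sum() * (self.n - 1))

    def scores_to_displacement(self, vector: np.ndarray) -> np.ndarray:
        """Back-transform a q-vector of PC-space coefficients to k x 3 landmark displacements."""
        vector = np.asarray(vector, dtype=float)
        return (vector @ self.basis).reshape(self.k, 3)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared distances of landmarks to their centroid."""
    config = np.asarray(config, dtype=float)
    if not np.all(np.isfinite(config)):
        raise ValueError("non-finite coordinates")
    centered = config - config.mean(axis=-2, keepdims=True)
    size = np.sqrt((centered**2).sum(axis=(-2, -1)))
    return float(size) if size.ndim == 0 else size


def reflect_relabel(config: np.ndarray, sym: SymmetryMap) -> np.ndarray:
    """Mirror a configuration across the x = 0 plane and swap paired labels.

    An involution: applying it twice returns the input exactly.  The choice
    of reflection axis is a convention; any axis is equivalent after
    Procrustes alignment.
    """
    config = np.asarray(config, dtype=float)
    k = config.shape[-2]
    perm = sym.relabel_permutation(k)
    out = config.copy()
    out[..., 0] = -out[..., 0]
    return out[..., perm, :]


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||source @ R - target||_F (Kabsch)."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def generalized_procrustes(
    configs: np.ndarray, tol: float = 1e-10, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Full generalized Procrustes superimposition.

    Configurations are centered and scaled to unit centroid size, then
    iteratively rotated to the running consensus (itself re-centered and
    re-scaled each round) until the consensus changes by less than ``tol``
    in Frobenius norm.  Returns (aligned (n,k,3), consensus (k,3)).
    """
    configs = np.asarray(configs, dtype=float)
    n = configs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 configurations")
    centered = configs - configs.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centered**2).sum(axis=(1, 2)))
    if np.any(sizes < 1e-12):
        raise ValueError("degenerate configuration with all-coincident landmarks")
    aligned = centered / sizes[:, None, None]
    consensus = aligned[0].copy()
    consensus /= np.sqrt((consensus**2).sum())
    for _ in range(max_iter):
        for i in range(n):
            aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus)
        new = aligned.mean(axis=0)
        new -= new.mean(axis=0)
        norm = np.sqrt((new**2).sum())
        if norm < 1e-12:
            raise ValueError("degenerate consensus")
        new /= norm
        if np.sqrt(((new - consensus) ** 2).sum()) < tol:
            consensus = new
            break
        consensus = new
    for i in range(n):
        aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus)
    return aligned, consensus


def tangent_project(aligned_flat: np.ndarray, consensus_flat: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the tangent space at the consensus.

    Removes the component along the (unit-norm) consensus direction:
    v = (I - mu mu^T) x.
    """
    mu = consensus_flat / np.linalg.norm(consensus_flat)
    return aligned_flat - np.outer(aligned_flat @ mu, mu)


def tangent_pca(
    tangent_coords: np.ndarray, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """PCA of tangent coordinates restricted to non-zero eigenvalues.

    Retains eigenvalues > tol * largest.  Returns (scores, basis,
    eigenvalues, mean) with eigenvalues the per-dimension variances
    (SS / (n - 1)), sorted descending.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    X = np.asarray(tangent_coords, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2 / (n - 1)
    q = int(np.sum(lam > tol * lam[0])) if lam.size and lam[0] > 0 else 0
    if q == 0:
        raise ValueError("no shape variation")
    scores = u[:, :q] * s[:q]
    return scores, vt[:q], lam[:q], mean


def gpa_object_symmetry(
    data: LandmarkSet,
    sym: SymmetryMap,
    tol: float = 1e-10,
    eigen_tol: float = 1e-9,
) -> ShapeSpace:
    """GPA with object symmetry and symmetric-component shape space.

    The sample is doubled with reflected-relabeled copies, all 2n
    configurations are superimposed jointly, and the consensus is symmetrized
    so the symmetric/asymmetric split is exact.  Symmetric components are
    projected to the tangent space at the consensus and reduced by PCA to
    the non-zero-variance subspace.
    """
    sym.validate_for(data.k)
    reflected = reflect_relabel(data.coords, sym)
    doubled = np.concatenate([data.coords, reflected], axis=0)
    aligned, consensus = generalized_procrustes(doubled, tol=tol)
    # Symmetrize the consensus and re-align: removes the residual asymmetry
    # of the iterative fit so that reflect_relabel(consensus) == consensus.
    consensus = 0.5 * (consensus + reflect_relabel(consensus, sym))
    consensus -= consensus.mean(axis=0)
    consensus /= np.sqrt((consensus**2).sum())
    n = data.n
    for i in range(2 * n):
        aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus)
    orig, refl = aligned[:n], aligned[n:]
    symmetric = 0.5 * (orig + refl)
    asymmetric = 0.5 * (orig - refl)
    flat = symmetric.reshape(n, -1)
    tang = tangent_project(flat, consensus.ravel())
    scores, basis, lam, mean = tangent_pca(tang, tol=eigen_tol)
    sizes = centroid_size(data.coords)
    return ShapeSpace(
        specimens=list(data.specimens),
        landmarks=list(data.landmarks),
        consensus=consensus,
        basis=basis,
        eigenvalues=lam,
        scores=scores,
        centroid_sizes=np.atleast_1d(sizes),
        mean_tangent=mean,
        symmetric=symmetric,
        asymmetric=asymmetric,
    )


def symmetric_component(
    aligned_original: np.ndarray, aligned_reflected: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric and asymmetric components of one aligned pair."""
    a = np.asarray(aligned_original, dtype=float)
    b = np.asarray(aligned_reflected, dtype=float)
    if a.shape != b.shape:
        raise ValueError("aligned original and reflected copies differ in shape")
    return 0.5 * (a + b), 0.5 * (a - b)


def landmark_repeatability(
    replicate_a: LandmarkSet,
    replicate_b: LandmarkSet,
    cutoff: float,
    quantile: float = 0.5,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-landmark replicate placement error and drop list.

    A landmark is flagged when the chosen quantile (default: median, read as
    "consistently") of its per-specimen replicate distances exceeds the
    cutoff (mm).
    """
    if replicate_a.specimens != replicate_b.specimens:
        raise ValueError("replicates cover different specimens")
    if replicate_a.landmarks != replicate_b.landmarks:
        raise ValueError("replicates cover different landmarks")
    dist = np.linalg.norm(replicate_a.coords - replicate_b.coords, axis=2)  # (n, k)
    stat = np.quantile(dist, quantile, axis=0)
    table = pd.DataFrame(
        {
            "landmark": replicate_a.landmarks,
            "mean_error_mm": dist.mean(axis=0),
            "median_error_mm": np.median(dist, axis=0),
            "quantile_error_mm": stat,
            "max_error_mm": dist.max(axis=0),
            "flagged": stat > cutoff,
        }
    )
    drop = table.loc[table["flagged"], "landmark"].tolist()
    return table, drop
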