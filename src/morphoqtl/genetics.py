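"""Genetic-map arithmetic and genotype probabilities for an N2 backcross.

An N2 backcross (F1 hybrid crossed back to one parental inbred) has two
possible genotype classes at every autosomal locus: homozygous for the
recurrent parent (HOM) or heterozygous (HET).  Observed marker genotypes are
noisy and incomplete, so genotype probabilities on a cM grid are computed
with a two-state hidden Markov model whose transition probabilities come
from a map function.  The Carter-Falconer map function is used by default
because it models the strong crossover interference seen in the mouse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

# Genotype codes used throughout the package.
HOM = 0  # homozygous for the recurrent inbred parent
HET = 1  # heterozygous (F1-derived)
MISSING = -1

GENO_CODE_MAP = {"A": HOM, "H": HET, "-": MISSING}
GENO_CODE_INV = {HOM: "A", HET: "H", MISSING: "-"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeMap:
    """Ordered markers of one chromosome with cM (and optional bp) positions."""

    name: str
    markers: list[str]
    cm: np.ndarray
    bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cm = np.asarray(self.cm, dtype=float)
        if len(self.markers) != self.cm.size:
            raise ValueError(f"chromosome {self.name}: marker/position length mismatch")
        if self.cm.size == 0:
            raise ValueError(f"chromosome {self.name}: no markers")
        if not np.all(np.isfinite(self.cm)):
            raise ValueError(f"chromosome {self.name}: non-finite cM position")
        if np.any(self.cm < 0):
            raise ValueError(f"chromosome {self.name}: negative cM position")
        if np.any(np.diff(self.cm) <= 0):
            raise ValueError(f"chromosome {self.name}: cM positions not strictly increasing")
        if self.bp is not None:
            self.bp = np.asarray(self.bp, dtype=float)
            if self.bp.size != self.cm.size:
                raise ValueError(f"chromosome {self.name}: bp present for only some markers")
            if np.any(np.diff(self.bp) <= 0):
                raise ValueError(f"chromosome {self.name}: bp positions not strictly increasing")

    @property
    def n_markers(self) -> int:
        return self.cm.size


@dataclass
class GeneticMap:
    """Ordered collection of chromosome maps."""

    chromosomes: list[ChromosomeMap]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        all_markers = [m for c in self.chromosomes for m in c.markers]
        if len(set(all_markers)) != len(all_markers):
            raise ValueError("duplicate marker names across the map")

    @property
    def chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def marker_names(self) -> list[str]:
        return [m for c in self.chromosomes for m in c.markers]

    def chromosome(self, name: str) -> ChromosomeMap:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome named {name!r}")


@dataclass
class MarkerGenotypes:
    """Observed marker genotypes, coded HOM/HET/MISSING per individual."""

    individuals: list[str]
    markers: list[str]
    codes: np.ndarray  # (n_individuals, n_markers) int8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.individuals), len(self.markers)):
            raise ValueError("genotype matrix shape does not match individuals x markers")
        valid = np.isin(self.codes, (HOM, HET, MISSING))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid genotype code {self.codes[i, j]} for individual "
                f"{self.individuals[i]!r} at marker {self.markers[j]!r}"
            )


@dataclass
class HMMConfig:
    """Settings of the genotype-probability HMM."""

    genotyping_error_rate: float = 1e-4
    grid_step: float = 1.0
    map_function: str = "carter_falconer"

    def __post_init__(self) -> None:
        if not 0.0 <= self.genotyping_error_rate < 0.5:
            raise ValueError("genotyping_error_rate must lie in [0, 0.5)")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.map_function != "carter_falconer":
            raise ValueError(f"unsupported map function {self.map_function!r}")


@dataclass
class GenotypeProbabilities:
    """Posterior genotype probabilities on the scan grid.

    ``grid`` holds one record per grid position (chrom, pos_cM, is_marker,
    marker name or ''); ``probs`` is (n_individuals, n_positions, 2) with the
    last axis ordered (HOM, HET).
    """

    individuals: list[str]
    grid: pd.DataFrame
    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.probs.shape != (len(self.individuals), len(self.grid), 2):
            raise ValueError("probability array shape mismatch")

    @property
    def het(self) -> np.ndarray:
        """P(HET) regressor matrix, individuals x grid positions."""
        return self.probs[:, :, 1]

    def to_frame(self) -> pd.DataFrame:
        """Wide export: one row per (individual, position)."""
        n, p, _ = self.probs.shape
        return pd.DataFrame(
            {
                "individual": np.repeat(self.individuals, p),
                "chrom": np.tile(self.grid["chrom"].to_numpy(), n),
                "pos_cM": np.tile(self.grid["pos_cM"].to_numpy(), n),
                "p_hom": self.probs[:, :, 0].ravel(),
                "p_het": self.probs[:, :, 1].ravel(),
            }
        )


# ---------------------------------------------------------------------------
# Carter-Falconer map function pair
# ---------------------------------------------------------------------------

def inverse_map_function_cf(r):
    """Genetic distance (cM) for a recombination fraction under Carter-Falconer.

    d(r) = 12.5 * ln((1 + 2r) / (1 - 2r)) + 25 * arctan(2r).  Strictly
    increasing on [0, 0.5) and diverging at r = 0.5.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 12.5 * np.log((1 + 2 * r) / (1 - 2 * r)) + 25.0 * np.arctan(2 * r)
    return float(d) if d.ndim == 0 else d


_R_UPPER = 0.5 * (1 - 1e-14)
_D_UPPER = 12.5 * np.log((1 + 2 * _R_UPPER) / (1 - 2 * _R_UPPER)) + 25.0 * np.arctan(2 * _R_UPPER)


def map_function_cf(d):
    """Recombination fraction for a genetic distance (cM), Carter-Falconer.

    The forward map has no closed form; it is obtained by Brent root finding
    on the closed-form inverse, to absolute tolerance 1e-12 on r.
    """
    d_arr = np.atleast_1d(np.asarray(d, dtype=float))
    if np.any(d_arr < 0):
        raise ValueError("genetic distance must be non-negative")
    out = np.empty_like(d_arr)
    for i, di in enumerate(d_arr.ravel()):
        if di == 0.0:
            out.ravel()[i] = 0.0
        elif di >= _D_UPPER:
            out.ravel()[i] = _R_UPPER
        else:
            out.ravel()[i] = brentq(
                lambda r: 12.5 * np.log((1 + 2 * r) / (1 - 2 * r)) + 25.0 * np.arctan(2 * r) - di,
                0.0,
                _R_UPPER,
                xtol=1e-12,
            )
    return float(out[0]) if np.asarray(d).ndim == 0 else out.reshape(np.shape(d))


# ---------------------------------------------------------------------------
# Scan grid
# ---------------------------------------------------------------------------

def build_chromosome_grid(cm: np.ndarray, step: float, tol: float = 1e-9):
    """Grid positions for one chromosome: markers plus uniform pseudomarkers.

    Each inter-marker interval is subdivided into the fewest equal segments
    whose spacing does not exceed ``step``.  Returns (positions, is_marker).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    cm = np.asarray(cm, dtype=float)
    if cm.size == 0:
        raise ValueError("empty chromosome")
    if cm.size == 1:
        return cm.copy(), np.array([True])
    positions = [cm[0]]
    is_marker = [True]
    for left, right in zip(cm[:-1], cm[1:]):
        span = right - left
        nseg = max(1, int(np.ceil(span / step - tol)))
        inner = left + span * np.arange(1, nseg) / nseg
        positions.extend(inner.tolist())
        is_marker.extend([False] * (nseg - 1))
        positions.append(right)
        is_marker.append(True)
    positions = np.asarray(positions)
    is_marker = np.asarray(is_marker, dtype=bool)
    # de-duplicate (tolerance in cM); markers win over pseudomarkers
    keep = np.ones(positions.size, dtype=bool)
    for i in range(1, positions.size):
        if positions[i] - positions[i - 1] <= tol:
            keep[i - 1 if is_marker[i] else i] = False
    return positions[keep], is_marker[keep]


def build_position_grid(gmap: GeneticMap, step: float) -> pd.DataFrame:
    """Scan grid across all chromosomes (markers tagged, pseudomarkers '')."""
    rows = []
    for chrom in gmap.chromosomes:
        pos, is_m = build_chromosome_grid(chrom.cm, step)
        names = iter(chrom.markers)
        for p, m in zip(pos, is_m):
            rows.append((chrom.name, p, m, next(names) if m else ""))
    return pd.DataFrame(rows, columns=["chrom", "pos_cM", "is_marker", "marker"])


# ---------------------------------------------------------------------------
# Hidden Markov model (forward-backward)
# ---------------------------------------------------------------------------

def _emission(obs: np.ndarray, eps: float) -> np.ndarray:
    """Emission probabilities, (n, 2): P(observed | true state)."""
    n = obs.size
    em = np.ones((n, 2))
    typed = obs != MISSING
    em[typed, 0] = np.where(obs[typed] == HOM, 1 - eps, eps)
    em[typed, 1] = np.where(obs[typed] == HET, 1 - eps, eps)
    return em


def _forward_backward_chrom(obs: np.ndarray, pos: np.ndarray, eps: float) -> np.ndarray:
    """Posterior state probabilities for one chromosome.

    obs: (n_individuals, n_positions) codes; pos: grid cM.  Two-state chain
    with initial distribution (1/2, 1/2) and symmetric transitions whose
    off-diagonal is the Carter-Falconer recombination fraction of the gap.
    Scaled forward-backward, vectorized over individuals.
    """
    n, P = obs.shape
    r = map_function_cf(np.diff(pos)) if P > 1 else np.empty(0)
    alpha = np.empty((n, P, 2))
    scale = np.empty((n, P))
    em0 = _emission(obs[:, 0], eps)
    a = 0.5 * em0
    scale[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / scale[:, 0, None]
    for t in range(1, P):
        rt = r[t - 1]
        prev = alpha[:, t - 1]
        pred = np.empty_like(prev)
        pred[:, 0] = prev[:, 0] * (1 - rt) + prev[:, 1] * rt
        pred[:, 1] = prev[:, 0] * rt + prev[:, 1] * (1 - rt)
        a = pred * _emission(obs[:, t], eps)
        scale[:, t] = a.sum(axis=1)
        alpha[:, t] = a / scale[:, t, None]
    beta = np.ones((n, 2))
    post = np.empty((n, P, 2))
    post[:, P - 1] = alpha[:, P - 1]
    for t in range(P - 2, -1, -1):
        rt = r[t]
        bt = beta * _emission(obs[:, t + 1], eps)
        nb = np.empty_like(bt)
        nb[:, 0] = bt[:, 0] * (1 - rt) + bt[:, 1] * rt
        nb[:, 1] = bt[:, 0] * rt + bt[:, 1] * (1 - rt)
        beta = nb / scale[:, t + 1, None]
        g = alpha[:, t] * beta
        post[:, t] = g / g.sum(axis=1, keepdims=True)
    return post


def genotype_probabilities(
    geno: MarkerGenotypes, gmap: GeneticMap, cfg: HMMConfig | None = None
) -> GenotypeProbabilities:
    """Posterior genotype probabilities on the cM grid.

    Pseudomarker positions enter the chain as untyped (uniform-emission)
    observations, so the forward-backward recursion yields their posteriors
    directly.  An individual with a whole chromosome missing gets flat (0.5,
    0.5) posteriors there.
    """
    cfg = cfg or HMMConfig()
    if geno.markers != gmap.marker_names:
        raise ValueError("genotype marker set does not match the genetic map")
    grid = build_position_grid(gmap, cfg.grid_step)
    n = len(geno.individuals)
    probs = np.empty((n, len(grid), 2))
    col = 0  # marker column offset into geno.codes
    for chrom in gmap.chromosomes:
        sel = grid["chrom"] == chrom.name
        sub = grid.loc[sel]
        pos = sub["pos_cM"].to_numpy()
        obs = np.full((n, len(sub)), MISSING, dtype=np.int8)
        marker_idx = np.flatnonzero(sub["is_marker"].to_numpy())
        obs[:, marker_idx] = geno.codes[:, col : col + chrom.n_markers]
        col += chrom.n_markers
        probs[:, sel.to_numpy(), :] = _forward_backward_chrom(
            obs, pos, cfg.genotyping_error_rate
        )
    return GenotypeProbabilities(geno.individuals, grid, probs)


def enumerate_genotype_posteriors(obs: np.ndarray, pos: np.ndarray, eps: float) -> np.ndarray:
    """Exhaustive-path posterior oracle for one individual, one chromosome.

    Sums the joint probability of every 2^P hidden path; intended as an
    independent check of the forward-backward recursion on short maps.
    """
    obs = np.asarray(obs)
    pos = np.asarray(pos, dtype=float)
    P = obs.size
    if P > 20:
        raise ValueError("enumeration oracle limited to 20 positions")
    r = map_function_cf(np.diff(pos)) if P > 1 else np.empty(0)
    em = _emission(obs, eps)  # (P, 2)
    post = np.zeros((P, 2))
    total = 0.0
    for path in range(2**P):
        states = [(path >> t) & 1 for t in range(P)]
        w = 0.5 * em[0, states[0]]
        for t in range(1, P):
            w *= (1 - r[t - 1]) if states[t] == states[t - 1] else r[t - 1]
            w *= em[t, states[t]]
        total += w
        for t in range(P):
            post[t, states[t]] += w
    return post / total


# ---------------------------------------------------------------------------
# cM <-> bp conversion
# ---------------------------------------------------------------------------

def cm_to_bp(anchors: pd.DataFrame, chrom: str, query):
    """Piecewise-linear cM-to-bp interpolation from an anchor table.

    ``anchors`` has columns (chrom, cM, bp).  Queries outside the anchor
    range are extrapolated from the terminal segment and flagged.  Returns
    (bp, extrapolated) arrays (scalars for scalar queries).
    """
    sub = anchors.loc[anchors["chrom"].astype(str) == str(chrom)]
    if len(sub) < 2:
        raise ValueError(f"need at least 2 anchors on chromosome {chrom}")
    cm = sub["cM"].to_numpy(dtype=float)
    bp = sub["bp"].to_numpy(dtype=float)
    order = np.argsort(cm)
    cm, bp = cm[order], bp[order]
    if np.any(np.diff(cm) <= 0) or np.any(np.diff(bp) <= 0):
        raise ValueError(f"anchors on chromosome {chrom} are not strictly monotone")
    q = np.atleast_1d(np.asarray(query, dtype=float))
    out = np.interp(q, cm, bp)
    flag = (q < cm[0]) | (q > cm[-1])
    lo = q < cm[0]
    hi = q > cm[-1]
    if lo.any():
        slope = (bp[1] - bp[0]) / (cm[1] - cm[0])
        out[lo] = bp[0] + slope * (q[lo] - cm[0])
    if hi.any():
        slope = (bp[-1] - bp[-2]) / (cm[-1] - cm[-2])
        out[hi] = bp[-1] + slope * (q[hi] - cm[-1])
    if np.asarray(query).ndim == 0:
        return float(out[0]), bool(flag[0])
    return out, flag
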