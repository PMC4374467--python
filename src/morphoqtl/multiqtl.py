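"""Penalized multiple-QTL model search, fitting, and credible intervals.

Model comparison uses a penalized joint logP: the Pillai logP of all QTL
tested jointly against the covariate-only model, minus the genome-wide
permutation threshold times the number of QTL.  A forward search grows the
model one additive QTL at a time (each step followed by iterative position
refinement), backward elimination walks it back to the null model, and the
best model over everything visited wins.  Per-QTL location uncertainty is a
Bayes credible interval from the 1/p profile of the QTL conditional on all
other refined QTL.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .genetics import cm_to_bp
from .morphometrics import ShapeSpace
from .scan import (
    PillaiResult,
    QTLScanData,
    _logp_from_f,
    _scan_pillai_V,
    pillai_test,
    scan_shape,
)

logger = logging.getLogger("morphoqtl")


@dataclass(frozen=True)
class Locus:
    chrom: str
    pos_cm: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}@{self.pos_cm:g}"


@dataclass
class CredibleInterval:
    chrom: str
    lower_cm: float
    upper_cm: float
    peak_cm: float
    coverage: float
    lower_bp: float | None = None
    upper_bp: float | None = None
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.coverage < 1:
            raise ValueError("coverage must lie in (0, 1)")
        if not self.lower_cm <= self.peak_cm <= self.upper_cm:
            raise ValueError("interval must contain its peak")


@dataclass
class QTLModel:
    """An ordered set of loci with its joint fit statistics."""

    loci: list[Locus]
    model_logP: float
    threshold: float

    @property
    def n_qtl(self) -> int:
        return len(self.loci)

    @property
    def penalized(self) -> float:
        return self.model_logP - self.threshold * self.n_qtl


# ---------------------------------------------------------------------------
# Model scoring
# ---------------------------------------------------------------------------

def _loci_indices(data: QTLScanData, loci: list[Locus]) -> list[int]:
    return [data.locus_index(l.chrom, l.pos_cm) for l in loci]


def _design_with(data: QTLScanData, idx: list[int]) -> np.ndarray:
    if not idx:
        return data.X
    return np.column_stack([data.X, data.G[:, idx]])


def model_logP(data: QTLScanData, loci: list[Locus]) -> float:
    """Joint Pillai logP of all model QTL against the covariate-only design."""
    if not loci:
        return 0.0
    idx = _loci_indices(data, loci)
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate loci in model")
    res = pillai_test(data.Y, _design_with(data, idx), data.X)
    return res.logP


def _joint_gain_profile(data: QTLScanData, fixed_idx: list[int]) -> np.ndarray:
    """Joint-V gain of placing one more QTL at each grid position.

    With covariate-only residual SSCP T fixed, the joint Pillai V of a model
    with QTL at fixed_idx plus a candidate at position j is, up to a
    constant, b_j^T T^-1 b_j where b_j is the candidate column residualized
    against covariates plus the fixed QTL.  Maximizing this gain maximizes
    the joint model logP.
    """
    X_base = _design_with(data, fixed_idx)
    Q, _ = np.linalg.qr(X_base)
    Yt = data.Y - Q @ (Q.T @ data.Y)
    Gt = data.G - Q @ (Q.T @ data.G)
    Qx, _ = np.linalg.qr(data.X)
    Y0 = data.Y - Qx @ (Qx.T @ data.Y)
    T = Y0.T @ Y0
    L = cholesky(T, lower=True)
    norms2 = (Gt**2).sum(axis=0)
    ok = norms2 > 1e-12 * data.n
    gains = np.full(data.G.shape[1], -np.inf)
    if ok.any():
        B = Gt[:, ok].T @ Yt
        bs = B / np.sqrt(norms2[ok])[:, None]
        Z = solve_triangular(L, bs.T, lower=True)
        gains[ok] = (Z**2).sum(axis=0)
    return gains


def conditional_scan(data: QTLScanData, loci: list[Locus],
                     exclude: int | None = None) -> pd.DataFrame:
    """Genome scan for one QTL conditional on covariates and the other model QTL.

    ``exclude`` drops one model QTL (by list index) before conditioning, which
    yields that QTL's own conditional profile over the genome.
    """
    idx = _loci_indices(data, loci)
    if exclude is not None:
        idx = idx[:exclude] + idx[exclude + 1 :]
    aug = QTLScanData(
        grid=data.grid,
        G=data.G,
        Y=data.Y,
        X=_design_with(data, idx),
        covariate_names=data.covariate_names + [str(loci[i]) for i in range(len(loci)) if
                                                exclude is None or i != exclude],
    )
    return scan_shape(aug)


# ---------------------------------------------------------------------------
# Position refinement
# ---------------------------------------------------------------------------

def refine_positions(
    data: QTLScanData,
    loci: list[Locus],
    max_cycles: int = 20,
    chromosome_restricted: bool = False,
) -> tuple[list[Locus], list[float]]:
    """Iteratively re-profile each QTL conditional on the others.

    Each QTL in turn is moved to the grid position maximizing the joint
    model logP with the other QTL held fixed (ties broken toward the lowest
    chromosome then lowest cM, i.e. first grid index).  Because the current
    position is always among the candidates, the joint logP is monotone
    non-decreasing across moves.  Stops when a full cycle changes nothing or
    after ``max_cycles``.  Returns (refined loci, model logP after each
    cycle).
    """
    if not loci:
        raise ValueError("refinement needs at least one QTL")
    loci = list(loci)
    idx = _loci_indices(data, loci)
    chroms = data.grid["chrom"].to_numpy()
    trace: list[float] = []
    for _ in range(max_cycles):
        moved = False
        for j in range(len(loci)):
            others = idx[:j] + idx[j + 1 :]
            gains = _joint_gain_profile(data, others)
            mask = np.zeros(gains.size, dtype=bool)
            mask[others] = True  # cannot sit on another model QTL
            if chromosome_restricted:
                mask |= chroms != loci[j].chrom
            gains = np.where(mask, -np.inf, gains)
            best = int(np.argmax(gains))
            if best != idx[j] and gains[best] > gains[idx[j]] + 1e-12:
                idx[j] = best
                row = data.grid.iloc[best]
                loci[j] = Locus(str(row["chrom"]), float(row["pos_cM"]))
                moved = True
        trace.append(model_logP(data, loci))
        if not moved:
            break
    return loci, trace


# ---------------------------------------------------------------------------
# Model search
# ---------------------------------------------------------------------------

def _max_model_size(data: QTLScanData, max_qtl: int) -> int:
    """Cap the model size so the error df stays at least q + 2."""
    Qx, Rm = np.linalg.qr(data.X)
    rank = int(np.sum(np.abs(np.diag(Rm)) > 1e-10))
    cap = data.n - rank - (data.q + 2)
    if cap < max_qtl:
        warnings.warn(f"max_qtl capped at {cap} to preserve error df")
    return min(max_qtl, max(cap, 0))


def forward_backward_search(
    data: QTLScanData,
    threshold: float,
    max_qtl: int = 50,
    refine: bool = True,
) -> tuple[QTLModel, list[dict]]:
    """Forward/backward penalized search for a multiple-QTL model.

    Forward: repeatedly add the grid position with the largest joint-logP
    gain conditional on the current model, refine all positions, and record
    the model; up to ``max_qtl`` QTL.  Backward: from the forward endpoint,
    repeatedly drop the QTL whose removal leaves the largest joint logP,
    refine, and record, down to the null model.  The returned model is the
    penalized-score argmax (logP - threshold * n_qtl) over every visited
    model, the null model (penalized 0) included.
    """
    max_qtl = _max_model_size(data, max_qtl)
    visited: list[QTLModel] = [QTLModel([], 0.0, threshold)]
    trace: list[dict] = [{"step": "null", "loci": [], "model_logP": 0.0, "penalized": 0.0}]
    current: list[Locus] = []
    grid = data.grid
    for _ in range(max_qtl):
        gains = _joint_gain_profile(data, _loci_indices(data, current))
        occupied = _loci_indices(data, current)
        gains[occupied] = -np.inf
        best = int(np.argmax(gains))
        if not np.isfinite(gains[best]):
            break
        row = grid.iloc[best]
        current = current + [Locus(str(row["chrom"]), float(row["pos_cM"]))]
        if refine:
            current, _ = refine_positions(data, current)
        m = QTLModel(list(current), model_logP(data, current), threshold)
        visited.append(m)
        trace.append({"step": "forward", "loci": [str(l) for l in m.loci],
                      "model_logP": m.model_logP, "penalized": m.penalized})
    while current:
        if len(current) == 1:
            current = []
            m = QTLModel([], 0.0, threshold)
        else:
            scores = []
            for j in range(len(current)):
                reduced = current[:j] + current[j + 1 :]
                scores.append(model_logP(data, reduced))
            j = int(np.argmax(scores))
            current = current[:j] + current[j + 1 :]
            if refine:
                current, _ = refine_positions(data, current)
            m = QTLModel(list(current), model_logP(data, current), threshold)
        visited.append(m)
        trace.append({"step": "backward", "loci": [str(l) for l in m.loci],
                      "model_logP": m.model_logP, "penalized": m.penalized})
    best_model = max(visited, key=lambda m: m.penalized)
    return best_model, trace


def stepwise_significance_search(
    data: QTLScanData,
    threshold: float,
    max_qtl: int = 50,
) -> QTLModel:
    """Stepwise search driven by conditional significance.

    QTL are added while the best candidate's logP conditional on all current
    QTL and covariates reaches the genome-wide threshold; after each
    addition, any QTL whose own conditional logP falls below the threshold
    is dropped; positions are refined after each change.
    """
    max_qtl = _max_model_size(data, max_qtl)
    current: list[Locus] = []
    for _ in range(2 * max_qtl + 1):
        scan = conditional_scan(data, current)
        occupied = _loci_indices(data, current)
        scores = scan["score"].to_numpy().copy()
        scores[occupied] = -np.inf
        best = int(np.argmax(scores))
        if scores[best] < threshold or len(current) >= max_qtl:
            break
        row = data.grid.iloc[best]
        current.append(Locus(str(row["chrom"]), float(row["pos_cM"])))
        current, _ = refine_positions(data, current)
        # drop any QTL that is no longer significant conditional on the rest
        changed = True
        while changed and len(current) > 1:
            changed = False
            idx = _loci_indices(data, current)
            full = _design_with(data, idx)
            for j in range(len(current)):
                reduced = _design_with(data, idx[:j] + idx[j + 1 :])
                res = pillai_test(data.Y, full, reduced)
                if res.logP < threshold:
                    current = current[:j] + current[j + 1 :]
                    current, _ = refine_positions(data, current)
                    changed = True
                    break
    return QTLModel(current, model_logP(data, current), threshold)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedQTLModel:
    """Multivariate least-squares fit of a fixed multiple-QTL model."""

    loci: list[Locus]
    term_names: list[str]          # covariates then loci (intercept first)
    coefficients: np.ndarray       # (n_terms, q), PC-score space
    conditional_tests: dict[str, PillaiResult]
    residual_sscp: np.ndarray      # (q, q)
    n: int
    fitted: np.ndarray             # (n, q)

    @property
    def q(self) -> int:
        return self.coefficients.shape[1]

    def effect(self, term: str) -> np.ndarray:
        return self.coefficients[self.term_names.index(term)]

    def effect_displacement(self, term: str, shape: ShapeSpace) -> np.ndarray:
        """Back-transform a term's effect vector to k x 3 landmark displacements."""
        return shape.scores_to_displacement(self.effect(term))


def fit_qtl_model(data: QTLScanData, loci: list[Locus]) -> FittedQTLModel:
    """Haley-Knott fit of the full model and per-term drop-one Pillai tests."""
    idx = _loci_indices(data, loci)
    Z = _design_with(data, idx)
    names = list(data.covariate_names) + [str(l) for l in loci]
    B, _, rank, _ = np.linalg.lstsq(Z, data.Y, rcond=None)
    if rank < Z.shape[1]:
        from .scan import check_full_rank

        check_full_rank(Z, names)  # raises with the collinear column names
    fitted = Z @ B
    resid = data.Y - fitted
    tests: dict[str, PillaiResult] = {}
    for t, name in enumerate(names):
        if name == "intercept":
            continue
        reduced = np.delete(Z, t, axis=1)
        tests[name] = pillai_test(data.Y, Z, reduced, full_names=names)
    return FittedQTLModel(
        loci=list(loci),
        term_names=names,
        coefficients=B,
        conditional_tests=tests,
        residual_sscp=resid.T @ resid,
        n=data.n,
        fitted=fitted,
    )


# ---------------------------------------------------------------------------
# Bayes credible intervals
# ---------------------------------------------------------------------------

def bayes_credible_interval(
    positions: np.ndarray,
    logp: np.ndarray,
    coverage: float = 0.95,
    chrom: str = "",
) -> CredibleInterval:
    """Bayes credible interval from a chromosome logP profile.

    Weights proportional to 10^logP (the 1/p profile) are normalized to unit
    mass over the chromosome grid; grid positions are accumulated in
    decreasing weight order until the requested coverage is reached, and the
    interval is the [min, max] position of the accumulated set.
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must lie in (0, 1)")
    positions = np.asarray(positions, dtype=float)
    logp = np.asarray(logp, dtype=float)
    if positions.size != logp.size or positions.size == 0:
        raise ValueError("positions and profile must be non-empty and aligned")
    peak = float(positions[np.argmax(logp)])
    if np.all(logp <= 0):
        warnings.warn("flat/zero profile: credible interval spans the whole chromosome")
        return CredibleInterval(chrom, float(positions.min()), float(positions.max()),
                                peak, coverage)
    w = np.power(10.0, logp - logp.max())
    w /= w.sum()
    order = np.argsort(-w, kind="stable")
    cum = np.cumsum(w[order])
    m = int(np.searchsorted(cum, coverage - 1e-12)) + 1
    sel = positions[order[:m]]
    return CredibleInterval(chrom, float(sel.min()), float(sel.max()), peak, coverage)


def qtl_credible_intervals(
    data: QTLScanData,
    loci: list[Locus],
    coverage: float = 0.95,
    anchors: pd.DataFrame | None = None,
) -> list[CredibleInterval]:
    """Per-QTL credible intervals from conditional chromosome profiles.

    Each QTL's profile is its conditional logP over its own chromosome with
    all other (refined) QTL and covariates in the model.  With an anchor
    table the cM bounds are also converted to bp.
    """
    intervals = []
    for j, locus in enumerate(loci):
        scan = conditional_scan(data, loci, exclude=j)
        sub = scan.loc[scan["chrom"].astype(str) == locus.chrom]
        ci = bayes_credible_interval(
            sub["pos_cM"].to_numpy(), sub["score"].to_numpy(), coverage, chrom=locus.chrom
        )
        ci.peak_cm = locus.pos_cm
        ci.lower_cm = min(ci.lower_cm, locus.pos_cm)
        ci.upper_cm = max(ci.upper_cm, locus.pos_cm)
        if anchors is not None:
            lo, f1 = cm_to_bp(anchors, locus.chrom, ci.lower_cm)
            hi, f2 = cm_to_bp(anchors, locus.chrom, ci.upper_cm)
            ci.lower_bp, ci.upper_bp, ci.extrapolated = lo, hi, bool(f1 or f2)
        intervals.append(ci)
    return intervals


def model_report(
    data: QTLScanData,
    loci: list[Locus],
    intervals: list[CredibleInterval],
    fitted: FittedQTLModel,
) -> pd.DataFrame:
    """Per-QTL summary table: position, closest marker, conditional logP, CI bounds."""
    rows = []
    for i, (locus, ci) in enumerate(zip(loci, intervals), start=1):
        sub = data.grid.loc[
            (data.grid["chrom"].astype(str) == locus.chrom) & data.grid["is_marker"]
        ]
        if len(sub):
            nearest = sub.iloc[(sub["pos_cM"] - locus.pos_cm).abs().argmin()]["marker"]
        else:
            nearest = ""
        test = fitted.conditional_tests.get(str(locus))
        rows.append(
            {
                "qtl": f"QTL{i}",
                "chrom": locus.chrom,
                "pos_cM": locus.pos_cm,
                "closest_marker": nearest,
                "conditional_logP": test.logP if test else np.nan,
                "lower_ci_cM": ci.lower_cm,
                "upper_ci_cM": ci.upper_cm,
                "lower_ci_bp": ci.lower_bp,
                "upper_ci_bp": ci.upper_bp,
            }
        )
    return pd.DataFrame(rows)


def intervals_to_bed(intervals: list[CredibleInterval], names: list[str] | None = None) -> pd.DataFrame:
    """BED frame (0-based half-open bp) of credible intervals; cM bounds in the name."""
    rows = []
    for i, ci in enumerate(intervals):
        if ci.lower_bp is None or ci.upper_bp is None:
            raise ValueError("intervals lack bp bounds; convert with cm_to_bp anchors first")
        name = names[i] if names else f"QTL{i + 1}"
        rows.append(
            {
                "chrom": ci.chrom,
                "start": int(round(ci.lower_bp)) - 1,
                "end": int(round(ci.upper_bp)),
                "name": f"{name}|{ci.lower_cm:g}-{ci.upper_cm:g}cM",
            }
        )
    return pd.DataFrame(rows)
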