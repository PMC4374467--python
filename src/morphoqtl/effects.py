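"""Effect-size accounting and anatomical decomposition of shape-QTL effects.

A QTL's effect on shape is a q-dimensional vector in the symmetric tangent
space.  Its magnitude is a Procrustes distance (the Euclidean norm of the
vector, invariant to the orthonormal PC basis); its contribution to the
sample is expressed both as a percentage of the total Procrustes variance
and as the variance explained along its own direction (projection scores).
Back-transformed to per-landmark displacements, the effect is parcellated
across anatomical regions and compared with the parcellation of isotropic
random vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .morphometrics import RegionMap, ShapeSpace
from .multiqtl import FittedQTLModel
from .scan import QTLScanData


# ---------------------------------------------------------------------------
# Magnitude, variance accounting, projection scores
# ---------------------------------------------------------------------------

def effect_magnitude(beta: np.ndarray) -> float:
    """Procrustes magnitude of an effect vector: ||beta|| = (beta beta^T)^0.5."""
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite effect vector")
    return float(np.linalg.norm(beta))


def variance_accounting(
    fitted: FittedQTLModel, data: QTLScanData, total_ss: float | None = None
) -> pd.DataFrame:
    """Percentage of total Procrustes variance accounted for by each model term.

    Per term: the drop-one (conditional) sum of squares, summed over all q
    response dimensions, divided by the total Procrustes sum of squares of
    the sample, times 100.  ``total_ss`` defaults to the centered total SS of
    the response scores, which equals the total Procrustes SS of the
    symmetric shapes because the PC basis is orthonormal.
    """
    Yc = data.Y - data.Y.mean(axis=0)
    tss = float((Yc**2).sum()) if total_ss is None else float(total_ss)
    if tss <= 0:
        raise ValueError("zero total Procrustes variance")
    rows = []
    for name, test in fitted.conditional_tests.items():
        # conditional SS of the term = tr(E_reduced - E_full); recover it from
        # the Pillai machinery via V and E_reduced is not stored, so recompute
        # directly from the design.
        rows.append((name, test))
    out = []
    names = fitted.term_names
    idx_by_name = {nm: t for t, nm in enumerate(names)}
    Z = _model_design(fitted, data)
    Qf, _ = np.linalg.qr(Z)
    rss_full = float(((data.Y - Qf @ (Qf.T @ data.Y)) ** 2).sum())
    for name, test in rows:
        reduced = np.delete(Z, idx_by_name[name], axis=1)
        Qr, _ = np.linalg.qr(reduced)
        rss_red = float(((data.Y - Qr @ (Qr.T @ data.Y)) ** 2).sum())
        out.append(
            {
                "term": name,
                "magnitude": effect_magnitude(fitted.effect(name)),
                "conditional_ss": rss_red - rss_full,
                "pct_total_procrustes_variance": 100.0 * (rss_red - rss_full) / tss,
                "logP": test.logP,
            }
        )
    return pd.DataFrame(out)


def _model_design(fitted: FittedQTLModel, data: QTLScanData) -> np.ndarray:
    from .multiqtl import _design_with, _loci_indices

    return _design_with(data, _loci_indices(data, fitted.loci))


def projection_scores(
    Y: np.ndarray, beta: np.ndarray, data: QTLScanData | None = None,
    fitted: FittedQTLModel | None = None, term: str | None = None,
) -> tuple[np.ndarray, float | None]:
    """Shape variable along an effect direction: s = Y beta^T / ||beta||.

    When the fitted model and term are supplied, also returns the percentage
    of var(s) explained by that term conditional on all other model terms
    (the conditional R-squared of the term in a regression of s on the full
    model design).
    """
    beta = np.asarray(beta, dtype=float)
    nrm = np.linalg.norm(beta)
    if nrm == 0:
        raise ValueError("zero-norm effect vector")
    s = np.asarray(Y, dtype=float) @ beta / nrm
    pct = None
    if fitted is not None and data is not None and term is not None:
        Z = _model_design(fitted, data)
        t = fitted.term_names.index(term)
        sc = s - s.mean()
        tot = float(sc @ sc)
        Qf, _ = np.linalg.qr(Z)
        rss_full = float(((s - Qf @ (Qf.T @ s)) ** 2).sum())
        Qr, _ = np.linalg.qr(np.delete(Z, t, axis=1))
        rss_red = float(((s - Qr @ (Qr.T @ s)) ** 2).sum())
        pct = 100.0 * (rss_red - rss_full) / tot if tot > 0 else np.nan
    return s, pct


# ---------------------------------------------------------------------------
# Region decomposition
# ---------------------------------------------------------------------------

def region_decomposition(
    displacement: np.ndarray, regions: RegionMap
) -> pd.DataFrame:
    """Parcellation of a landmark displacement field across anatomical regions.

    Each landmark contributes the Euclidean norm of its 3-vector; a landmark
    on a region boundary splits its magnitude equally among its regions.
    Raw proportions divide region sums by the grand sum; normalized
    proportions divide each region sum by the region's fractional landmark
    count, then renormalize to sum 1.
    """
    disp = np.asarray(displacement, dtype=float)
    k = disp.shape[0]
    regions.validate_for(k)
    mags = np.linalg.norm(disp, axis=1)
    grand = mags.sum()
    if grand <= 0:
        raise ValueError("zero total displacement magnitude")
    names = regions.region_names
    sums = dict.fromkeys(names, 0.0)
    counts = dict.fromkeys(names, 0.0)
    for lm in range(k):
        regs = regions.regions[lm]
        share = 1.0 / len(regs)
        for r in regs:
            sums[r] += mags[lm] * share
            counts[r] += share
    raw = np.array([sums[r] / grand for r in names])
    per_lm = np.array([sums[r] / counts[r] for r in names])
    normalized = per_lm / per_lm.sum()
    return pd.DataFrame(
        {
            "region": names,
            "raw_proportion": raw,
            "normalized_proportion": normalized,
            "fractional_landmark_count": [counts[r] for r in names],
        }
    )


def random_vector_intervals(
    shape: ShapeSpace,
    regions: RegionMap,
    n_draws: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Null region-proportion intervals from isotropic random effect vectors.

    Draws standard-normal vectors in the q-dimensional symmetric tangent
    subspace, back-transforms them to landmark displacements, parcellates
    each across regions, and returns the empirical (alpha/2, 1 - alpha/2)
    interval per region for both raw and normalized proportions.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    rng = np.random.default_rng(seed)
    names = regions.region_names
    raw = np.empty((n_draws, len(names)))
    nor = np.empty((n_draws, len(names)))
    for d in range(n_draws):
        z = rng.standard_normal(shape.q)
        disp = shape.scores_to_displacement(z)
        dec = region_decomposition(disp, regions)
        raw[d] = dec["raw_proportion"].to_numpy()
        nor[d] = dec["normalized_proportion"].to_numpy()
    lo, hi = alpha / 2, 1 - alpha / 2
    return pd.DataFrame(
        {
            "region": names,
            "raw_low": np.quantile(raw, lo, axis=0),
            "raw_high": np.quantile(raw, hi, axis=0),
            "raw_mean": raw.mean(axis=0),
            "normalized_low": np.quantile(nor, lo, axis=0),
            "normalized_high": np.quantile(nor, hi, axis=0),
            "normalized_mean": nor.mean(axis=0),
        }
    )


def flag_against_null(
    decomposition: pd.DataFrame, null_intervals: pd.DataFrame
) -> pd.DataFrame:
    """Mark region proportions falling outside their random-vector interval."""
    merged = decomposition.merge(null_intervals, on="region")
    merged["raw_above"] = merged["raw_proportion"] > merged["raw_high"]
    merged["raw_below"] = merged["raw_proportion"] < merged["raw_low"]
    merged["normalized_above"] = merged["normalized_proportion"] > merged["normalized_high"]
    merged["normalized_below"] = merged["normalized_proportion"] < merged["normalized_low"]
    return merged


# ---------------------------------------------------------------------------
# Angles between QTL effects and phenotypic PCs
# ---------------------------------------------------------------------------

def _angle_deg(beta: np.ndarray, mode: str, k: int) -> float:
    nrm = np.linalg.norm(beta)
    if nrm == 0:
        raise ValueError("zero-norm effect vector")
    if mode == "pc1":
        c = abs(beta[0]) / nrm
    elif mode == "subspace":
        c = np.linalg.norm(beta[:k]) / nrm
    else:
        raise ValueError(f"unknown angle mode {mode!r}")
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def pc_angle_analysis(
    effects: list[np.ndarray],
    shape_or_q: ShapeSpace | int,
    mode: str = "subspace",
    subspace_variance: float = 0.90,
    k: int | None = None,
    n_null: int = 10000,
    n_shuffle: int = 10000,
    seed: int | None = None,
) -> dict:
    """Angles of QTL effect vectors to the leading phenotypic PC structure.

    Effect vectors are expressed in PC-score space (coordinates ordered by
    descending eigenvalue).  Mode "pc1": angle to the first PC axis; mode
    "subspace": angle between the vector and its orthogonal projection onto
    the span of the first k PCs (k chosen to carry ``subspace_variance`` of
    the phenotypic variance unless given).  The null is the same angle for
    isotropic random q-vectors; the Monte-Carlo p tests whether the observed
    mean angle is smaller than random.  Also reports the Pearson correlation
    between per-QTL angle and magnitude with a permutation p-value.
    """
    if len(effects) == 0:
        raise ValueError("need at least one effect vector")
    if isinstance(shape_or_q, ShapeSpace):
        q = shape_or_q.q
        lam = shape_or_q.eigenvalues
    else:
        q = int(shape_or_q)
        lam = None
    if mode == "subspace" and k is None:
        if lam is None:
            raise ValueError("subspace mode needs a ShapeSpace or an explicit k")
        frac = np.cumsum(lam) / lam.sum()
        k = int(np.searchsorted(frac, subspace_variance)) + 1
    k = k or 1
    rng = np.random.default_rng(seed)
    angles = np.array([_angle_deg(np.asarray(b, dtype=float), mode, k) for b in effects])
    mags = np.array([np.linalg.norm(b) for b in effects])
    null_vectors = rng.standard_normal((n_null, q))
    null_angles = np.array([_angle_deg(v, mode, k) for v in null_vectors])
    # Monte-Carlo p for the mean observed angle being smaller than random
    m = len(effects)
    null_means = null_angles[: (n_null // m) * m].reshape(-1, m).mean(axis=1)
    p_mean = float((1 + np.sum(null_means <= angles.mean())) / (1 + null_means.size))
    if m >= 3 and np.std(mags) > 0 and np.std(angles) > 0:
        r = float(stats.pearsonr(angles, mags)[0])
        count = 0
        for _ in range(n_shuffle):
            rp = np.corrcoef(angles, rng.permutation(mags))[0, 1]
            if abs(rp) >= abs(r) - 1e-12:
                count += 1
        p_corr = float((1 + count) / (1 + n_shuffle))
    else:
        r, p_corr = np.nan, np.nan
    return {
        "mode": mode,
        "k": k,
        "angles_deg": angles,
        "magnitudes": mags,
        "mean_angle_deg": float(angles.mean()),
        "null_angle_quantiles": {
            "q05": float(np.quantile(null_angles, 0.05)),
            "q50": float(np.quantile(null_angles, 0.50)),
            "q95": float(np.quantile(null_angles, 0.95)),
        },
        "null_mean_angle_deg": float(null_angles.mean()),
        "p_mean_angle_smaller": p_mean,
        "angle_magnitude_r": r,
        "angle_magnitude_p": p_corr,
    }
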