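"""Synthetic backcross genotypes and 3D landmark phenotypes with planted QTL.

The generator emulates an N2 backcross mapping panel: 433 offspring in the
four sex-by-direction-of-cross strata of the emulated design, 19 autosomes
with evenly spaced SNP markers (~880 in total), and skull-like 3D landmark
configurations with object symmetry (22 bilateral pairs + 9 midline
landmarks by default).  Hidden genotypes follow the marker-interval Markov
chain whose recombination fractions come from the Carter-Falconer map
function; shape phenotypes follow the additive multivariate model used in
mapping (QTL effects + covariate effects + correlated residual), built in
the symmetric tangent subspace of a base configuration and then pushed
through per-specimen nuisance rotation, translation and scale.  Ground
truth is recorded losslessly for every generated dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .genetics import (
    HET,
    HOM,
    MISSING,
    ChromosomeMap,
    GeneticMap,
    MarkerGenotypes,
    map_function_cf,
)
from .morphometrics import LandmarkSet, RegionMap, SymmetryMap, centroid_size
from .scan import CovariateTable

# Sex / direction-of-cross strata of the emulated design:
# (direction, sex, count); direction 0 = A/J dam x F1 sire, 1 = reciprocal.
DEFAULT_STRATA = ((0, 0, 84), (0, 1, 79), (1, 0, 128), (1, 1, 142))


@dataclass
class PlantedQTL:
    """A planted additive locus: position, Procrustes-magnitude, direction.

    ``regions`` targets the effect displacement at the named anatomical
    regions (otherwise the direction is drawn isotropically in the symmetric
    tangent subspace).  ``size_effect`` is an additive effect on log centroid
    size (per HET allele)."""

    chrom: str
    pos_cm: float
    magnitude: float = 0.0
    regions: tuple[str, ...] | None = None
    size_effect: float = 0.0


@dataclass
class SimulationConfig:
    strata: tuple = DEFAULT_STRATA
    n: int | None = None                   # overrides strata with an even 4-way split
    n_chrom: int = 19
    markers_per_chrom: int = 46
    chrom_length_cm: float = 73.0
    pairs: int = 22
    midline: int = 9
    qtl: tuple = ()
    total_shape_variance: float = 5e-4     # Procrustes variance of the symmetric shapes
    n_factors: int = 10
    factor_share: float = 0.6              # variance carried by the low-rank factors
    factor_decay: float = 0.9
    allometry_pct: float = 4.0             # covariate shares of total shape variance (%)
    sex_pct: float = 1.0
    direction_pct: float = 2.0
    base_centroid_size: float = 60.0       # mm
    log_cs_sd: float = 0.03
    sex_size_effect: float = 0.01          # on log centroid size
    direction_size_effect: float = 0.005
    asym_sd: float = 0.002                 # asymmetric coordinate noise, shape units
    genotyping_error: float = 1e-4
    missingness: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.genotyping_error, self.missingness):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if any(q.magnitude < 0 for q in self.qtl):
            raise ValueError("QTL magnitudes must be non-negative")

    @property
    def n_individuals(self) -> int:
        if self.n is not None:
            return self.n
        return sum(s[2] for s in self.strata)


@dataclass
class GroundTruth:
    """Hidden state of a simulated dataset."""

    qtl: list[PlantedQTL]
    qtl_effects_basis: np.ndarray       # (n_qtl, m) effect vectors, symmetric-basis coords
    qtl_effects_displacement: np.ndarray  # (n_qtl, k, 3)
    covariate_effects_basis: dict[str, np.ndarray]
    hidden_marker_genotypes: np.ndarray   # (n, n_markers) before error/missingness
    hidden_qtl_genotypes: np.ndarray      # (n, n_qtl)
    seed: int


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    gmap: GeneticMap
    genotypes: MarkerGenotypes
    landmarks: LandmarkSet
    covariates: CovariateTable
    symmetry: SymmetryMap
    regions: RegionMap
    truth: GroundTruth
    base_shape: np.ndarray              # (k, 3) unit centroid size
    symmetric_basis: np.ndarray         # (m, 3k)


# ---------------------------------------------------------------------------
# Base configuration, symmetry metadata and the symmetric tangent basis
# ---------------------------------------------------------------------------

def make_base_configuration(pairs: int = 22, midline: int = 9,
                            seed: int = 20150326) -> tuple[np.ndarray, SymmetryMap]:
    """A generic mirror-symmetric base configuration, unit centroid size.

    Left/right pairs occupy indices (2i, 2i+1); midline landmarks follow.
    The geometry is a fixed pseudo-random cloud (symmetric across x = 0),
    generic enough that all symmetric shape dimensions carry variance.
    """
    rng = np.random.default_rng(seed)
    k = 2 * pairs + midline
    coords = np.zeros((k, 3))
    for i in range(pairs):
        pt = rng.uniform([0.3, -1.0, -1.0], [1.0, 1.0, 1.0])
        coords[2 * i] = pt
        coords[2 * i + 1] = pt * np.array([-1.0, 1.0, 1.0])
    for j in range(midline):
        coords[2 * pairs + j] = [0.0, *rng.uniform(-1.0, 1.0, size=2)]
    coords -= coords.mean(axis=0)
    coords /= centroid_size(coords)
    sym = SymmetryMap(
        pairs=[(2 * i, 2 * i + 1) for i in range(pairs)],
        midline=list(range(2 * pairs, k)),
    )
    return coords, sym


def default_region_map(pairs: int = 22, midline: int = 9) -> RegionMap:
    """Four skull regions with a few two-region boundary landmarks.

    Paired landmarks are split across neurocranium, lateral face, dorsal face
    and palate in blocks; two pairs sit on region boundaries (assigned to two
    regions); midline landmarks go to neurocranium, dorsal face and palate.
    """
    regions: dict[int, tuple[str, ...]] = {}
    blocks = [
        ("neurocranium", range(0, max(1, pairs // 4))),
        ("lateral_face", range(max(1, pairs // 4), pairs // 2)),
        ("dorsal_face", range(pairs // 2, 3 * pairs // 4)),
        ("palate", range(3 * pairs // 4, pairs)),
    ]
    for name, rng_ in blocks:
        for i in rng_:
            regions[2 * i] = (name,)
            regions[2 * i + 1] = (name,)
    if pairs >= 8:  # boundary pairs between neurocranium and the facial regions
        regions[2 * (pairs // 4)] = ("neurocranium", "lateral_face")
        regions[2 * (pairs // 4) + 1] = ("neurocranium", "lateral_face")
        regions[2 * (pairs // 2)] = ("neurocranium", "dorsal_face")
        regions[2 * (pairs // 2) + 1] = ("neurocranium", "dorsal_face")
    mid_names = ["neurocranium", "dorsal_face", "palate"]
    for j in range(midline):
        regions[2 * pairs + j] = (mid_names[j % 3],)
    return RegionMap(regions)


def symmetric_tangent_basis(base: np.ndarray, sym: SymmetryMap) -> np.ndarray:
    """Orthonormal basis of the symmetric tangent subspace at the base shape.

    Spans mirror-symmetric landmark perturbations (a pair moves as
    (dx, dy, dz) / (-dx, dy, dz); midline landmarks move within the plane)
    orthogonal to the similarity transformations that preserve the symmetry:
    in-plane translations, the rotation about the symmetry-plane normal
    axis, and scale.  Dimension 3p + 2l - 4.
    """
    k = base.shape[0]
    sym.validate_for(k)
    raw: list[np.ndarray] = []
    for left, right in sym.pairs:
        for axis, sign in ((0, -1.0), (1, 1.0), (2, 1.0)):
            v = np.zeros((k, 3))
            v[left, axis] = 1.0
            v[right, axis] = sign
            raw.append(v.ravel())
    for lm in sym.midline:
        for axis in (1, 2):
            v = np.zeros((k, 3))
            v[lm, axis] = 1.0
            raw.append(v.ravel())
    S = np.asarray(raw).T  # (3k, 3p + 2l)
    centered = base - base.mean(axis=0)
    sim = []
    for axis in (1, 2):  # translations within the symmetry plane
        t = np.zeros((k, 3))
        t[:, axis] = 1.0
        sim.append(t.ravel())
    rot = np.zeros((k, 3))  # generator of rotation about the x axis
    rot[:, 1] = -centered[:, 2]
    rot[:, 2] = centered[:, 1]
    sim.append(rot.ravel())
    sim.append(centered.ravel())  # scale direction
    simM = np.asarray(sim).T
    # project the similarity directions out of the symmetric span
    Qs, _ = np.linalg.qr(S)
    proj_sim = Qs @ (Qs.T @ simM)
    Qsim, _ = np.linalg.qr(proj_sim)
    reduced = Qs - Qsim @ (Qsim.T @ Qs)
    u, s, vt = np.linalg.svd(reduced.T @ reduced)
    m = int(np.sum(s > 1e-9))
    basis = (Qs @ u[:, :m]).T
    # orthonormalize exactly
    qb, _ = np.linalg.qr(basis.T)
    return qb.T


# ---------------------------------------------------------------------------
# Backcross genotypes
# ---------------------------------------------------------------------------

def _default_map(cfg: SimulationConfig) -> GeneticMap:
    chrom_maps = []
    for c in range(1, cfg.n_chrom + 1):
        cm = np.linspace(0.0, cfg.chrom_length_cm, cfg.markers_per_chrom)
        names = [f"m{c}_{j}" for j in range(cfg.markers_per_chrom)]
        chrom_maps.append(ChromosomeMap(str(c), names, cm))
    return GeneticMap(chrom_maps)


def _simulate_chain(n: int, pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Hidden two-state genotypes along one chromosome for n individuals."""
    P = pos.size
    out = np.empty((n, P), dtype=np.int8)
    out[:, 0] = rng.random(n) < 0.5
    if P > 1:
        r = map_function_cf(np.diff(pos))
        for t in range(1, P):
            flip = rng.random(n) < r[t - 1]
            out[:, t] = np.where(flip, 1 - out[:, t - 1], out[:, t - 1])
    return out


def simulate_backcross(
    cfg: SimulationConfig, rng: np.random.Generator | None = None,
    gmap: GeneticMap | None = None,
) -> tuple[MarkerGenotypes, GeneticMap, np.ndarray, np.ndarray]:
    """Backcross genotypes with genotyping error and missingness.

    Returns (observed genotypes, map, hidden marker genotypes, hidden
    genotypes at the planted QTL positions).  The hidden chain runs over the
    union of marker and QTL positions so planted loci between markers get
    exact genotypes.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    gmap = gmap or _default_map(cfg)
    n = cfg.n_individuals
    hidden_m = np.empty((n, len(gmap.marker_names)), dtype=np.int8)
    hidden_q = np.empty((n, len(cfg.qtl)), dtype=np.int8)
    col = 0
    for chrom in gmap.chromosomes:
        q_here = [(j, q.pos_cm) for j, q in enumerate(cfg.qtl) if str(q.chrom) == chrom.name]
        pos = np.unique(np.concatenate([chrom.cm, [p for _, p in q_here]]))
        chain = _simulate_chain(n, pos, rng)
        m_idx = np.searchsorted(pos, chrom.cm)
        hidden_m[:, col : col + chrom.n_markers] = chain[:, m_idx]
        for j, p in q_here:
            hidden_q[:, j] = chain[:, np.searchsorted(pos, p)]
        col += chrom.n_markers
    observed = hidden_m.copy()
    if cfg.genotyping_error > 0:
        flip = rng.random(observed.shape) < cfg.genotyping_error
        observed = np.where(flip, 1 - observed, observed).astype(np.int8)
    if cfg.missingness > 0:
        observed = np.where(rng.random(observed.shape) < cfg.missingness,
                            MISSING, observed).astype(np.int8)
    individuals = [f"ind{i + 1}" for i in range(n)]
    geno = MarkerGenotypes(individuals, gmap.marker_names, observed)
    return geno, gmap, hidden_m, hidden_q


def _strata_covariates(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = cfg.n_individuals
    if cfg.n is not None:
        per = [n // 4] * 4
        per[3] += n - sum(per)
        strata = [(d, s, c) for (d, s, _), c in zip(DEFAULT_STRATA, per)]
    else:
        strata = list(cfg.strata)
    direction = np.concatenate([np.full(c, d) for d, s, c in strata]).astype(float)
    sex = np.concatenate([np.full(c, s) for d, s, c in strata]).astype(float)
    return sex, direction


def _region_direction(regions: tuple[str, ...], region_map: RegionMap,
                      basis: np.ndarray, k: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit direction in the symmetric subspace concentrated on given regions."""
    disp = np.zeros((k, 3))
    for lm, regs in region_map.regions.items():
        if any(r in regions for r in regs):
            disp[lm] = rng.standard_normal(3)
    u = basis @ disp.ravel()  # project onto the symmetric tangent subspace
    nrm = np.linalg.norm(u)
    if nrm < 1e-12:
        raise ValueError(f"no symmetric displacement within regions {regions}")
    return u / nrm


def simulate_shapes(
    hidden_q: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sex: np.ndarray,
    direction: np.ndarray,
) -> tuple[LandmarkSet, CovariateTable, GroundTruth, np.ndarray, np.ndarray,
           SymmetryMap, RegionMap]:
    """Landmark phenotypes from hidden QTL genotypes and covariates.

    The symmetric shape is base + QTL effects + covariate effects +
    correlated residual (low-rank factors plus diagonal), all within the
    symmetric tangent subspace; raw configurations add asymmetric
    coordinate noise and a random rotation, translation and scale per
    specimen.
    """
    n = hidden_q.shape[0] if len(cfg.qtl) else cfg.n_individuals
    base, sym = make_base_configuration(cfg.pairs, cfg.midline)
    region_map = default_region_map(cfg.pairs, cfg.midline)
    basis = symmetric_tangent_basis(base, sym)
    m = basis.shape[0]
    k = base.shape[0]
    T = cfg.total_shape_variance

    # planted QTL directions and magnitudes (basis coordinates)
    betas = np.zeros((len(cfg.qtl), m))
    for j, q in enumerate(cfg.qtl):
        u = (
            _region_direction(q.regions, region_map, basis, k, rng)
            if q.regions
            else _unit(rng.standard_normal(m))
        )
        betas[j] = q.magnitude * u

    # covariate effect vectors scaled to their variance shares
    sex_c = sex - sex.mean()
    dir_c = direction - direction.mean()
    beta_sex = _unit(rng.standard_normal(m)) * np.sqrt(
        cfg.sex_pct / 100.0 * T / max(sex_c.var(), 1e-12)
    )
    beta_dir = _unit(rng.standard_normal(m)) * np.sqrt(
        cfg.direction_pct / 100.0 * T / max(dir_c.var(), 1e-12)
    )
    beta_allo = _unit(rng.standard_normal(m)) * np.sqrt(
        cfg.allometry_pct / 100.0 * T
    ) / cfg.log_cs_sd

    # centroid sizes with allometric genotype/sex/direction contributions
    log_cs = (
        np.log(cfg.base_centroid_size)
        + cfg.sex_size_effect * sex_c
        + cfg.direction_size_effect * dir_c
        + rng.normal(0.0, cfg.log_cs_sd, size=n)
    )
    for j, q in enumerate(cfg.qtl):
        if q.size_effect:
            log_cs += q.size_effect * (hidden_q[:, j] - 0.5)
    cs = np.exp(log_cs)
    allo_x = log_cs - log_cs.mean()

    # residual: low-rank factors + diagonal, scaled to the leftover variance
    used = cfg.allometry_pct + cfg.sex_pct + cfg.direction_pct
    resid_T = max(T * (1 - used / 100.0), 0.1 * T)
    f = cfg.factor_decay ** np.arange(1, cfg.n_factors + 1)
    f *= cfg.factor_share * resid_T / f.sum()
    load = np.linalg.qr(rng.standard_normal((m, cfg.n_factors)))[0]  # (m, nf)
    psi = (1 - cfg.factor_share) * resid_T / m
    Z = rng.standard_normal((n, cfg.n_factors)) * np.sqrt(f)
    U = Z @ load.T + rng.standard_normal((n, m)) * np.sqrt(psi)
    for j in range(len(cfg.qtl)):
        U += np.outer(hidden_q[:, j] - 0.5, betas[j])
    U += np.outer(sex_c, beta_sex) + np.outer(dir_c, beta_dir) + np.outer(allo_x, beta_allo)

    shapes = base[None] + (U @ basis).reshape(n, k, 3)
    if cfg.asym_sd > 0:
        shapes = shapes + rng.normal(0.0, cfg.asym_sd, size=shapes.shape)
    coords = np.empty_like(shapes)
    rots = Rotation.random(n, rng=rng).as_matrix()
    trans = rng.uniform(-10.0, 10.0, size=(n, 3))
    for i in range(n):
        coords[i] = (shapes[i] * cs[i]) @ rots[i].T + trans[i]

    individuals = [f"ind{i + 1}" for i in range(n)]
    landmarks = LandmarkSet(individuals, [f"L{j}" for j in range(k)], coords)
    covars = CovariateTable(
        pd.DataFrame(
            {"sex": sex, "cross_direction": direction, "log_centroid_size": log_cs},
            index=pd.Index(individuals, name="individual"),
        )
    )
    truth = GroundTruth(
        qtl=list(cfg.qtl),
        qtl_effects_basis=betas,
        qtl_effects_displacement=(betas @ basis).reshape(len(cfg.qtl), k, 3),
        covariate_effects_basis={"sex": beta_sex, "cross_direction": beta_dir,
                                 "log_centroid_size": beta_allo},
        hidden_marker_genotypes=np.empty((0, 0), dtype=np.int8),
        hidden_qtl_genotypes=hidden_q,
        seed=cfg.seed,
    )
    return landmarks, covars, truth, base, basis, sym, region_map


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """End-to-end dataset: genotypes, landmarks, covariates and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    geno, gmap, hidden_m, hidden_q = simulate_backcross(cfg, rng)
    sex, direction = _strata_covariates(cfg, rng)
    landmarks, covars, truth, base, basis, sym, regions = simulate_shapes(
        hidden_q, cfg, rng, sex, direction
    )
    truth.hidden_marker_genotypes = hidden_m
    return SimulatedDataset(
        config=cfg,
        gmap=gmap,
        genotypes=geno,
        landmarks=landmarks,
        covariates=covars,
        symmetry=sym,
        regions=regions,
        truth=truth,
        base_shape=base,
        symmetric_basis=basis,
    )


def effect_magnitude_for_share(share: float, total_variance: float,
                               genotype_variance: float = 0.25) -> float:
    """Procrustes magnitude of a backcross effect explaining a variance share.

    A backcross HET indicator has variance 1/4, so an effect vector of
    magnitude b contributes b^2/4 to the total shape variance.
    """
    return float(np.sqrt(share * total_variance / genotype_variance))


def simulate_score_phenotype(
    G: np.ndarray,
    loci_idx: list[int],
    effect_vectors: np.ndarray,
    q: int,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Score-space phenotype shortcut: Y = sum_j g_j beta_j + N(0, noise_sd^2 I_q).

    Used for method calibration where the landmark pipeline is not under
    test; ``G`` holds genotype regressors (e.g. hidden genotypes or P(HET)).
    """
    n = G.shape[0]
    Y = rng.normal(0.0, noise_sd, size=(n, q))
    for j, idx in enumerate(loci_idx):
        Y += np.outer(G[:, idx] - G[:, idx].mean(), effect_vectors[j])
    return Y


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(dataset: SimulatedDataset, directory) -> dict[str, str]:
    """Write the full dataset as plain-text files; returns the path map.

    Emits the rotated cross CSV, long landmark CSV, symmetry/region metadata
    JSON, covariate CSV, a cM-bp anchor table (1 cM = 0.5 Mb within each
    chromosome, offset 3 Mb) and the ground-truth JSON.
    """
    from . import io as mio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "cross": str(directory / "cross.csv"),
        "landmarks": str(directory / "landmarks.csv"),
        "metadata": str(directory / "metadata.json"),
        "covariates": str(directory / "covariates.csv"),
        "anchors": str(directory / "anchors.csv"),
        "truth": str(directory / "ground_truth.json"),
    }
    cov_for_cross = CovariateTable(dataset.covariates.table[["sex", "cross_direction"]])
    mio.write_cross(paths["cross"], dataset.gmap, dataset.genotypes, cov_for_cross)
    mio.write_landmarks_csv(paths["landmarks"], dataset.landmarks)
    mio.write_symmetry_metadata(paths["metadata"], dataset.symmetry, dataset.regions)
    mio.write_covariates(paths["covariates"], dataset.covariates)
    anchors = pd.DataFrame(
        [
            {"chrom": c.name, "cM": cm, "bp": 3_000_000 + 500_000 * cm}
            for c in dataset.gmap.chromosomes
            for cm in (c.cm[0], c.cm[-1])
        ]
    )
    anchors.to_csv(paths["anchors"], index=False)
    truth = dataset.truth
    Path(paths["truth"]).write_text(
        json.dumps(
            {
                "seed": truth.seed,
                "qtl": [asdict(q) for q in truth.qtl],
                "qtl_effects_basis": truth.qtl_effects_basis.tolist(),
                "hidden_qtl_genotypes": truth.hidden_qtl_genotypes.tolist(),
                "hidden_marker_genotypes": truth.hidden_marker_genotypes.tolist(),
            }
        )
    )
    return paths
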