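"""File formats: cross CSV, landmark CSV/TPS, metadata JSON, anchors, results.

The cross file uses a rotated layout common in experimental-cross QTL work:
row 1 names the id/covariate columns then the markers, row 2 gives each
marker's chromosome, row 3 its cM position, and each following row is one
individual (id, sex, cross_direction, then genotype codes A/H/-).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genetics import (
    GENO_CODE_INV,
    GENO_CODE_MAP,
    ChromosomeMap,
    GeneticMap,
    MarkerGenotypes,
)
from .morphometrics import LandmarkSet, RegionMap, SymmetryMap
from .scan import CovariateTable, PermutationResult

_N_ID_COLS = 3  # id, sex, cross_direction


def read_cross(path) -> tuple[GeneticMap, MarkerGenotypes, CovariateTable]:
    """Parse the rotated cross CSV into map, genotypes and covariates."""
    raw = pd.read_csv(path, header=None, dtype=str)
    header = raw.iloc[0].tolist()
    markers = [str(m) for m in header[_N_ID_COLS:]]
    if len(set(markers)) != len(markers):
        raise ValueError("duplicate marker names in cross file")
    chroms = raw.iloc[1, _N_ID_COLS:].tolist()
    cms = raw.iloc[2, _N_ID_COLS:].astype(float).to_numpy()
    body = raw.iloc[3:]
    individuals = body.iloc[:, 0].astype(str).tolist()
    sex = body.iloc[:, 1].astype(float).to_numpy()
    direction = body.iloc[:, 2].astype(float).to_numpy()
    codes = np.empty((len(individuals), len(markers)), dtype=np.int8)
    geno_str = body.iloc[:, _N_ID_COLS:].to_numpy(dtype=str)
    for i in range(geno_str.shape[0]):
        for j in range(geno_str.shape[1]):
            code = geno_str[i, j]
            if code not in GENO_CODE_MAP:
                raise ValueError(
                    f"invalid genotype code {code!r} for individual "
                    f"{individuals[i]!r} at marker {markers[j]!r}"
                )
            codes[i, j] = GENO_CODE_MAP[code]
    chrom_maps = []
    order: list[str] = []
    for c in chroms:
        if c not in order:
            order.append(c)
    for c in order:
        sel = [j for j, cc in enumerate(chroms) if cc == c]
        chrom_maps.append(
            ChromosomeMap(name=str(c), markers=[markers[j] for j in sel], cm=cms[sel])
        )
    gmap = GeneticMap(chrom_maps)
    geno = MarkerGenotypes(individuals, gmap.marker_names, codes)
    covars = CovariateTable(
        pd.DataFrame({"sex": sex, "cross_direction": direction},
                     index=pd.Index(individuals, name="individual"))
    )
    return gmap, geno, covars


def write_cross(path, gmap: GeneticMap, geno: MarkerGenotypes,
                covars: CovariateTable) -> None:
    """Write the rotated cross CSV (inverse of :func:`read_cross`)."""
    markers = gmap.marker_names
    if geno.markers != markers:
        raise ValueError("genotype markers do not match the map")
    chrom_row, cm_row = [], []
    for c in gmap.chromosomes:
        chrom_row += [c.name] * c.n_markers
        cm_row += [f"{v:.12g}" for v in c.cm]
    lines = [
        ",".join(["id", "sex", "cross_direction", *markers]),
        ",".join(["", "", "", *chrom_row]),
        ",".join(["", "", "", *cm_row]),
    ]
    tab = covars.table
    for i, ind in enumerate(geno.individuals):
        row = tab.loc[ind]
        geno_codes = [GENO_CODE_INV[int(c)] for c in geno.codes[i]]
        lines.append(
            ",".join([ind, f"{row['sex']:g}", f"{row['cross_direction']:g}", *geno_codes])
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def read_landmarks_csv(path) -> LandmarkSet:
    """Long-format landmarks: columns specimen_id, landmark, x, y, z (mm)."""
    df = pd.read_csv(path, dtype={"specimen_id": str, "landmark": str})
    specimens = list(dict.fromkeys(df["specimen_id"]))
    landmarks = list(dict.fromkeys(df["landmark"]))
    k, n = len(landmarks), len(specimens)
    coords = np.full((n, k, 3), np.nan)
    si = {s: i for i, s in enumerate(specimens)}
    li = {l: i for i, l in enumerate(landmarks)}
    for _, row in df.iterrows():
        coords[si[row["specimen_id"]], li[row["landmark"]]] = (row["x"], row["y"], row["z"])
    return LandmarkSet(specimens, landmarks, coords)


def write_landmarks_csv(path, data: LandmarkSet) -> None:
    n, k = data.n, data.k
    df = pd.DataFrame(
        {
            "specimen_id": np.repeat(data.specimens, k),
            "landmark": np.tile(data.landmarks, n),
            "x": data.coords[:, :, 0].ravel(),
            "y": data.coords[:, :, 1].ravel(),
            "z": data.coords[:, :, 2].ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_tps(path) -> LandmarkSet:
    """Minimal TPS reader for LM3 blocks (3D landmarks with ID lines)."""
    specimens, blocks = [], []
    current: list[list[float]] = []
    expected = 0
    sid = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        up = line.upper()
        if up.startswith("LM3="):
            if current:
                blocks.append(current)
                specimens.append(sid or f"specimen_{len(blocks)}")
            expected = int(line.split("=", 1)[1])
            current, sid = [], None
        elif up.startswith("ID="):
            sid = line.split("=", 1)[1]
        elif up[0].isdigit() or up[0] in "+-.":
            current.append([float(v) for v in line.split()])
    if current:
        blocks.append(current)
        specimens.append(sid or f"specimen_{len(blocks)}")
    if not blocks:
        raise ValueError("no LM3 blocks found")
    k = len(blocks[0])
    if any(len(b) != k for b in blocks) or (expected and expected != k):
        raise ValueError("inconsistent landmark counts across TPS blocks")
    coords = np.asarray(blocks, dtype=float)
    return LandmarkSet(specimens, [f"L{i}" for i in range(k)], coords)


def write_symmetry_metadata(path, sym: SymmetryMap, regions: RegionMap | None = None) -> None:
    meta = {"pairs": [list(p) for p in sym.pairs], "midline": list(sym.midline)}
    if regions is not None:
        meta["regions"] = {str(i): list(v) for i, v in regions.regions.items()}
    Path(path).write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Covariates, anchors, results
# ---------------------------------------------------------------------------

def read_covariates(path) -> CovariateTable:
    df = pd.read_csv(path, dtype={"individual": str}).set_index("individual")
    return CovariateTable(df)


def write_covariates(path, covars: CovariateTable) -> None:
    covars.table.to_csv(path, float_format="%.12g")


def read_anchors(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"chrom", "cM", "bp"}
    if not need.issubset(df.columns):
        raise ValueError(f"anchor table must have columns {sorted(need)}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_scan(path, scan: pd.DataFrame) -> None:
    scan.to_csv(path, index=False, float_format="%.10g")


def write_permutation(prefix, perm: PermutationResult) -> None:
    """Permutation maxima as CSV plus an {alpha, threshold, n_perm, seed} JSON."""
    prefix = Path(prefix)
    pd.DataFrame({"max_score": perm.maxima}).to_csv(
        prefix.with_suffix(".maxima.csv"), index=False, float_format="%.10g"
    )
    prefix.with_suffix(".json").write_text(
        json.dumps(
            {
                "alpha": perm.alpha,
                "threshold": perm.threshold,
                "n_perm": perm.n_perm,
                "seed": perm.seed,
            },
            indent=1,
        )
    )


def read_threshold(path) -> float:
    return float(json.loads(Path(path).read_text())["threshold"])


def write_trace_jsonl(path, trace: list[dict]) -> None:
    with open(path, "w") as fh:
        for rec in trace:
            fh.write(json.dumps(rec) + "\n")


def write_bed(path, bed: pd.DataFrame) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved settings of a pipeline run; unknown keys are rejected."""

    cross: str = ""
    landmarks: str = ""
    metadata: str = ""
    covariates: str = ""
    anchors: str = ""
    output_dir: str = "."
    grid_step: float = 1.0
    error_rate: float = 1e-4
    n_perm: int = 1000
    alpha: float = 0.05
    max_qtl: int = 50
    coverage: float = 0.95
    eigen_tol: float = 1e-9
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]
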