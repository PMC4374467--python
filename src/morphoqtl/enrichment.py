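"""Interval-to-gene overlap and hypergeometric enrichment.

Given QTL credible intervals in bp and a gene annotation, candidate genes
are those overlapping any interval; enrichment of a training gene set among
the candidates is assessed by the exact hypergeometric upper tail
P(X >= k) for k training genes among n candidates, with K training genes in
a genome of N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .multiqtl import CredibleInterval


@dataclass
class EnrichmentResult:
    N: int  # genes in the genome universe
    K: int  # training genes in the universe
    n: int  # candidate genes in the intervals
    k: int  # training genes among the candidates
    p: float  # upper-tail P(X >= k)


def read_gene_annotation(path, fmt: str = "bed") -> pd.DataFrame:
    """Gene annotation as (symbol, chrom, start, end), 1-based inclusive.

    BED input (0-based half-open: chrom, start, end, name) is converted to
    1-based inclusive coordinates; 'csv' expects columns symbol, chrom,
    start, end already 1-based inclusive.
    """
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "symbol"])
        df["start"] = df["start"].astype(int) + 1
        df["end"] = df["end"].astype(int)
    elif fmt == "csv":
        df = pd.read_csv(path)
        df = df[["symbol", "chrom", "start", "end"]]
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    df["chrom"] = df["chrom"].astype(str)
    if (df["start"] > df["end"]).any():
        raise ValueError("gene with start > end")
    if df["symbol"].duplicated().any():
        raise ValueError("duplicate gene symbols in annotation")
    return df.reset_index(drop=True)


def genes_in_intervals(
    annotation: pd.DataFrame,
    intervals: list[CredibleInterval],
    mode: str = "any",
) -> list[str]:
    """Genes overlapping the credible intervals (1-based inclusive bp).

    mode 'any': one shared bp suffices; mode 'contained': the gene span must
    lie entirely within an interval.  Genes hit by several intervals are
    counted once.
    """
    if mode not in ("any", "contained"):
        raise ValueError("mode must be 'any' or 'contained'")
    hits: list[str] = []
    seen: set[str] = set()
    for _, g in annotation.iterrows():
        for ci in intervals:
            if ci.lower_bp is None or ci.upper_bp is None:
                raise ValueError(
                    "interval lacks bp bounds; convert cM bounds with cm_to_bp anchors"
                )
            if str(ci.chrom) != g["chrom"]:
                continue
            lo, hi = ci.lower_bp, ci.upper_bp
            if mode == "any":
                ok = g["start"] <= hi and g["end"] >= lo
            else:
                ok = g["start"] >= lo and g["end"] <= hi
            if ok and g["symbol"] not in seen:
                seen.add(g["symbol"])
                hits.append(g["symbol"])
                break
    return hits


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Exact hypergeometric upper tail P(X >= k), summed in log space."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError("inconsistent counts: need 0 <= k <= min(K, n) <= N")
    if k == 0:
        return EnrichmentResult(N, K, n, k, 1.0)
    support = np.arange(k, min(K, n) + 1)
    logp = stats.hypergeom.logpmf(support, N, K, n)
    p = float(np.exp(logsumexp(logp)))
    return EnrichmentResult(N, K, n, k, min(p, 1.0))


def enrichment_from_lists(
    annotation: pd.DataFrame,
    intervals: list[CredibleInterval],
    training_genes: list[str],
    universe_size: int | None = None,
    mode: str = "any",
) -> tuple[EnrichmentResult, list[str]]:
    """Full enrichment pipeline: overlap, count, exact upper-tail p.

    The universe defaults to the annotation size; pass ``universe_size`` to
    use an external genome-wide gene count.
    """
    training = set(training_genes)
    candidates = genes_in_intervals(annotation, intervals, mode=mode)
    N = universe_size if universe_size is not None else len(annotation)
    K = len(training & set(annotation["symbol"])) if universe_size is None else len(training)
    n = len(candidates)
    k = len(training & set(candidates))
    return hypergeometric_enrichment(N, K, n, k), candidates
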