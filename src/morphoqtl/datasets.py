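"""Published reference QTL tables from a C57BL/6J x A/J backcross skull study.

Bundled for interval arithmetic, worked examples and tests: seven skull
centroid-size QTL and thirty skull shape QTL with their Bayes credible
interval bounds in bp (mouse reference genome GRCm38), plus the gene counts
behind the craniofacial-gene enrichment computation (known autosomal genes,
curated craniofacial training genes, candidate genes within the shape-QTL
intervals and the training genes among them).
"""

from __future__ import annotations

import pandas as pd

# Skull centroid-size QTL: name, closest marker, chromosome, position (cM),
# LOD, Bayes credible interval bounds (bp).
_SIZE_QTL = [
    ("SCS.qtl1", "rs3658927", "2", 60.37, 3.33, 52_795_574, 141_957_105),
    ("SCS.qtl2", "rs13478002", "4", 68.08, 4.85, 129_338_356, 142_748_609),
    ("SCS.qtl3", "rs13478540", "5", 72.26, 4.71, 117_927_219, 137_110_565),
    ("SCS.qtl4", "rs13478841", "6", 34.74, 5.42, 51_455_318, 87_816_657),
    ("SCS.qtl5", "rs13481127", "11", 48.5, 4.41, 45_970_896, 91_694_862),
    ("SCS.qtl6", "mCV24625340", "13", 44.75, 7.81, 53_171_098, 94_326_861),
    ("SCS.qtl7", "rs4160288", "16", 4.43, 4.6, 4_326_565, 16_886_506),
]

# Skull shape QTL: name, closest marker, chromosome, position (cM), logP,
# Bayes credible interval bounds (bp).
_SHAPE_QTL = [
    ("SSH.qtl1", "mCV24784983", "1", 10.5, 12.0, 5_920_984, 25_974_921),
    ("SSH.qtl2", "rs3678634", "1", 52.6, 28.3, 115_819_089, 127_021_793),
    ("SSH.qtl3", "rs13466711", "1", 78.6, 17.7, 168_066_210, 175_710_316),
    ("SSH.qtl4", "rs13480734", "10", 52.9, 18.3, 89_335_908, 105_325_377),
    ("SSH.qtl5", "rs13481127", "11", 48.5, 27.3, 80_139_712, 81_911_051),
    ("SSH.qtl6", "rs3672597", "11", 77.5, 24.8, 112_611_769, 114_027_932),
    ("SSH.qtl7", "rs3717860", "12", 8.8, 32.5, 16_866_101, 28_237_591),
    ("SSH.qtl8", "rs3710348", "13", 13.4, 19.5, 30_941_216, 35_713_142),
    ("SSH.qtl9", "gnf13.115.241", "13", 62.8, 13.4, 110_281_304, 118_066_332),
    ("SSH.qtl10", "rs6396829", "14", 20.1, 28.1, 30_970_692, 38_186_621),
    ("SSH.qtl11", "CEL-15_43206205", "15", 16.8, 15.0, 39_391_647, 47_392_759),
    ("SSH.qtl12", "rs4191367", "16", 35.4, 13.9, 54_657_678, 66_961_706),
    ("SSH.qtl13", "rs6298471", "17", 19.2, 23.8, 36_252_692, 43_916_321),
    ("SSH.qtl14", "rs6328845", "18", 31.3, 11.4, 56_230_871, 70_306_352),
    ("SSH.qtl15", "rs3023496", "19", 40.1, 17.0, 46_867_039, 49_396_956),
    ("SSH.qtl16", "rs13476580", "2", 44.3, 20.6, 72_637_926, 76_844_869),
    ("SSH.qtl17", "rs6209325", "2", 73.3, 16.5, 146_817_118, 155_755_548),
    ("SSH.qtl18", "rs6246699", "3", 18.0, 14.6, 34_942_416, 39_449_337),
    ("SSH.qtl19", "rs4138887", "3", 44.0, 13.4, 96_754_992, 130_100_724),
    ("SSH.qtl20", "rs3660863", "4", 3.1, 9.7, 3_867_296, 11_352_972),
    ("SSH.qtl21", "rs3711477", "4", 40.1, 20.5, 81_877_569, 105_794_559),
    ("SSH.qtl22", "rs3663950", "4", 65.1, 23.2, 126_198_546, 134_724_460),
    ("SSH.qtl23", "rs13459085", "5", 17.3, 24.8, 20_284_721, 35_523_469),
    ("SSH.qtl24", "CEL-5_117374791", "5", 59.3, 14.7, 117_729_579, 119_888_175),
    ("SSH.qtl25", "rs6181382", "6", 35.5, 34.8, 78_232_602, 84_781_463),
    ("SSH.qtl26", "rs6265387", "6", 78.2, 27.3, 144_446_852, 148_260_112),
    ("SSH.qtl27", "rs13479395", "7", 49.5, 16.4, 78_470_627, 90_617_547),
    ("SSH.qtl28", "rs13479776", "8", 29.7, 23.2, 47_753_313, 78_304_228),
    ("SSH.qtl29", "rs3714664", "9", 22.5, 11.3, 39_523_343, 46_544_750),
    ("SSH.qtl30", "rs13480351", "9", 49.5, 16.0, 90_683_187, 99_809_852),
]

_COLS = ["qtl", "closest_marker", "chrom", "pos_cM", "score", "lower_ci_bp", "upper_ci_bp"]

# Craniofacial-gene enrichment counts: known autosomal genes, curated
# craniofacial training genes, candidate genes within the shape-QTL
# intervals, training genes among the candidates.
ENRICHMENT_COUNTS = {"N": 22_644, "K": 102, "n": 2_476, "k": 23}


def size_qtl_table() -> pd.DataFrame:
    """The seven skull centroid-size QTL with bp credible-interval bounds."""
    return pd.DataFrame(_SIZE_QTL, columns=_COLS)


def shape_qtl_table() -> pd.DataFrame:
    """The thirty skull shape QTL with bp credible-interval bounds."""
    return pd.DataFrame(_SHAPE_QTL, columns=_COLS)


def interval_widths_mb(table: pd.DataFrame) -> pd.Series:
    """Credible-interval widths in megabases."""
    return (table["upper_ci_bp"] - table["lower_ci_bp"]) / 1e6
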