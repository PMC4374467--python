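import numpy as np
import pytest

from morphoqtl.genetics import HMMConfig, genotype_probabilities
from morphoqtl.scan import QTLScanData
from morphoqtl.simulate import PlantedQTL, SimulationConfig, simulate_backcross


@pytest.fixture(scope="session")
def small_backcross():
    """A small backcross with genotype probabilities on a 1-cM grid."""
    cfg = SimulationConfig(
        n=200, n_chrom=3, markers_per_chrom=8, chrom_length_cm=49.0,
        qtl=(PlantedQTL("2", 21.0, 1.0),), seed=42,
    )
    geno, gmap, hidden_m, hidden_q = simulate_backcross(cfg)
    probs = genotype_probabilities(geno, gmap, HMMConfig())
    return {"cfg": cfg, "geno": geno, "gmap": gmap, "hidden_m": hidden_m,
            "hidden_q": hidden_q, "probs": probs}


def make_scan_bundle(probs, Y, X=None, names=None):
    n = Y.shape[0]
    if X is None:
        X = np.ones((n, 1))
        names = ["intercept"]
    return QTLScanData(probs.grid, probs.het, Y, X, names or ["intercept"])
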