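# morphoqtl

Multivariate QTL mapping for 3D landmark shape data from experimental
crosses.

Morphological shape is a high-dimensional trait: after generalized
Procrustes superimposition, a configuration of k landmarks varies in a
tangent space of far more dimensions than any single measurement captures.
`morphoqtl` maps quantitative trait loci for such traits in an N2 backcross
— the motivating application is the mouse skull (C57BL/6J × A/J, 53
landmarks, ~880 SNPs) — treating shape as one multivariate phenotype rather
than mapping principal components one at a time. It is aimed at
geneticists and morphometricians who have per-specimen 3D landmarks, a
marker map with genotypes, and covariates, and want mapped loci with
genome-wide significance, credible intervals, effect decompositions, and
candidate-gene enrichment.

## The method

1. **Shape phenotype.** Full generalized Procrustes analysis with object
   symmetry: each configuration is superimposed together with its
   reflected, relabeled copy; the symmetric component (the average of the
   pair) is projected onto the tangent space at the consensus and reduced
   by PCA to the non-zero-eigenvalue subspace. For p bilateral pairs and l
   midline landmarks this subspace has exactly 3p + 2l − 4 dimensions (80
   for the 22-pair, 9-midline skull set). Centroid size is the size trait.

2. **Genotype probabilities.** A two-state hidden Markov model (HOM/HET)
   with genotyping error ε = 10⁻⁴ gives P(genotype | markers) at every
   centimorgan, using the Carter–Falconer map function
   d(r) = 12.5 ln((1+2r)/(1−2r)) + 25 arctan(2r) to respect crossover
   interference.

3. **Genome scan.** At each position, Haley–Knott regression of the score
   matrix y ~ N_q(μ + Σ_c x_ic β_c + p_i β, S) on covariates plus P(HET);
   evidence is Pillai's trace V = tr[H(H+E)⁻¹] through its approximate F,
   reported as logP = −log₁₀ p (a multivariate LOD analog). Size uses
   LOD = (n/2) log₁₀(RSS₀/RSS₁). Genome-wide thresholds come from
   permutations that reshuffle phenotype and covariates jointly against
   fixed genotypes.

4. **Multiple-QTL model.** Forward search to 50 QTL and backward
   elimination to the null, scored by the penalized joint logP
   (model logP − T·n_QTL, T the permutation threshold), with iterative
   position refinement conditional on the other QTL. Per-QTL 95% Bayes
   credible intervals come from the 1/p profile normalized to unit mass
   over the chromosome.

5. **Effects and enrichment.** Effect magnitude ‖β‖ in Procrustes units,
   variance percentages, projection scores s = yβᵗ(ββᵗ)^−0.5, anatomical
   region decomposition against random-vector nulls, PC-angle statistics,
   interval→gene overlap, and exact hypergeometric enrichment.

A synthetic-data generator emulates the full study design (433 individuals
in four sex×direction strata, 19 autosomes, 53 landmarks) with planted QTL
and lossless ground truth, and backs every statistical test in the suite.

## Worked example

Simulate a 300-individual backcross with one planted shape QTL on
chromosome 3 at 28 cM whose effect explains 3% of the total shape variance,
then map it end to end:

```python
import numpy as np
from morphoqtl import (SimulationConfig, PlantedQTL, simulate_dataset,
                       gpa_object_symmetry, genotype_probabilities, HMMConfig,
                       make_scan_data, scan_shape, genome_wide_threshold,
                       forward_backward_search, qtl_credible_intervals,
                       fit_qtl_model, effect_magnitude_for_share)
from morphoqtl.multiqtl import model_report

mag = effect_magnitude_for_share(0.03, 5e-4)   # 3% of a 5e-4 total variance
cfg = SimulationConfig(n=300, n_chrom=5, markers_per_chrom=12,
                       chrom_length_cm=66.0,
                       qtl=(PlantedQTL("3", 28.0, mag),), seed=11)
ds = simulate_dataset(cfg)

shape = gpa_object_symmetry(ds.landmarks, ds.symmetry)
probs = genotype_probabilities(ds.genotypes, ds.gmap, HMMConfig())
data = make_scan_data(probs, shape, ds.covariates)

scan = scan_shape(data)
perm = genome_wide_threshold(data, n_perm=200, alpha=0.05, seed=11)
best, trace = forward_backward_search(data, perm.threshold, max_qtl=5)
report = model_report(data, best.loci,
                      qtl_credible_intervals(data, best.loci),
                      fit_qtl_model(data, best.loci))
```

which prints (via the session's `print` statements):

```
shape space: 300 specimens, 80 PCs
scan peak: chr 3 at 28.0 cM, logP = 34.73
genome-wide 5% threshold: 3.06
best model: 1 QTL, penalized score 31.67
 qtl chrom  pos_cM closest_marker  conditional_logP  lower_ci_cM  upper_ci_cM
QTL1     3    28.0           m3_5         34.729623         27.0         29.0
effect magnitude: 0.0087 Procrustes units (2.1% of total variance; planted 0.0077, 3%)
```

The 53-landmark configurations yield the expected 80 non-zero PCs, the scan
peaks at the planted position far above the genome-wide threshold, the
penalized search keeps exactly one QTL, its 95% credible interval spans
27–29 cM around the truth, and the fitted effect magnitude matches the
planted one up to sampling error.

The same workflow is available from the shell:

```bash
morphoqtl simulate --seed 11 --out data/
morphoqtl search --cross data/cross.csv --landmarks data/landmarks.csv \
    --metadata data/metadata.json --anchors data/anchors.csv \
    --n-perm 1000 --out results/
morphoqtl enrich --report results/qtl_report.csv --annotation genes.bed \
    --training craniofacial_genes.txt --out results/
```

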