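"""BSLMM GWAS and polygenic-score cross-validation on a synthetic trait.

Simulates genotypes for 200 individuals at 1,000 loci, builds a trait
with one large-effect locus (15% of variance) on a polygenic background
(35%), fits the Bayesian sparse linear mixed model, and validates the
polygenic scores by 4-fold masked-phenotype cross-validation.
"""

import numpy as np

from migrasv import BSLMMConfig, bslmm_fit, pgs_crossval
from migrasv.gwas import kinship
from migrasv.io import SVRecord
from migrasv.svmerge import CohortSVMatrix
from migrasv.synth import TraitModel, simulate_phenotypes

rng = np.random.default_rng(21)
n, p = 200, 1000
freqs = rng.uniform(0.1, 0.9, p)
dosages = rng.binomial(2, freqs[:, None], (p, n)).astype(np.int16)
loci = [SVRecord(id=f"sv{i:04d}", chrom="chr1", start=2000 * i, end=2000 * i + 100,
                 svtype="DEL", length=100) for i in range(p)]
matrix = CohortSVMatrix(loci, [f"ind{j:03d}" for j in range(n)], dosages)

table, effects = simulate_phenotypes(
    matrix, [TraitModel(name="trait", h2=0.35, focal={7: (0.15, 1.0)})], seed=22
)
y = table["trait"].to_numpy()
K = kinship(matrix)

config = BSLMMConfig(burn_in=2000, steps=8000, thin=8, n_chains=2, seed=23)
fit = bslmm_fit(y, matrix, K=K, config=config)
top = np.argsort(fit.pip)[::-1][:3]
print(f"posterior PVE: {fit.pve_mean:.2f} +/- {fit.pve_sd:.2f}  (truth 0.50)")
print("top PIPs:", [(loci[i].id, round(float(fit.pip[i]), 2)) for i in top])
# the focal locus sv0007 should carry the highest posterior inclusion
# probability; PVE estimates the chip heritability of the trait

pgs = pgs_crossval(y, matrix, K=K,
                   config=BSLMMConfig(burn_in=500, steps=2500, thin=5, n_chains=1, seed=24),
                   seed=25)
print(f"polygenic-score cross-validation: r = {pgs.r:.2f}, p = {pgs.p_value:.2g}")
# each individual's phenotype was masked in exactly one fold and predicted
# from the remaining 75%; a positive r with small p shows the SV set
# captures real trait variance
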