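import numpy as np
import pytest

from migrasv.io import GenomeLayout, SVRecord
from migrasv.svmerge import CohortSVMatrix


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout({"chr1": 1_000_000, "chr2": 500_000})


def make_matrix(dosages, chrom="chr1", spacing=3000, svtype="DEL", length=100):
    """Cohort matrix from a plain dosage array (loci x individuals)."""
    dosages = np.asarray(dosages, dtype=np.int16)
    loci = [
        SVRecord(
            id=f"l{i:04d}", chrom=chrom, start=spacing * i, end=spacing * i + length,
            svtype=svtype, length=length,
        )
        for i in range(dosages.shape[0])
    ]
    return CohortSVMatrix(loci, [f"i{j:03d}" for j in range(dosages.shape[1])], dosages)


def random_matrix(n_ind, n_loci, seed, maf_lo=0.1, maf_hi=0.9):
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_lo, maf_hi, n_loci)
    return make_matrix(rng.binomial(2, freqs[:, None], (n_loci, n_ind)))
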