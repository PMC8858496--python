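import numpy as np
import pandas as pd
import pytest

from heatgp.simdata import GenotypeMatrix


def make_genotypes(n, m, seed=0, n_chrom=1, freq_range=(0.1, 0.9),
                   spacing_bp=1000, breed="A", tier="array"):
    """Unstructured genotype matrix with independent SNPs."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*freq_range, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    per = np.array_split(np.arange(m), n_chrom)
    chrom = np.concatenate([np.full(len(ix), c + 1) for c, ix in enumerate(per)])
    pos = np.concatenate([(np.arange(len(ix)) + 1) * spacing_bp for ix in per])
    smap = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chromosome": chrom,
        "position_bp": pos,
        "ref_allele": "A",
        "alt_allele": "C",
        "tier": tier,
    })
    ids = np.array([f"i{i}" for i in range(n)], dtype=object)
    breeds = np.full(n, breed, dtype=object)
    return GenotypeMatrix(dos, smap, ids, breeds)


@pytest.fixture(scope="session")
def small_genotypes():
    return make_genotypes(200, 400, seed=11)
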