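import numpy as np
import pandas as pd
import pytest

from giltgwas.qc import GenotypeMatrix


def make_markers(n, chrom="1", start=1000, step=1000, prefix="SNP"):
    return pd.DataFrame(
        {
            "name": [f"{prefix}{i + 1}" for i in range(n)],
            "chrom": [str(chrom)] * n,
            "pos_bp": [start + i * step for i in range(n)],
            "allele1": ["B"] * n,
            "allele2": ["A"] * n,
        }
    )


def make_geno(codes, chroms=None):
    """GenotypeMatrix from a (n, m) code array; one chromosome unless given."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    if chroms is None:
        markers = make_markers(m)
    else:
        frames = []
        off = 0
        for c, k in chroms:
            frames.append(make_markers(k, chrom=c, prefix=f"SNP{c}_"))
            off += k
        markers = pd.concat(frames, ignore_index=True)
    return GenotypeMatrix(
        codes=codes, animal_ids=[f"A{i + 1}" for i in range(n)], markers=markers
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def toy_geno(rng):
    """Random complete 12 x 20 genotype matrix on two chromosomes."""
    codes = rng.integers(0, 3, size=(12, 20)).astype(np.int8)
    return make_geno(codes, chroms=[("1", 12), ("2", 8)])
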