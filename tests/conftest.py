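import numpy as np
import pandas as pd
import pytest

from cll_eqtl.genotype_ld import GenotypePanel


def panel_from_haplotypes(hap, loci=None, chrom="1"):
    """Build a phased panel from a (2n × L) 0/1 array."""
    hap = np.asarray(hap, dtype=np.int8)
    n2, L = hap.shape
    assert n2 % 2 == 0
    if loci is None:
        loci = pd.DataFrame(
            {
                "snp_id": [f"s{i + 1}" for i in range(L)],
                "chrom": chrom,
                "pos": [1000 * (i + 1) for i in range(L)],
                "ref": "A",
                "alt": "G",
            }
        )
    genotypes = hap[0::2] + hap[1::2]
    return GenotypePanel(
        sample_ids=[f"ind{i + 1}" for i in range(n2 // 2)],
        loci=loci,
        genotypes=genotypes,
        haplotypes=hap,
    )


@pytest.fixture
def two_locus_panel():
    """100 haplotypes with counts AB=40, Ab=10, aB=10, ab=40 (coded=1)."""
    blocks = [(1, 1)] * 40 + [(1, 0)] * 10 + [(0, 1)] * 10 + [(0, 0)] * 40
    return panel_from_haplotypes(np.array(blocks))


@pytest.fixture(scope="session")
def study_fx():
    from cll_eqtl import synthetic_data as synth

    return synth.study_fixture(seed=11)
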