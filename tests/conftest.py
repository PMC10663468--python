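import numpy as np
import pandas as pd
import pytest

from pdxevo.signatures import CONTEXTS_96, SignatureMatrix
from pdxevo.variants import VariantRecord


def make_signature_matrix(
    n_sigs: int = 4, seed: int = 0, names=None, alpha: float = 0.2
) -> SignatureMatrix:
    """Small synthetic SBS matrix: sparse Dirichlet columns, well separated."""
    rng = np.random.default_rng(seed)
    names = names or [f"SBS_T{i + 1}" for i in range(n_sigs)]
    data = rng.dirichlet(np.full(96, alpha), size=n_sigs).T
    return SignatureMatrix(pd.DataFrame(data, index=list(CONTEXTS_96), columns=names))


def make_record(chrom="chr1", pos=1000, ref="C", alt="T", **kw) -> VariantRecord:
    """A variant record that passes every filter unless overridden."""
    defaults = dict(
        callers=frozenset({"MuTect2", "Strelka"}),
        tumor_depth=100,
        tumor_alt_reads=30,
        normal_depth=60,
        normal_vaf=0.0,
        population_af=0.0,
    )
    defaults.update(kw)
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, **defaults)


@pytest.fixture
def signature_matrix():
    return make_signature_matrix()


@pytest.fixture(scope="session")
def toy_cytobands():
    from pdxevo.simulate import default_cytobands

    return default_cytobands()


@pytest.fixture(scope="session")
def toy_arms(toy_cytobands):
    from pdxevo.io import arms_from_cytobands

    arms, mask = arms_from_cytobands(toy_cytobands, telomere_bp=0)
    return arms, mask
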