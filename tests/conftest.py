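import numpy as np
import pytest

from poolsweep.poolio import PoolCounts


def make_counts(ref, alt, sizes=None, pos=None, chrom=None):
    """PoolCounts from explicit read matrices (snp x pool)."""
    ref = np.atleast_2d(np.asarray(ref))
    alt = np.atleast_2d(np.asarray(alt))
    s, k = ref.shape
    return PoolCounts(
        chrom=np.asarray(chrom if chrom is not None else ["1"] * s, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, s + 1) * 100),
        ref_allele=np.asarray(["A"] * s, dtype=object),
        alt_allele=np.asarray(["G"] * s, dtype=object),
        ref_reads=ref,
        alt_reads=alt,
        pool_names=[f"p{i}" for i in range(k)],
        pool_haploid_sizes=np.asarray(sizes if sizes is not None else [100] * k),
    )


@pytest.fixture
def tiny_counts():
    """3 SNPs x 2 pools, depth 40 everywhere."""
    ref = [[30, 20], [10, 25], [40, 5]]
    alt = [[10, 20], [30, 15], [0, 35]]
    return make_counts(ref, alt)


@pytest.fixture(scope="session")
def sim_counts_mid():
    """One mid-size Balding-Nichols simulation shared across tests."""
    from poolsweep.simdata import SimParams, simulate_pools

    params = SimParams(n_pools=2, n_snps=20_000, mean_depth=100, fst_target=0.10, seed=11)
    return simulate_pools(params)
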