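import numpy as np
import pytest

import biclink as b


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with two planted subgroups, reused across tests."""
    cfg = b.CohortConfig(
        n_participants=150,
        n_snps=400,
        n_lipids=40,
        n_subgroups=2,
        subgroup_size_range=(25, 35),
        snps_per_subgroup=25,
        lipids_per_subgroup=8,
        seed=42,
    )
    return cfg, b.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def hwe_sim_oracle(rng, n, n_snps, maf_lo=0.05, maf_hi=0.5):
    """Independent HWE-conforming SNPs: two binomial haplotypes per sample."""
    ps = []
    for _ in range(n_snps):
        q = rng.uniform(maf_lo, maf_hi)
        g = (rng.random(n) < q).astype(int) + (rng.random(n) < q).astype(int)
        ps.append(b.hwe_exact_test(int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum())))
    return np.asarray(ps)
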