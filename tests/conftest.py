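import numpy as np
import pytest

import kinlod as kl


@pytest.fixture(scope="session")
def biallelic():
    return kl.LocusModel("L1", ("A", "B"), np.array([0.5, 0.5]))


@pytest.fixture(scope="session")
def small_loci():
    """Three loci with 2, 3 and 4 alleles and asymmetric frequencies."""
    return [
        kl.LocusModel("L1", (100, 104), np.array([0.7, 0.3])),
        kl.LocusModel("L2", (100, 104, 108), np.array([0.5, 0.3, 0.2])),
        kl.LocusModel("L3", (100, 104, 108, 112), np.array([0.4, 0.3, 0.2, 0.1])),
    ]


@pytest.fixture(scope="session")
def fixture_bundle():
    return kl.study_fixture(1)


@pytest.fixture(scope="session")
def fixture_run(fixture_bundle):
    """Deduplicated fixture with context and all pair scores (shared)."""
    samples = fixture_bundle.samples
    provisional = kl.estimate_allele_freqs(samples)
    ctx0 = kl.KinshipModelContext(provisional, kl.ErrorModel(0.0077))
    dedup = kl.deduplicate(samples, ctx0, n_sim=20000, seed=3)
    loci = kl.estimate_allele_freqs(dedup.unique_individuals)
    ctx = kl.KinshipModelContext(loci, kl.ErrorModel(0.0077))
    scores = kl.score_all_pairs(dedup.unique_individuals, ctx)
    return {"bundle": fixture_bundle, "dedup": dedup, "loci": loci,
            "ctx": ctx, "scores": scores}
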