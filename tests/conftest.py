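import numpy as np
import pandas as pd
import pytest

from pgslink.config import SimConfig
from pgslink import simulate


SMALL_KWARGS = dict(
    n_discovery=1500, n_replication=800, n_gwas_exposure=1500,
    n_gwas_outcome=4000, n_proteins=10, pgs_n_variants=40,
    n_true_targets=4, n_trans_hit=4, n_distinct_regions=2,
    n_trial_causal=3,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, **SMALL_KWARGS)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One small simulated study shared across read-only tests."""
    ledger = simulate.make_truth(small_config)
    geno = simulate.simulate_genotypes(small_config)
    cohort, ledger = simulate.simulate_cohort(small_config, geno, ledger)
    return {"config": small_config, "ledger": ledger, "geno": geno,
            "cohort": cohort}


@pytest.fixture(scope="session")
def small_trial(small_study):
    cfg = small_study["config"]
    return simulate.simulate_trial(cfg, small_study["cohort"],
                                   small_study["ledger"])


def toy_genotypes(dosage_matrix, chrom=None, pos=None, mafs=None,
                  variant_ids=None):
    """Hand-built GenotypeMatrix for oracle tests."""
    D = np.asarray(dosage_matrix, dtype=float)
    n, m = D.shape
    variant_ids = variant_ids or [f"v{j}" for j in range(m)]
    variants = pd.DataFrame({
        "variant_id": variant_ids,
        "chrom": chrom if chrom is not None else [1] * m,
        "pos": pos if pos is not None else [1000 * (j + 1) for j in range(m)],
        "effect_allele": ["A"] * m,
        "other_allele": ["G"] * m,
        "maf": mafs if mafs is not None else D.mean(axis=0) / 2,
        "region_id": ["toy"] * m,
        "cis_protein": [""] * m,
    })
    return simulate.GenotypeMatrix(dosages=D, variants=variants,
                                   sample_ids=[f"s{i}" for i in range(n)])
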