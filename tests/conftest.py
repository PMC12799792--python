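import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from targetmr import SimConfig, generate_world, run_pipeline

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_world():
    """A compact world reused by structural tests across modules."""
    cfg = SimConfig(
        n_traits=10,
        n_genes=100,
        seed=7,
        n_approved_pairs=40,
        n_dev_pairs=20,
        frac_causal=0.05,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def small_run(small_world):
    """Full pipeline on the small world (model stages included)."""
    return run_pipeline(world=small_world)


def random_mr_fixture(rng, k):
    """Random exposure/outcome effect sets for estimator oracles."""
    bx = rng.normal(0.2, 0.1, k)
    bx[np.abs(bx) < 1e-3] = 0.05
    sy = rng.uniform(0.02, 0.2, k)
    by = 0.5 * bx + rng.normal(0, sy)
    sx = rng.uniform(0.005, 0.02, k)
    return bx, sx, by, sy


def gwas_frame(**overrides):
    """One-variant GWAS record with sensible defaults for unit fixtures."""
    base = {
        "variant_id": "rs1",
        "chrom": "1",
        "pos": 1_000_000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.02,
        "pval": 1e-6,
        "n": 10_000,
        "n_cases": np.nan,
    }
    base.update(overrides)
    return pd.DataFrame([base])
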