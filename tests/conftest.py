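import numpy as np
import pandas as pd
import pytest

from metaprs import synthgen
from metaprs.containers import GenotypeMatrix


@pytest.fixture(scope="session")
def small_pop_spec():
    return synthgen.PopulationSpec(
        n_variants=100, n_blocks=20, block_size=5,
        within_block_r2=0.3, fst_divergence=0.05,
    )


@pytest.fixture(scope="session")
def small_cohort(small_pop_spec):
    """600-sample two-stratum cohort with one quantitative and one binary trait."""
    traits = [
        synthgen.TraitSpec(name="hdl", n_causal=10, h2=0.3,
                           ancestry_effect_corr=0.7),
        synthgen.TraitSpec(name="t2d", kind="binary", n_causal=10, h2=0.3,
                           prevalence=0.169, ancestry_effect_corr=0.7),
    ]
    return synthgen.simulate_cohort(
        small_pop_spec, traits, {"EA": 300, "AA": 300}, seed=11
    )


@pytest.fixture()
def toy_genotypes():
    """Hand-sized dosage matrix: 6 samples x 4 variants, no LD structure."""
    dosages = np.array(
        [
            [0, 1, 2, 1],
            [1, 1, 0, 2],
            [2, 0, 1, 0],
            [0, 2, 1, 1],
            [1, 0, 0, 1],
            [2, 1, 1, 0],
        ],
        dtype=float,
    )
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(4)],
            "chrom": "1",
            "pos": [100, 200, 300, 400],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(
        dosages, variants, pd.Index([f"s{i}" for i in range(6)]),
        pd.Series(["EA"] * 3 + ["AA"] * 3),
    )
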