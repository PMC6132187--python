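import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles as `oracles`

from omicsqc import synthetic
from omicsqc.containers import AbundanceMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """40 brains x 3 modalities, 2,000 autosomal + 400 X variants."""
    cfg = synthetic.CohortConfig(
        n_brains=40, n_autosomal_variants=2000, n_x_variants=400, rng_seed=7
    )
    return synthetic.generate_genotypes(cfg)


@pytest.fixture(scope="session")
def default_proteomics():
    """Moderate default-parameter proteomics run with replicate pairs."""
    cfg = synthetic.ProteomicsSimConfig(
        n_proteins=300, n_samples=140, n_replicate_pairs=10, rng_seed=11
    )
    return synthetic.generate_proteomics(cfg)


def abundance_from_values(values: np.ndarray, batches, is_reference=None,
                          pairs=None) -> AbundanceMatrix:
    """Small helper to wrap a raw array as an AbundanceMatrix."""
    values = np.asarray(values, dtype=float)
    n_prot, n_samp = values.shape
    cols = pd.Index([f"s{j}" for j in range(n_samp)], name="sample_id")
    idx = pd.Index([f"p{i}" for i in range(n_prot)], name="protein")
    samples = pd.DataFrame(
        {
            "batch": list(batches),
            "is_reference": (
                [False] * n_samp if is_reference is None else list(is_reference)
            ),
        },
        index=cols,
    )
    return AbundanceMatrix(
        pd.DataFrame(values, index=idx, columns=cols), samples,
        replicate_pairs=pairs or [],
    )
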