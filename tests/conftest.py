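import numpy as np
import pandas as pd
import pytest

from twinewas.datatypes import MethylationDataset
from twinewas.simulate import SimConfig, generate_cohort

UNRELATED = {"mz_pairs": 0.0, "dz_pairs": 0.0, "singletons": 1.0}


@pytest.fixture(scope="session")
def small_twin_cohort():
    """400 samples with MZ/DZ families, 300 CpGs, no planted effects."""
    return generate_cohort(SimConfig(n_samples=400, n_cpgs=300, seed=11))


@pytest.fixture(scope="session")
def small_unrelated_cohort():
    return generate_cohort(
        SimConfig(n_samples=400, n_cpgs=300, seed=12, family_structure=dict(UNRELATED))
    )


def toy_dataset(beta, handedness, covariates=None, family=None, zygosity=None):
    """Hand-built MethylationDataset from a CpG × sample array."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    m, n = beta.shape
    cpgs = [f"cg{i:03d}" for i in range(m)]
    sids = [f"s{i:03d}" for i in range(n)]
    manifest = pd.DataFrame(
        {"chr": "1", "pos": np.arange(1, m + 1) * 100}, index=pd.Index(cpgs, name="cpg")
    )
    samples = pd.DataFrame(
        {
            "family_id": family if family is not None else [f"f{i}" for i in range(n)],
            "zygosity": zygosity if zygosity is not None else ["NA"] * n,
            "handedness": np.asarray(handedness, dtype=float),
        },
        index=pd.Index(sids, name="sample_id"),
    )
    if covariates is not None:
        for k, v in covariates.items():
            samples[k] = v
    return MethylationDataset(
        beta=pd.DataFrame(beta, index=manifest.index, columns=sids),
        manifest=manifest,
        samples=samples,
    )
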