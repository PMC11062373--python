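import numpy as np
import pandas as pd
import pytest

from slidefx.core_io import MethylationDataset


def make_dataset(n_cpgs=6, n_slides=2, samples_per_slide=2, seed=0):
    """Small hand-checkable dataset with uniform betas and simple annotations."""
    rng = np.random.default_rng(seed)
    n = n_slides * samples_per_slide
    cpgs = [f"cg{i:03d}" for i in range(n_cpgs)]
    samples = [f"s{i}" for i in range(n)]
    beta = pd.DataFrame(
        rng.uniform(0.05, 0.95, (n_cpgs, n)), index=pd.Index(cpgs, name="cpg_id"),
        columns=pd.Index(samples, name="sample_id"),
    )
    ann = pd.DataFrame(
        {
            "chromosome": [str(i % 4 + 1) for i in range(n_cpgs)],
            "position": 1000 + 100 * np.arange(n_cpgs),
        },
        index=beta.index,
    )
    sheet = pd.DataFrame(
        {"slide_id": [f"sl{i // samples_per_slide}" for i in range(n)]},
        index=beta.columns,
    )
    return MethylationDataset(beta=beta, annotations=ann, samples=sheet)


@pytest.fixture
def toy_dataset():
    return make_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
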