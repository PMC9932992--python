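import numpy as np
import pandas as pd
import pytest

from xidosage import simulate as sim
from xidosage.io import meta_frame
from xidosage.types import SampleMeta


@pytest.fixture(scope="session")
def lcl_cohort():
    """Full-design LCL cohort with sample truth (seed fixed)."""
    metas, truths = sim.generate_cohort(sim.DEFAULT_LCL_DESIGN, seed=11)
    return metas, truths


@pytest.fixture(scope="session")
def lcl_meta(lcl_cohort):
    return meta_frame(lcl_cohort[0])


@pytest.fixture()
def tiny_meta():
    """Six samples, two batches, xi = 0..2, mixed Y."""
    rows = [
        ("s1", "45,X", "b1"),
        ("s2", "46,XY", "b2"),
        ("s3", "46,XX", "b1"),
        ("s4", "47,XXY", "b2"),
        ("s5", "47,XXX", "b1"),
        ("s6", "48,XXXX", "b2"),
    ]
    metas = [
        SampleMeta.from_karyotype(sid, k, "LCL", batch) for sid, k, batch in rows
    ]
    return meta_frame(metas)


def random_counts(rng, n_genes=50, n_samples=6, low=1, high=2000):
    data = rng.integers(low, high, size=(n_genes, n_samples))
    return pd.DataFrame(
        data,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j + 1}" for j in range(n_samples)],
    )
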