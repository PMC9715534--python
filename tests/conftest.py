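import numpy as np
import pandas as pd
import pytest

from stylemorph.counts import CountMatrix
from stylemorph.simulate import SimulationConfig, simulate_bundle


def make_count_matrix(counts: dict[str, list[int]], genes: list[str],
                      tissues: dict[str, str] | None = None,
                      morphs: dict[str, str] | None = None) -> CountMatrix:
    """Small literal CountMatrix; metadata defaults to one tissue per sample."""
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))
    samples = list(df.columns)
    meta = pd.DataFrame({
        "tissue": [tissues.get(s, s) if tissues else s for s in samples],
        "morph": [morphs.get(s, "NA") if morphs else "NA" for s in samples],
        "species": "toy",
        "group": "",
    }, index=pd.Index(samples, name="sample_id"))
    return CountMatrix(df, meta)


@pytest.fixture(scope="session")
def small_bundle():
    """One modest synthetic study reused by read-only tests."""
    cfg = SimulationConfig(seed=11, n_orthogroups=300)
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
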