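import numpy as np
import pandas as pd
import pytest

from sweepscan import GenotypeDataset, SimConfig, simulate_cohort


def make_dataset(calls, chrom=None, pos=None, ref=None, alt=None, populations=None):
    """Small-dataset builder for hand-constructed fixtures."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    markers = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "ref": ref if ref is not None else ["A"] * m,
        "alt": alt if alt is not None else ["G"] * m,
    })
    samples = pd.DataFrame({
        "sample_id": [f"i{i}" for i in range(n)],
        "population": populations if populations is not None else ["pop"] * n,
    })
    return GenotypeDataset(markers, samples, calls)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest admixed cohort shared by read-only tests."""
    cfg = SimConfig(n_snps=1200, n_chromosomes=2, n_admixed=60, seed=42)
    cohort, hset, truth, panels, freq = simulate_cohort(cfg)
    return dict(cfg=cfg, cohort=cohort, hset=hset, truth=truth,
                panels=panels, freq=freq)
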