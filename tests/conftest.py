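import numpy as np
import pandas as pd
import pytest

from csdscan.genotypes import Call, GenotypeMatrix, SampleTable
from csdscan.synthetic import SimulationConfig, simulate_cohort


def build_matrix(
    positions,
    calls,
    samples=None,
    chrom="chr1",
    chrom_length=None,
    qual=50.0,
):
    """Assemble a GenotypeMatrix from positions and a (sites x samples) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 1:
        calls = calls[:, None]
    n_sites, n_samples = calls.shape
    samples = samples or [f"S{i + 1}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": "A",
            "alt": "T",
            "qual": qual,
        }
    )
    length = chrom_length or int(max(positions)) + 1000
    return GenotypeMatrix(sites, samples, calls, {chrom: length})


def build_samples(females=(), diploid_males=(), haploid_males=()):
    names = list(females) + list(diploid_males) + list(haploid_males)
    df = pd.DataFrame(
        {
            "sex": ["female"] * len(females) + ["male"] * (len(diploid_males) + len(haploid_males)),
            "ploidy": ["2"] * (len(females) + len(diploid_males)) + ["1"] * len(haploid_males),
            "group": "g",
            "role": "case",
        },
        index=pd.Index(names, name="sample"),
    )
    return SampleTable(df)


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort at default conditions, shared across tests."""
    cfg = SimulationConfig(seed=42)
    gm, st, mask, truth = simulate_cohort(cfg)
    return cfg, gm, st, mask, truth


HET, HOM_REF, HOM_ALT = Call.HET, Call.HOM_REF, Call.HOM_ALT
HAP_REF, HAP_ALT, MISSING = Call.HAP_REF, Call.HAP_ALT, Call.MISSING
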