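import numpy as np
import pandas as pd
import pytest

from parallelscan.core import MISSING, GenotypeMatrix, PopulationMap


def make_gm(dosage, chrom="chr1", start_pos=1, spacing=1, samples=None, ref="A", alt="C"):
    """Build a GenotypeMatrix from a (samples x sites) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if isinstance(chrom, str):
        chroms = [chrom] * n_sites
    else:
        chroms = list(chrom)
    pos, cur, last_chrom = [], start_pos, None
    for c in chroms:
        if c != last_chrom:
            cur = start_pos
            last_chrom = c
        pos.append(cur)
        cur += spacing
    sites = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref, "alt": alt})
    return GenotypeMatrix(sites, samples, dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_gm(rng):
    """10 samples x 200 sites random matrix with some missingness, for
    oracle-equivalence checks."""
    dosage = rng.integers(0, 3, size=(10, 200)).astype(np.int8)
    miss = rng.random((10, 200)) < 0.05
    dosage[miss] = MISSING
    return make_gm(dosage, spacing=37)


@pytest.fixture
def two_pop_map():
    return PopulationMap({f"s{i}": ("pop1" if i < 5 else "pop2") for i in range(10)})


@pytest.fixture(scope="session")
def null_sim():
    """One cached simulation of the no-gene-flow scenario, shared by tests."""
    from parallelscan.synthetic_data import scenario_library, simulate

    lib = scenario_library()
    return simulate(lib["null_no_flow"].with_genome([("chr1", 500_000), ("chr2", 500_000)]), 11)
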