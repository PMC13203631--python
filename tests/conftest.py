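import numpy as np
import pandas as pd
import pytest

from sweepscan.io_formats import SITE_COLUMNS, GenotypeMatrix, PopulationMap
from sweepscan.simulate import SimulationConfig, simulate


def make_gm(dosage, positions=None, chrom="chr1", samples=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from an (n_samples, n_sites) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "site_id": [f"v{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )[SITE_COLUMNS]
    return GenotypeMatrix(samples=samples, sites=sites, dosage=dosage)


def split_popmap(gm: GenotypeMatrix, n_a: int) -> PopulationMap:
    return PopulationMap(
        assignment={s: ("A" if i < n_a else "B") for i, s in enumerate(gm.samples)}
    )


@pytest.fixture(scope="session")
def two_pop_sim():
    """Strongly diverged two-population dataset (F = 0.3, 50+50 samples,
    2,000 sites on one 50-Mb chromosome)."""
    cfg = SimulationConfig(
        n_per_pop=50,
        n_sites=2000,
        divergence_fst=0.3,
        missing_rate=0.02,
        chrom_lengths={"chr1": 50_000_000},
        seed=5,
    )
    gm, pm, truth = simulate(cfg)
    return gm, pm, truth


@pytest.fixture(scope="session")
def small_sim():
    """Mildly diverged dataset for oracle comparisons (10+10 samples,
    200 sites)."""
    cfg = SimulationConfig(
        n_per_pop=10,
        n_sites=200,
        divergence_fst=0.1,
        missing_rate=0.05,
        chrom_lengths={"chr1": 1_000_000},
        seed=11,
    )
    gm, pm, truth = simulate(cfg)
    return gm, pm, truth
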