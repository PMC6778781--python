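import numpy as np
import pandas as pd
import pytest

from clinescan import GenotypeMatrix, SimScenario, simulate_panel


def make_matrix(dosage, chrom=None, pos=None, samples=None, ref=None, alt=None):
    """Small GenotypeMatrix from a literal dosage array (np.nan = missing)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(n)],
        variants=pd.DataFrame(
            {
                "snp_id": [f"v{j}" for j in range(m)],
                "chrom": chrom or ["1H"] * m,
                "pos": pos or list(range(100, 100 + 1000 * m, 1000)),
                "ref": ref or ["A"] * m,
                "alt": alt or ["G"] * m,
            }
        ),
        dosage=dosage,
    )


@pytest.fixture(scope="session")
def island_panel():
    """Two-island panel with moderate differentiation, no adaptive loci."""
    scenario = SimScenario(
        n_pops=2, n_per_pop=60, n_snps=500, target_fst=0.15,
        n_adaptive=0, missing_rate=0.02, seed=11,
    )
    g, meta, truth = simulate_panel(scenario)
    return g, meta, truth


@pytest.fixture(scope="session")
def structured_panel():
    """Eight-population panel exercising every standard partition."""
    scenario = SimScenario(
        n_pops=8, n_per_pop=25, n_snps=400, target_fst=0.10,
        n_adaptive=8, missing_rate=0.02, seed=7,
    )
    g, meta, truth = simulate_panel(scenario)
    return g, meta, truth
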