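import numpy as np
import pandas as pd
import pytest

from isochron import scqc, synthgen


@pytest.fixture(scope="session")
def panel():
    """The standard multi-condition expression panel, filtered + normalized."""
    adata = synthgen.simulate_counts(synthgen.default_expression_spec(seed=0, n_cells=120))
    adata = scqc.filter_genes(adata, 100, 2)
    return scqc.rpm_log2(adata)


@pytest.fixture(scope="session")
def imaging_cohort():
    """One simulated section: (cells, geometry, truth)."""
    spec = synthgen.CohortSimSpec(n_cells=300, center=0.35, spread_sd=0.12, seed=5)
    return synthgen.simulate_cohort(spec)


def random_cell_table(rng: np.random.Generator, n_sections: int = 3) -> pd.DataFrame:
    """Random detected-cell table for brute-force gating oracles."""
    parts = []
    for s in range(n_sections):
        n = int(rng.integers(3, 40))
        parts.append(
            pd.DataFrame(
                {
                    "section_id": f"s{s}",
                    "x": rng.uniform(0, 100, n),
                    "y": rng.uniform(0, 100, n),
                    "ft_intensity": rng.choice([0.5, 1.0, 2.0, 3.5, 7.0], n)
                    * rng.uniform(0.9, 1.1, n),
                    "brdu_intensity": rng.choice([0.0, 0.2, 1.0, 5.0], n)
                    * rng.uniform(0.9, 1.1, n),
                    "size": rng.uniform(20, 60, n),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)
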