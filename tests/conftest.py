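import numpy as np
import pandas as pd
import pytest

import supergene as sg


@pytest.fixture(scope="session")
def small_population():
    """11 S + 7 L samples, 2 contigs, 5 perfectly associated supergene SNPs."""
    cfg = sg.SupergeneSimConfig(n_S=11, n_L=7, n_snps=300, seed=42)
    gt, sheet = sg.simulate_supergene_population(cfg)
    return cfg, gt, sheet


@pytest.fixture(scope="session")
def sheet_15_15():
    n = 15
    return sg.SampleSheet(
        tuple([f"S{i:02d}" for i in range(n)] + [f"L{i:02d}" for i in range(n)]),
        tuple(["S"] * n + ["L"] * n),
        tuple(["pop"] * 2 * n),
    )


@pytest.fixture()
def toy_anova_data():
    """Balanced 2×2 with hand-computable sums of squares
    (SS: morph 50, treatment 8, interaction 2, residual 8)."""
    return pd.DataFrame(
        {
            "morph": ["L"] * 4 + ["S"] * 4,
            "treatment": ["control", "control", "eBL", "eBL"] * 2,
            "length": [10.0, 12.0, 11.0, 13.0, 4.0, 6.0, 7.0, 9.0],
        }
    )


def genotype_table_from_matrix(dosages, positions, contig="c1"):
    """Build a GenotypeTable from a samples × variants dosage matrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "contig": [contig] * m,
            "pos": list(positions),
            "start": [p - 1 for p in positions],
            "ref": ["A"] * m,
            "alt": ["T"] * m,
        }
    )
    return sg.GenotypeTable(
        variants=variants,
        dosages=dosages,
        sample_ids=tuple(f"s{i}" for i in range(n)),
    )
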