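import numpy as np
import pandas as pd
import pytest

from namqtl import gwas, nam_sim, pheno


@pytest.fixture(scope="session")
def tiny_config():
    """Small two-chromosome NAM design with a 4H allelic-series QTL."""
    return nam_sim.SimConfig(
        n_families=5,
        lines_per_family=40,
        snps_per_chromosome=20,
        chromosome_lengths={"1H": 150.0, "4H": 150.0},
        qtl=nam_sim.QtlSpec(
            chromosome="4H",
            position_cm=111.3,
            effects={"F02": 4.0, "F04": 2.5, "F05": 3.2},
        ),
        seed=101,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return nam_sim.simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_analysis(tiny_dataset):
    """BLUEs plus imputed genotypes for the tiny dataset."""
    ds = tiny_dataset
    blues = pheno.compute_blues(ds.phenotypes)
    geno = gwas.impute_dosages(ds.genotypes, ds.families)
    return ds, geno, blues


def balanced_records(rng, n_lines=20, n_years=2, n_reps=2, s2g=0.5, s2y=0.02, s2gy=0.2, s2r=0.1):
    """Direct two-way random-model records, independent of the simulator."""
    g = rng.normal(0, np.sqrt(s2g), n_lines)
    yr = rng.normal(0, np.sqrt(s2y), n_years)
    rows = []
    for i in range(n_lines):
        for t in range(n_years):
            gy = rng.normal(0, np.sqrt(s2gy))
            for k in range(n_reps):
                rows.append(
                    {
                        "line": f"L{i:03d}",
                        "year": f"Y{t + 1}",
                        "replicate": f"R{k + 1}",
                        "score": 3.0 + g[i] + yr[t] + gy + rng.normal(0, np.sqrt(s2r)),
                    }
                )
    return pd.DataFrame(rows)
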