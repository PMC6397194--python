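import numpy as np
import pandas as pd
import pytest

from repairimmune.cohort_io import ExpressionMatrix, compute_zscores
from repairimmune.synthetic_data import SimulationParams, simulate_cohort


SMALL_SIM = dict(
    n_samples=30,
    tmb_baseline_mean=20,
    n_genes=400,
    n_cell_types=6,
    n_mutation_genes=60,
    n_protein_genes=8,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort bundle."""
    return simulate_cohort(SimulationParams(seed=101, **SMALL_SIM))


@pytest.fixture(scope="session")
def small_bundle_dir(small_cohort, tmp_path_factory):
    """The small cohort written out as plain-text files."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = small_cohort.write(outdir)
    return outdir, paths


@pytest.fixture()
def toy_zscored_matrix():
    rng = np.random.default_rng(0)
    genes = [f"G{i:03d}" for i in range(50)]
    vals = pd.DataFrame(
        rng.lognormal(2.0, 0.5, (50, 6)), index=genes, columns=[f"S{i}" for i in range(6)]
    )
    return compute_zscores(ExpressionMatrix(values=vals))
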