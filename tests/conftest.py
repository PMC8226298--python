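import numpy as np
import pandas as pd
import pytest

import coextime as ct


@pytest.fixture(scope="session")
def small_sim():
    """A small compendium with two planted modules and known ground truth."""
    cfg = ct.SimConfig(
        seed=11,
        n_genes=300,
        n_experiments=4,
        samples_per_experiment=6,
        replicates_per_group=2,
        n_modules=2,
        module_size=10,
        module_phases=(8.0, 20.0),
    )
    return ct.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_cascade(small_sim):
    mat, meta, _ = small_sim
    return ct.normalize_cascade(mat, meta)


@pytest.fixture(scope="session")
def small_network(small_cascade):
    corr = ct.pcc_matrix(small_cascade.rnaseq4, axis="gene")
    ranks = ct.rank_matrix(corr, direction="co")
    mr = ct.mutual_rank(ranks)
    return ct.build_networks(mr)


def truth_phase_table(truth):
    """Phase table built from simulation ground truth (constant q)."""
    rhythmic = truth.rhythmic_genes()
    return ct.PhaseTable(
        pd.DataFrame({"phase": truth.phase[rhythmic], "q": 0.0}), source="truth"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
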