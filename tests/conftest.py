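import numpy as np
import pandas as pd
import pytest

import dielseason as ds
from dielseason import simulate as sim
from dielseason.experiment import mean_by_timepoint


@pytest.fixture(scope="session")
def small_population():
    """Three well-separated archetypes x 30 genes, with spike-ins."""
    specs, labels = sim.make_gene_population(
        {"3R": 30, "11Oa-postdusk": 30, "4D-EQ-peak": 30}, seed=11)
    exp, truth = sim.simulate_counts(sim.DesignSpec(seed=11), specs,
                                     dispersion=0.05, n_spikeins=5)
    return exp, truth, labels


@pytest.fixture(scope="session")
def small_mean_expr(small_population):
    exp, _truth, _labels = small_population
    norm = ds.cpm(exp)
    return mean_by_timepoint(norm.cpm.loc[~exp.spikein], exp.design)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
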