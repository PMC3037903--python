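import numpy as np
import pandas as pd
import pytest

from mirnarray import (
    SimulationConfig,
    TargetTable,
    make_array_design,
    simulate_probe_signals,
)
from mirnarray.preprocess import ExpressionMatrix

#: A scaled-down array design: 15 miRNA genes (10 human, 5 viral) across the
#: four probe-multiplicity classes, 2 positive controls, 4 negative probes.
SMALL_CLASSES = {2: 6, 3: 2, 4: 6, 1: 1}


@pytest.fixture(scope="session")
def small_design():
    return make_array_design(
        class_counts=SMALL_CLASSES,
        n_human=10,
        n_viral=5,
        n_pos_controls=2,
        n_neg_probes=4,
        neg_replicates=10,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return simulate_probe_signals(small_design, SimulationConfig(seed=42, n_spikein=4))


@pytest.fixture(scope="session")
def full_design():
    return make_array_design()


@pytest.fixture(scope="session")
def full_dataset(full_design):
    return simulate_probe_signals(full_design, SimulationConfig(seed=7))


@pytest.fixture()
def noise_free_dataset(small_design):
    config = SimulationConfig(
        seed=3, noise_sd=0.0, affinity_sd=0.0, bg_gradient=0.0, n_spikein=4
    )
    return simulate_probe_signals(small_design, config)


def make_targets(treatments, subjects=None):
    levels = list(dict.fromkeys(treatments))
    data = {
        "FileName": [f"arr{i}.txt" for i in range(len(treatments))],
        "Treatment": list(treatments),
        "GErep": [levels.index(t) + 1 for t in treatments],
    }
    if subjects is not None:
        data["Subject"] = list(subjects)
    return TargetTable(pd.DataFrame(data))


def make_exprs(values, treatments, gene_names=None):
    """Wrap a plain matrix as an ExpressionMatrix for DE-level tests."""
    values = np.asarray(values, dtype=float)
    targets = make_targets(treatments)
    return ExpressionMatrix(
        values=values,
        gene_names=gene_names or [f"g{i}" for i in range(values.shape[0])],
        array_names=targets.file_names,
        groups=targets.ge_rep,
        treatments=targets.treatments,
        method="rma",
    )
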