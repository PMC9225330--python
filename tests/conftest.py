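import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from immunets import synthetic as syn
from immunets.matrix import ExpressionMatrix


@pytest.fixture
def small_compendium():
    """One 8-gene module in CT1 of a 3-cell-type compendium, 30 samples/type."""
    spec = syn.CompendiumSpec(
        n_cell_types=3,
        states_per_type=3,
        samples_per_state=10,
        n_background_genes=60,
        modules=(
            syn.PlantedModule(
                tuple(f"MG{i + 1:03d}" for i in range(8)),
                ("CT1",),
                within_module_correlation=0.95,
            ),
        ),
        noise_sd=1.0,
        seed=7,
    )
    return syn.simulate_compendium(spec)


@pytest.fixture
def response_cohort():
    """15 vs 15 cohort with 20 genes planted 4-fold up in responders."""
    planted = tuple(f"G{i + 1:05d}" for i in range(20))
    spec = syn.ResponseCohortSpec(
        n_response=15,
        n_nonresponse=15,
        n_stable=4,
        n_genes=200,
        planted_up=planted,
        fold=4.0,
        dispersion=0.5,
        seed=1,
    )
    return syn.simulate_response_cohort(spec)


@pytest.fixture
def tiny_matrix():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]],
        index=["g1", "g2"],
        columns=["s1", "s2", "s3", "s4"],
    )
    ann = pd.DataFrame(
        {"cell_type": ["A", "A", "B", "B"]}, index=values.columns
    )
    return ExpressionMatrix(values, ann)
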