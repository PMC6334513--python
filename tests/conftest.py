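import numpy as np
import pandas as pd
import pytest

from detoxshift.simulate import SimulationConfig, default_design, simulate_counts
from detoxshift.types import CountMatrix, GeneCatalog, SampleDesign


@pytest.fixture(scope="session")
def design6x4():
    return default_design()


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced synthetic scenario shared by the slower integration tests."""
    cfg = SimulationConfig(
        n_background=2_000,
        family_counts={"P450": 30, "GST": 10, "COE": 8, "UDPGT": 20, "SULT": 6, "ABC": 16},
        n_constitutive_over_per_species=2,
        n_constitutive_under_per_species=1,
        machinery_multiplicity=((3, 4), (2, 6)),
        n_discordant_multi=4,
        n_single_plastic=20,
    )
    design = default_design()
    counts, catalog, truth = simulate_counts(design, cfg, seed=101)
    return counts, catalog, truth


@pytest.fixture()
def tiny_design():
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "species": ["A", "A", "B", "B"],
                "plant": ["eggplant"] * 4,
                "replicate": [1, 2, 1, 2],
            }
        )
    )


@pytest.fixture()
def tiny_counts(tiny_design):
    values = pd.DataFrame(
        [[10, 12, 30, 28], [5, 7, 5, 6], [100, 90, 40, 50]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=tiny_design.sample_ids,
    )
    return CountMatrix(values, tiny_design)


@pytest.fixture()
def catalog6():
    return GeneCatalog(
        {
            "g1": "P450",
            "g2": "GST",
            "g3": "COE",
            "g4": "UDPGT",
            "g5": "SULT",
            "g6": "ABC",
        }
    )
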