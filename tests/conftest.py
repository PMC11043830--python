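import pandas as pd
import pytest
from hypothesis import settings

from mossdiv import CommunityDataset, default_config, simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_records(rows):
    """rows: (pair, treatment, plot, quadrat, cell, species, count) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "treatment",
            "plot_id",
            "quadrat_id",
            "cell_id",
            "species",
            "count",
        ],
    )


@pytest.fixture
def tiny_dataset():
    """Two pairs, both treatments, two quadrats, a handful of cells."""
    rows = []
    for pair in ("p01", "p02"):
        for treatment in ("absence", "presence"):
            plot = f"{pair}_{treatment}"
            for quadrat in (1, 2):
                for cell in (1, 2, 3):
                    rows.append((pair, treatment, plot, quadrat, cell, "spA", 3))
                    rows.append((pair, treatment, plot, quadrat, cell, "spB", cell))
    registry = pd.DataFrame(
        {
            "species": ["spA", "spB"],
            "genus": ["genA", "genB"],
            "growth_form": ["acrocarp", "pleurocarp"],
        }
    )
    return CommunityDataset(records=make_records(rows), registry=registry)


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the full study design with the default treatment effects."""
    cfg = default_config()
    cfg.seed = 11
    return simulate_dataset(cfg)
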