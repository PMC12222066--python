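import numpy as np
import pandas as pd
import pytest

from standalloc import synthetic
from standalloc.datasets import load_harvest_trees


@pytest.fixture(scope="session")
def harvest():
    """The 20-tree harvest biomass table."""
    return load_harvest_trees()


@pytest.fixture(scope="session")
def mature_stand():
    """One deterministic mature-stand stem map (~84 trees expected)."""
    cfg = synthetic.StandConfig.from_age_group("mature", seed=42)
    return synthetic.generate_stand(cfg)


@pytest.fixture(scope="session")
def mature_chm(mature_stand):
    cfg = synthetic.StandConfig.from_age_group("mature")
    return synthetic.synthesize_chm(
        mature_stand, resolution=0.1, plot_width=cfg.plot_width, plot_height=cfg.plot_height
    )


def random_unit(rng, n=None):
    """One random structural unit: centre height, neighbour heights,
    distances and azimuths."""
    n = n or int(rng.integers(1, 9))
    return {
        "center_h": float(rng.uniform(5, 30)),
        "neighbor_h": rng.uniform(5, 30, n),
        "distances": rng.uniform(0.5, 10, n),
        "azimuths": rng.uniform(0, 360, n),
    }


def random_tree_frame(rng, n, width=25.82, height=25.82):
    xy = rng.uniform((0, 0), (width, height), size=(n, 2))
    return pd.DataFrame(
        {
            "tree_id": np.arange(1, n + 1),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "height": rng.uniform(8, 25, n),
            "crown_width": rng.uniform(1.5, 4, n),
            "dbh": rng.uniform(10, 35, n),
            "plot_id": "T",
            "age_group": "",
            "is_buffer": False,
        }
    )
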