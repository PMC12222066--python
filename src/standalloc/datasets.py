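"""Packaged reference tables.

``load_harvest_trees``
    The 20 destructively harvested Chinese fir trees used to build the
    organ biomass models: per-tree aboveground, stem, branch and leaf dry
    weights (kg), DBH (cm) and height (m).
``load_detection_counts``
    Per-plot tree-top detection bookkeeping for the 33 survey plots: the
    best local-maximum window, observed/detected/correct/error/missed
    counts, and the published detection rate, precision and F-score.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_harvest_trees", "load_detection_counts"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("standalloc.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_harvest_trees() -> pd.DataFrame:
    """Harvest biomass table (20 trees)."""
    return _read("harvest_trees.csv")


def load_detection_counts() -> pd.DataFrame:
    """Per-plot detection counts and published scores (33 plots)."""
    return _read("detection_counts.csv")
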