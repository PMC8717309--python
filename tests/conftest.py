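import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from harelink import datasets
from harelink.mobility import Patch


@pytest.fixture(scope="session")
def table1():
    """Derived-trait table of the packaged 44-species feeding experiment."""
    return datasets.table1_frame()


@pytest.fixture(scope="session")
def table1_records():
    return datasets.fixture_table1()


@pytest.fixture()
def toy_patches():
    """A 2x2 grid of 1 km unit squares: grassland / field / field / forest."""
    return [
        Patch("P1", "grassland", box(0, 0, 1000, 1000)),
        Patch("P2", "field", box(1000, 0, 2000, 1000)),
        Patch("P3", "field", box(0, 1000, 1000, 2000)),
        Patch("P4", "forest", box(1000, 1000, 2000, 2000)),
    ]


@pytest.fixture()
def hourly_track():
    def make(xy, start="2020-04-01T00:00:00", individual="h1"):
        xy = np.asarray(xy, dtype=float)
        return pd.DataFrame(
            {
                "individual_id": individual,
                "t": pd.date_range(start, periods=len(xy), freq="h"),
                "x": xy[:, 0],
                "y": xy[:, 1],
            }
        )

    return make
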