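import numpy as np
import pandas as pd
import pytest

from forestchange.datamodel import MODERN, PRECOLONIAL
from forestchange.simulate import SimConfig, generate, landscape_dataset


@pytest.fixture(scope="session")
def small_landscape():
    """A 6x5 synthetic landscape shared by read-only tests."""
    return generate(SimConfig(nx=6, ny=5, seed=7))


@pytest.fixture(scope="session")
def small_dataset(small_landscape):
    return landscape_dataset(small_landscape)


@pytest.fixture(scope="session")
def landscape_dir(small_landscape, tmp_path_factory):
    """The small landscape written in the on-disk dialects."""
    from forestchange.simulate import write_landscape
    outdir = tmp_path_factory.mktemp("landscape")
    write_landscape(small_landscape, outdir)
    return outdir


def make_trees(rows):
    """Build a tree table from (town, era, code, dbh, plot) tuples; raw_name
    and taxon_code are both set to the given code."""
    recs = []
    for town, era, code, dbh, plot in rows:
        recs.append({
            "town_id": town, "era": era, "raw_name": code, "taxon_code": code,
            "dbh_cm": dbh if era == MODERN else np.nan,
            "plot_id": plot if era == MODERN else pd.NA,
        })
    return pd.DataFrame(recs, columns=["town_id", "era", "raw_name",
                                       "taxon_code", "dbh_cm", "plot_id"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
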