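import numpy as np
import pandas as pd
import pytest

from fixverse.cleaning import build_catalog
from fixverse.io import Geometry, TrialSet
from fixverse.synthetic import SyntheticConfig, Trial, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_subjects=8, n_items=12, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def artifact_config():
    return SyntheticConfig(
        n_subjects=10,
        n_items=16,
        artifact_short_rate=0.3,
        artifact_long_rate=0.1,
        sparse_trial_rate=0.05,
        seed=23,
    )


@pytest.fixture(scope="session")
def artifact_dataset(artifact_config):
    return generate_dataset(artifact_config)


@pytest.fixture(scope="session")
def catalog_map():
    return {c.config_id: c for c in build_catalog()}


@pytest.fixture
def geometry():
    return Geometry(pixels_per_degree=40.0)


def make_trial(durs, xs=None, ys=None, ias=None):
    n = len(durs)
    return Trial(
        x=np.asarray(xs if xs is not None else np.arange(n) * 50.0, dtype=float),
        y=np.asarray(ys if ys is not None else np.full(n, 300.0), dtype=float),
        dur=np.asarray(durs, dtype=float),
        ia=np.asarray(ias if ias is not None else np.arange(1, n + 1), dtype=float),
    )


def trialset_from_rows(rows, items=None, geometry=None):
    """rows: list of dicts with the canonical fixation columns."""
    fx = pd.DataFrame(rows)
    fx["ia_index"] = pd.array(
        [None if pd.isna(v) else int(v) for v in fx["ia_index"]], dtype="Int64"
    )
    return TrialSet(
        fixations=fx, items=items, geometry=geometry or Geometry()
    )
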