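import warnings

import numpy as np
import pandas as pd
import pytest

import msbatch as mb


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Silence the advisory warnings (small batches, imputation) in tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", FutureWarning)
        yield


def make_annotation(samples, batches, run_order=None, groups=None, rep=None):
    frame = pd.DataFrame(
        {
            "sample_id": samples,
            "run_order": run_order if run_order is not None else range(1, len(samples) + 1),
            "batch": batches,
        }
    )
    bio = []
    if groups is not None:
        frame["group"] = groups
        bio = ["group"]
    rep_col = None
    if rep is not None:
        frame["replicate_group"] = rep
        rep_col = "replicate_group"
    return mb.SampleAnnotation(frame, batch_factors=["batch"], bio_factors=bio,
                               replicate_group=rep_col)


def table_from_wide(values, features=None, samples=None):
    """Build a long table from a 2-D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    wide = pd.DataFrame(values, index=features, columns=samples)
    wide.index.name = "feature_id"
    wide.columns.name = "sample_id"
    return mb.wide_to_long(wide)


@pytest.fixture(scope="session")
def default_sim():
    """The default simulated study, shared across tests (read-only)."""
    spec = mb.SimulationSpec(seed=20260921)
    return mb.simulate(spec)


@pytest.fixture(scope="session")
def fixture_dataset():
    return mb.worked_fixture()
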