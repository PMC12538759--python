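import warnings

import numpy as np
import pandas as pd
import pytest

from remap.instruments import Instrument, ItemResponseSet, Timepoint


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def make_mfi_items(responses: dict[int, int], pid="p1", tp=Timepoint.BSL):
    return ItemResponseSet(
        pid, tp, Instrument.MFI20, {str(k): v for k, v in responses.items()}
    )


def make_sf36_items(responses: dict[int, int], pid="p1", tp=Timepoint.BSL):
    return ItemResponseSet(
        pid, tp, Instrument.SF36, {str(k): v for k, v in responses.items()}
    )


@pytest.fixture(scope="session")
def trial_bundle():
    """One trial-shaped pipeline run shared across tests (seeded)."""
    from remap.pipeline import PipelineConfig, run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(PipelineConfig(seed=11, compare_imputers=False))
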