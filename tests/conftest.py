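import numpy as np
import pandas as pd
import pytest

from edukinetics import (
    DEFAULT_SAMPLE_TIMES,
    CellCycleParams,
    LabelingProtocol,
    LaggedRiseShape,
)


@pytest.fixture
def dmso_shape() -> LaggedRiseShape:
    return LaggedRiseShape(level0=0.436, break1=10.0, break2=21.0, plateau=0.95)


@pytest.fixture
def fzm1_shape() -> LaggedRiseShape:
    return LaggedRiseShape(level0=0.434, break1=16.0, break2=26.0, plateau=0.95)


@pytest.fixture
def lagged_protocol() -> LabelingProtocol:
    return LabelingProtocol(mode="lagged_rise")


@pytest.fixture
def agent_protocol() -> LabelingProtocol:
    return LabelingProtocol(mode="agent")


@pytest.fixture
def dmso_agent_params() -> CellCycleParams:
    return CellCycleParams(tc_mean=31.0, ts=10.0, growth_fraction=0.9)


def noiseless_aggregate(shape_fn, times=DEFAULT_SAMPLE_TIMES, n_fields=15) -> pd.DataFrame:
    """Aggregated curve whose means lie exactly on a given index function."""
    t = np.asarray(times, dtype=float)
    return pd.DataFrame(
        {
            "time_h": t,
            "mean_index": np.asarray(shape_fn(t), dtype=float),
            "sem": 0.0,
            "n_fields": n_fields,
        }
    )
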