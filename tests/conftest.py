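import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import behavcal as bc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The canonical synthetic cohort: 30 children, normal family,
    published reference moments, seed 0."""
    return bc.generate_cohort(bc.CohortConfig(seed=0))


@pytest.fixture()
def small_labeled() -> pd.DataFrame:
    """A tiny hand-checkable labelled frame: one channel, six behaviours,
    three epochs each, counts increasing with intensity."""
    rows = []
    for i, b in enumerate(bc.Behaviour):
        for j in range(3):
            rows.append(
                {
                    "child_id": "c1",
                    "device": bc.Device.MW8,
                    "position": bc.Position.WRIST,
                    "behaviour": b,
                    "epoch_index": j,
                    "count": float(10 * (i + 1) + j),
                }
            )
    return pd.DataFrame(rows)


def make_series(counts, child="c1", device=bc.Device.MW8, position=bc.Position.WRIST,
                start="2021-01-01T09:00:00", epoch_seconds=30.0) -> bc.EpochSeries:
    return bc.EpochSeries(
        child_id=child,
        device=device,
        position=position,
        start_time=pd.Timestamp(start),
        counts=np.asarray(counts, dtype=float),
        epoch_seconds=epoch_seconds,
    )
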