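import numpy as np
import pandas as pd
import pytest

import wearaq as wq


def utc_minutes(n, start="2019-11-04T00:00:00Z"):
    return pd.date_range(start, periods=n, freq="min", tz="UTC")


def series(values, channel="no2", start="2019-11-04T00:00:00Z"):
    vals = np.asarray(values, dtype=float)
    return wq.SensorSeries(channel,
                           pd.Series(vals, index=utc_minutes(len(vals), start)))


@pytest.fixture(scope="session")
def default_campaign():
    """Three participant-weeks with the default artifact model.

    Shared by curation-invariant and artifact-recall checks; truths carry
    the artifact ledger.
    """
    bundles, truths = wq.generate_campaign(n_participants=3,
                                           duration_days=7.0, seed=11)
    curated = [wq.curate(b) for b in bundles]
    return bundles, truths, curated


@pytest.fixture(scope="session")
def clean_campaign():
    """One clean participant-week: no artifacts, no pollution peaks."""
    emission = wq.EmissionModel(spike_rate={e: {} for e in wq.ENVIRONMENTS})
    sched = wq.generate_schedule(7, seed=5)
    traces = wq.generate_traces(sched, emission=emission,
                                artifacts=wq.ArtifactModel.none(), seed=6)
    return sched, traces
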