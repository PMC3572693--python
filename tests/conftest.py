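import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from critwin.synthetic import GeneratorConfig, SourceSet

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=25)
settings.load_profile("suite")


def make_sources(coords, n_days=400, active=None, regime="monitor",
                 origin="2001-01-01") -> SourceSet:
    """Hand-built source set for constructed exposure fixtures."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    frame = pd.DataFrame({
        "source_id": np.arange(len(coords)),
        "regime": regime,
        "x_km": coords[:, 0],
        "y_km": coords[:, 1],
    })
    if active is None:
        active = np.ones((len(coords), n_days), dtype=bool)
    return SourceSet(frame, np.asarray(active, dtype=bool),
                     pd.Timestamp(origin))


def make_cohort(rows) -> pd.DataFrame:
    """Cohort frame from (x, y, gestational_age, birth_day) tuples."""
    df = pd.DataFrame(rows, columns=["x_km", "y_km", "gestational_age",
                                     "birth_day"])
    df.insert(0, "birth_id", np.arange(len(df)))
    df["conception_day"] = df["birth_day"] - 7 * df["gestational_age"]
    return df


@pytest.fixture
def small_config():
    """Small-region configuration for fast generator tests."""
    return GeneratorConfig(n_births=300, region_extent=48.0, dense_spacing=4.0,
                           monitor_count=3, seed=7)


@pytest.fixture
def default_cohort_2k():
    cfg = GeneratorConfig(n_births=2000, seed=3)
    from critwin.synthetic import gen_cohort
    return gen_cohort(cfg)
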