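import numpy as np
import pandas as pd
import pytest

from bellwether import (
    DEFAULT_ANCHORS,
    FIELDLIKE_PARAMS,
    CampaignConfig,
    fit_beta_from_percentiles,
    generate_field_surveys,
    run_grid,
)


@pytest.fixture(scope="session")
def calibrated_dist():
    """Beta distribution calibrated to the shipped percentile anchors."""
    return fit_beta_from_percentiles(*DEFAULT_ANCHORS)


@pytest.fixture(scope="session")
def full_grid(calibrated_dist):
    """Full correlation x bellwether grid at 10,000 reps (run once)."""
    return run_grid(CampaignConfig(reps=10_000), calibrated_dist, seed=20_250_901)


@pytest.fixture(scope="session")
def fieldlike_surveys():
    """One synthetic survey table from the field-like preset."""
    return generate_field_surveys(
        params=FIELDLIKE_PARAMS, rng=np.random.default_rng(42)
    )


def make_exponential_surveys(
    n: int,
    mean_ttd: float,
    rng: np.random.Generator,
    year_ratio: float = 1.0,
    censor: float = 30.0,
) -> pd.DataFrame:
    """Minimal survey table with exponential TTD; optional year effect.

    Half the records are 2009 with mean ``mean_ttd * year_ratio``, half
    2010 with mean ``mean_ttd``.
    """
    year = np.where(np.arange(n) % 2 == 0, 2010, 2009)
    scale = np.where(year == 2010, mean_ttd, mean_ttd * year_ratio)
    t = rng.exponential(scale)
    detected = t <= censor
    t = np.minimum(t, censor)
    return pd.DataFrame(
        {
            "pond": [f"p{i:03d}" for i in range(n)],
            "year": year,
            "window": "middle",
            "method": "dipnet",
            "observer": "obs_a",
            "time_min": t,
            "detected": detected,
        }
    )
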