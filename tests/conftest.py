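import numpy as np
import pandas as pd
import pytest

from nipponia import simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic simulated data set shared by read-only tests."""
    cfg = simulate.SimConfig(n_individuals=2, n_days=30, seed=11)
    fixes, truth = simulate.simulate_trajectories(cfg)
    return cfg, fixes, truth


def make_drift_track(n: int, drift_m_per_h: float, seed: int) -> pd.DataFrame:
    """Synthetic track drifting north-east at a constant speed (+10 m noise)."""
    rng = np.random.default_rng(seed)
    ts = pd.date_range("2021-03-01", periods=n, freq="h")
    y = np.arange(n) * drift_m_per_h + rng.normal(0, 10, n)
    x = np.arange(n) * drift_m_per_h * 0.5 + rng.normal(0, 10, n)
    lat = 32.2 + y / 111194.9
    lon = 114.5 + x / (111194.9 * np.cos(np.radians(32.2)))
    return pd.DataFrame(
        {"individual_id": "a", "timestamp": ts, "lat": lat, "lon": lon, "imputed": False}
    )
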