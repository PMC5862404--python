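import numpy as np
import pandas as pd
import pytest

from avichange.synthetic_data import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A small seeded scenario shared by read-only tests: 8 species x 6
    parks x 2 seasons x 2 RCPs = 384 keys."""
    config = ScenarioConfig(n_parks=6, n_species=8, seed=42)
    return generate_scenario(config)


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Noise-free scenario where every planted class must be recovered
    exactly."""
    config = ScenarioConfig(n_parks=6, n_species=10, noise_sd=0.0, seed=7)
    return generate_scenario(config)


def make_key_df(values_by_period, species="SP0001", park="P001", season="summer", rcp="RCP8.5"):
    """Build the 12-row (or fewer) suitability frame for one key from a
    mapping {period: iterable of per-GCM values}."""
    from avichange.data_model import GCMS

    rows = []
    for period, vals in values_by_period.items():
        for gcm, v in zip(GCMS, vals):
            rows.append(
                {
                    "species_id": species, "park_id": park, "season": season,
                    "rcp": rcp, "gcm": gcm, "period": period, "suitability": v,
                }
            )
    return pd.DataFrame(rows)


def ols_closed_form(x, y):
    """Independent closed-form OLS oracle: slope, intercept, two-sided p."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = np.sum((x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    ss_res = np.sum(resid**2)
    se = np.sqrt(ss_res / (n - 2) / sxx)
    if se == 0:
        p = 1.0 if slope == 0 else 0.0
    else:
        p = 2 * t_dist.sf(abs(slope / se), n - 2)
    return slope, intercept, p
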