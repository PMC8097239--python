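import numpy as np
import pandas as pd
import pytest

import openinterval as oi


@pytest.fixture(scope="session")
def high_survey() -> pd.DataFrame:
    """Niger-like high-fertility simulated survey."""
    return oi.simulate_survey(oi.high_fertility_preset(cohort_size=8000, seed=42).config)


@pytest.fixture(scope="session")
def trans_survey() -> pd.DataFrame:
    """Colombia-like transitional-fertility simulated survey."""
    return oi.simulate_survey(
        oi.transitional_fertility_preset(cohort_size=8000, seed=43).config
    )


@pytest.fixture(scope="session")
def regime_panel() -> pd.DataFrame:
    """Per-regime summary across the 12-step fertility ladder.

    One row per simulated regime: TFR, GFR, fitted power parameters
    (signed b) and the mean open interval.
    """
    rows = []
    for preset in oi.regime_ladder(n_regimes=12, cohort_size=4000, seed=7):
        records = oi.simulate_survey(preset.config)
        fit = oi.fit_power(oi.tabulate_distribution(records, preset.name))
        rows.append(
            {
                "regime": preset.name,
                "tfr": oi.compute_tfr(records),
                "gfr": oi.compute_gfr(records),
                "a": fit.params["a"],
                "b": -fit.params["b"],
                "mean_interval": oi.mean_open_interval(records),
                "ceb": oi.mean_ceb(records),
            }
        )
    return pd.DataFrame(rows)


def make_records(**columns) -> pd.DataFrame:
    """Hand-built woman records with schema defaults filled in."""
    n = max(len(v) for v in columns.values() if hasattr(v, "__len__"))
    base = {
        "woman_id": [f"t{i}" for i in range(n)],
        "interview_cmc": 1200,
        "age_years": 30,
        "parity": 1,
        "last_birth_cmc": 1190,
        "currently_pregnant": False,
        "currently_married": True,
    }
    base.update(columns)
    df = pd.DataFrame(base)
    df["last_birth_cmc"] = pd.array(
        [pd.NA if v is None or (isinstance(v, float) and np.isnan(v)) else int(v)
         for v in df["last_birth_cmc"]],
        dtype="Int64",
    )
    return df
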