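"""Period fertility measures from microdata with birth histories.

TFR and GFR are computed from births and woman-months of exposure in a
reference window before the interview (default 36 months, the usual
retrospective window for survey-based period rates):

* TFR — sum over the seven 5-year age groups 15–49 of the age-specific
  fertility rate (births to women in the group / woman-years lived in
  the group) times 5; the expected births per woman under current rates.
* GFR — 1,000 × births to women aged 15–44 at the birth per woman-year
  lived at ages 15–44.
* mean CEB — the arithmetic mean of parity over women 15–49.

All three use the full simulated population (married or not), the
conventional denominators; interval tabulation, by contrast, restricts
to married women.  A woman's own birth date is placed at the midpoint of
her reported age in years (CMC = interview − 12·age − 6), the standard
treatment when only completed age is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .survey_io import parse_birth_histories

N_AGE_GROUPS = 7


@dataclass
class FertilityMeasures:
    tfr: float
    gfr: float
    mean_ceb: float
    reference_window_months: int


def _own_birth_cmc(records: pd.DataFrame) -> np.ndarray:
    return (records["interview_cmc"] - 12 * records["age_years"] - 6).to_numpy()


def _window_tabulation(records: pd.DataFrame, window_months: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Births and exposure months per 5-year age group 15–49.

    The window is the ``window_months`` calendar months before the
    interview month (the interview month itself is incomplete and
    excluded).
    """
    if records.empty:
        raise EmptyInputError("no records")
    own_birth = _own_birth_cmc(records)
    interview = records["interview_cmc"].to_numpy()
    histories = parse_birth_histories(records)

    exposure_months = np.zeros(N_AGE_GROUPS)
    births = np.zeros(N_AGE_GROUPS)

    # Exposure: age in months at each month offset k = 1..window.
    offsets = np.arange(1, window_months + 1)
    age_m = (interview[:, None] - offsets[None, :]) - own_birth[:, None]
    group = (age_m // 12 - 15) // 5
    valid = (age_m >= 15 * 12) & (age_m < 50 * 12)
    exposure_months += np.bincount(
        group[valid].astype(int).ravel(), minlength=N_AGE_GROUPS
    )

    for i, history in enumerate(histories):
        if history.size == 0:
            continue
        in_window = (history >= interview[i] - window_months) & (
            history <= interview[i] - 1
        )
        ages = history[in_window] - own_birth[i]
        g = (ages // 12 - 15) // 5
        ok = (ages >= 15 * 12) & (ages < 50 * 12)
        births += np.bincount(g[ok].astype(int), minlength=N_AGE_GROUPS)
    return births, exposure_months


def compute_tfr(records: pd.DataFrame, window_months: int = 36) -> float:
    """Total fertility rate from birth histories over the window."""
    births, exposure = _window_tabulation(records, window_months)
    tfr = 0.0
    for g in range(N_AGE_GROUPS):
        if exposure[g] == 0:
            if births[g] > 0:
                warnings.warn(
                    f"age group {g}: births with zero exposure; contributing 0",
                    stacklevel=2,
                )
            continue
        tfr += births[g] / (exposure[g] / 12.0) * 5.0
    return tfr


def compute_gfr(records: pd.DataFrame, window_months: int = 36) -> float:
    """General fertility rate: births per 1,000 woman-years at ages 15–44."""
    births, exposure = _window_tabulation(records, window_months)
    woman_years = exposure[:6].sum() / 12.0
    if woman_years == 0:
        raise EmptyInputError("no exposure at ages 15-44")
    return 1000.0 * births[:6].sum() / woman_years


def mean_ceb(records: pd.DataFrame) -> float:
    """Mean children ever born (parity) over women aged 15–49."""
    sub = records[records["age_years"].between(15, 49)]
    if sub.empty:
        raise EmptyInputError("no women aged 15-49")
    return float(sub["parity"].mean())


def compute_fertility_measures(records: pd.DataFrame, window_months: int = 36
                               ) -> FertilityMeasures:
    return FertilityMeasures(
        tfr=compute_tfr(records, window_months),
        gfr=compute_gfr(records, window_months),
        mean_ceb=mean_ceb(records),
        reference_window_months=window_months,
    )
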