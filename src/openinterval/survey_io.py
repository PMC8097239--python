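"""Survey microdata CSV schema and packaged reference tables.

The microdata schema emulates the core DHS woman's-recode variables needed
for open-interval work (the native recode mapping is v008→interview_cmc,
b3→last_birth_cmc, v213→currently_pregnant, v012→age_years, v201→parity,
v502→currently_married).  Dates are century-month codes (CMC): months
elapsed since January 1900, so interval arithmetic is integer.

Two reference tables ship with the package:

* ``colombia_parity_by_age.csv`` — percent distribution of parity within
  five-year age groups for Colombia, six surveys 1990–2015, with printed
  row means.
* ``country_panel.csv`` — fitted power-model parameters (a, b), TFR, GFR
  and reported R² for the latest survey in 75 countries.

Both carry a provenance comment line and are checked against an embedded
sha256 on load.
"""

from __future__ import annotations

import hashlib
import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FixtureIntegrityError, RowValidationError, SchemaError

#: Required microdata columns, in canonical order.
SURVEY_COLUMNS = [
    "woman_id",
    "interview_cmc",
    "age_years",
    "parity",
    "last_birth_cmc",
    "currently_pregnant",
    "currently_married",
]

#: Optional extension carrying the full birth history as a
#: semicolon-separated list of CMC birth dates (empty for parity 0).
BIRTH_HISTORY_COLUMN = "birth_cmcs"

_FIXTURE_SHA256 = {
    "colombia_parity_by_age.csv": "283ef86d21e37c6fb9a913771593197f27a0d767668fa618b415f5662bf567d2",
    "country_panel.csv": "0d10ba0d0b1e6e3257d95637040ba34a0d4142a04ce10dfb28ac7366930ab70d",
}

PARITY_COLUMNS = ["p0", "p1", "p2", "p3", "p4", "p5", "p6plus"]


def _fixture_bytes(name: str) -> bytes:
    data = resources.files("openinterval.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    expected = _FIXTURE_SHA256[name]
    if digest != expected:
        raise FixtureIntegrityError(
            f"fixture {name} checksum mismatch: {digest} != {expected}"
        )
    return data


def _read_fixture(name: str) -> pd.DataFrame:
    import io as _io

    return pd.read_csv(_io.BytesIO(_fixture_bytes(name)), comment="#")


def survey_mid_year(label: str) -> float:
    """Mid-fieldwork year parsed from a survey label.

    ``"Colombia 2015"`` → 2015.0; ``"Benin 2017-18"`` → 2017.5;
    ``"Central African Republic 1994-95"`` → 1994.5.
    """
    m = re.search(r"(\d{4})(?:\s*-\s*(\d{2,4}))?\s*$", label)
    if not m:
        raise ValueError(f"no survey year found in label {label!r}")
    start = int(m.group(1))
    if m.group(2) is None:
        return float(start)
    return start + 0.5


def survey_country(label: str) -> str:
    """Country name portion of a survey label (the part before the year)."""
    m = re.search(r"\s*(\d{4})(?:\s*-\s*(\d{2,4}))?\s*$", label)
    if not m:
        return label.strip()
    return label[: m.start()].strip()


def load_country_panel(correct_b: bool = True) -> pd.DataFrame:
    """Load the 75-survey (a, b, TFR, GFR, R²) panel.

    Parenthesized b magnitudes in the source denote negative slopes; the
    fixture stores the printed magnitude and this loader applies the sign.
    Three rows (Benin 2017-18, Guinea 2018, Haiti 2016-17) print a b
    magnitude below 0.2 against a > 0.4, inconsistent with the rule that
    the slope magnitude is largest where the curve starts high; they are
    treated as decimal-shift misprints and multiplied by 10 before
    negation, flagged ``b_corrected``.  Pass ``correct_b=False`` to keep
    the printed magnitudes.

    Returns a DataFrame with columns ``survey_label, country, mid_year,
    a, b, tfr, gfr, r2, b_corrected`` where ``b`` is signed (negative).
    """
    df = _read_fixture("country_panel.csv")
    if len(df) != 75:
        raise FixtureIntegrityError(f"country panel has {len(df)} rows, expected 75")
    misprint = (df["b_printed"] < 0.2) & (df["a"] > 0.4)
    magnitude = df["b_printed"].where(~(misprint & correct_b), df["b_printed"] * 10)
    out = pd.DataFrame(
        {
            "survey_label": df["survey_label"],
            "country": df["survey_label"].map(survey_country),
            "mid_year": df["survey_label"].map(survey_mid_year),
            "a": df["a"],
            "b": -magnitude,
            "tfr": df["tfr"],
            "gfr": df["gfr"],
            "r2": df["r2"],
            "b_corrected": misprint & correct_b,
        }
    )
    bad = out[(out["a"] <= 0) | (out["b"] >= 0) | (out["r2"] <= 0) | (out["r2"] > 1)]
    if len(bad):
        raise FixtureIntegrityError(f"panel rows violate invariants: {bad.survey_label.tolist()}")
    return out


def load_colombia_parity_table(tolerance: float = 0.3) -> pd.DataFrame:
    """Load the Colombia parity-within-age-group table (42 rows).

    Each row holds the percent distribution over parities 0–5 and 6+ for
    one (age group, survey year) cell, plus the printed mean parity.  Row
    percentages must sum to 100 within ``tolerance`` (printed rounding).
    """
    df = _read_fixture("colombia_parity_by_age.csv")
    if len(df) != 42:
        raise FixtureIntegrityError(f"parity table has {len(df)} rows, expected 42")
    sums = df[PARITY_COLUMNS].sum(axis=1)
    off = (sums - 100).abs() > tolerance
    if off.any():
        rows = df.loc[off, ["age_group", "year"]].itertuples(index=False)
        raise FixtureIntegrityError(
            "row percentages do not sum to 100: "
            + ", ".join(f"({r.age_group}, {r.year})" for r in rows)
        )
    return df


# ---------------------------------------------------------------------------
# Microdata reading and writing


def write_survey_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write woman records to the canonical CSV schema (empty = missing)."""
    cols = list(SURVEY_COLUMNS)
    if BIRTH_HISTORY_COLUMN in records.columns:
        cols.append(BIRTH_HISTORY_COLUMN)
    missing = [c for c in SURVEY_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"records are missing columns: {missing}")
    out = records[cols].copy()
    out["currently_pregnant"] = out["currently_pregnant"].astype(bool)
    out["currently_married"] = out["currently_married"].astype(bool)
    out.to_csv(path, index=False)


def _coerce_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    return series.astype(str).str.strip().str.lower().map(mapping)


def read_survey_csv(
    path: str | Path, strict: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate survey microdata.

    Returns ``(records, rejections)``.  Rows violating a record invariant
    are dropped and listed once each in ``rejections`` with a reason
    (``strict=True`` raises on the first violation instead).  Enforced
    invariants:

    * ``last_birth_cmc`` present iff ``parity >= 1``;
    * ``last_birth_cmc <= interview_cmc``;
    * ``age_years`` within 15–49 and consistent with a plausible birth
      cohort (a woman aged a at interview was born after CMC 0).
    """
    df = pd.read_csv(path, dtype={"woman_id": str})
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    df["currently_pregnant"] = _coerce_bool(df["currently_pregnant"])
    df["currently_married"] = _coerce_bool(df["currently_married"])
    df["last_birth_cmc"] = pd.to_numeric(df["last_birth_cmc"], errors="coerce")

    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        mask = mask & (reasons == "")
        reasons[mask] = reason

    flag(df["currently_pregnant"].isna() | df["currently_married"].isna(),
         "unparseable boolean flag")
    flag((df["parity"] > 0) & df["last_birth_cmc"].isna(),
         "parity>0 without last birth")
    flag((df["parity"] == 0) & df["last_birth_cmc"].notna(),
         "parity=0 with last birth date")
    flag(df["last_birth_cmc"] > df["interview_cmc"], "last birth after interview")
    flag((df["age_years"] < 15) | (df["age_years"] > 49), "age outside 15-49")
    flag(df["interview_cmc"] - 12 * df["age_years"] < 0,
         "age inconsistent with birth cohort")

    bad = reasons != ""
    if strict and bad.any():
        first = df.index[bad][0]
        raise RowValidationError(
            f"{path}: row {first} (woman_id={df.loc[first, 'woman_id']}): "
            f"{reasons[first]}"
        )
    rejections = pd.DataFrame(
        {"woman_id": df.loc[bad, "woman_id"], "reason": reasons[bad]}
    ).reset_index(drop=True)
    records = df[~bad].reset_index(drop=True)
    records["last_birth_cmc"] = records["last_birth_cmc"].astype("Int64")
    records["parity"] = records["parity"].astype(int)
    records["currently_pregnant"] = records["currently_pregnant"].astype(bool)
    records["currently_married"] = records["currently_married"].astype(bool)
    return records, rejections


def parse_birth_histories(records: pd.DataFrame) -> list[np.ndarray]:
    """Decode the ``birth_cmcs`` column into one CMC array per woman."""
    if BIRTH_HISTORY_COLUMN not in records.columns:
        raise SchemaError(f"records lack the {BIRTH_HISTORY_COLUMN!r} column")
    out = []
    for value in records[BIRTH_HISTORY_COLUMN].fillna(""):
        value = str(value).strip()
        if not value:
            out.append(np.empty(0, dtype=np.int64))
        else:
            out.append(np.array([int(float(v)) for v in value.split(";")]))
    return out
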