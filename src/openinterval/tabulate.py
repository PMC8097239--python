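"""Open-interval tabulation and age/parity decompositions.

The open birth interval is the time since a woman's most recent live
birth, observed at interview.  Distributions are tabulated over interval
years 1–20, where year k covers months [12(k−1), 12k) since the last
birth.  Eligibility follows the standard survey convention: currently
married women aged 15–49 who are either mothers (parity ≥ 1) or currently
pregnant.  Pregnant women are assigned to the first interval year
regardless of the date of their last birth, being close to a birth and
similar in composition to the first-year group.  Women 20 or more years
past their last birth are excluded and percentages renormalized over the
20 bins, so every distribution sums to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError

N_INTERVALS = 20

AGE_GROUPS = ["15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49"]
PARITY_CATEGORIES = ["1", "2", "3", "4", "5", "6+"]

#: Enumerable exclusion reasons; a record maps to exactly one bin or reason.
EXCLUSION_REASONS = ("not_married", "age_out_of_range", "nulliparous_not_pregnant",
                     "interval_20plus_years")


def age_group_label(age_years: int) -> str | None:
    """Five-year age-group label for ages 15–49, else None."""
    if 15 <= age_years <= 49:
        return AGE_GROUPS[(int(age_years) - 15) // 5]
    return None


@dataclass
class OpenIntervalDistribution:
    """Counts and percentages of eligible women by interval year 1–20."""

    label: str
    counts: np.ndarray
    exclusions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_INTERVALS,):
            raise DomainError(f"expected {N_INTERVALS} bins, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise DomainError("negative bin count")

    @property
    def n_eligible(self) -> int:
        return int(self.counts.sum())

    @property
    def percentages(self) -> np.ndarray:
        return 100.0 * self.counts / self.n_eligible

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n_eligible

    @property
    def interval_years(self) -> np.ndarray:
        return np.arange(1, N_INTERVALS + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.label,
                "interval_year": self.interval_years,
                "count": self.counts,
                "percentage": self.percentages,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str | None = None
                   ) -> "OpenIntervalDistribution":
        df = df.sort_values("interval_year")
        if not np.array_equal(df["interval_year"].to_numpy(),
                              np.arange(1, N_INTERVALS + 1)):
            raise DomainError("frame must contain interval years 1..20 exactly")
        if label is None:
            label = str(df["label"].iloc[0]) if "label" in df else ""
        return cls(label, df["count"].to_numpy())


@dataclass
class IntervalComposition:
    """Category shares (percent) and axis means within each interval year.

    ``shares`` is indexed by category with one column per interval year;
    empty intervals are flagged in ``empty_intervals`` and carry NaN
    shares rather than propagating through downstream arithmetic.
    """

    axis: str
    shares: pd.DataFrame
    means: np.ndarray
    n_per_interval: np.ndarray
    empty_intervals: list[int]
    notes: list[str] = field(default_factory=list)


@dataclass
class AgeParityTable:
    """Percent distribution of parity (0–5, 6+) within age groups."""

    table: pd.DataFrame          # rows: AGE_GROUPS; cols: p0..p6plus
    row_means: pd.Series         # mean parity from true (un-topcoded) parity
    row_counts: pd.Series
    empty_rows: list[str] = field(default_factory=list)


def _interval_years(records: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Vectorized bin assignment.

    Returns ``(years, reasons)``: years in 1..20 (NaN where excluded) and
    the exclusion reason (empty string where eligible).
    """
    age = records["age_years"]
    reasons = pd.Series("", index=records.index, dtype=object)
    eligible = pd.Series(True, index=records.index)

    def exclude(mask, reason):
        nonlocal eligible
        mask = mask & eligible
        reasons[mask] = reason
        eligible &= ~mask

    exclude(~records["currently_married"].astype(bool), "not_married")
    exclude((age < 15) | (age > 49), "age_out_of_range")
    pregnant = records["currently_pregnant"].astype(bool)
    exclude((records["parity"] == 0) & ~pregnant, "nulliparous_not_pregnant")

    months = records["interview_cmc"] - records["last_birth_cmc"]
    if ((months < 0) & eligible & ~pregnant).any():
        raise DomainError("negative months since last birth")
    exclude(~pregnant & (months >= 12 * N_INTERVALS), "interval_20plus_years")

    years = pd.Series(np.nan, index=records.index)
    years[eligible & pregnant] = 1
    rest = eligible & ~pregnant
    years[rest] = months[rest] // 12 + 1
    return years, reasons


def open_interval_year(record) -> int | None:
    """Interval year 1–20 for one woman record, or None if excluded.

    ``record`` is any mapping (dict, Series, namedtuple) with the survey
    schema fields.  Pregnant women map to year 1 regardless of parity;
    non-pregnant mothers map months since last birth m to ⌊m/12⌋+1, with
    m ≥ 240 excluded; unmarried women, ages outside 15–49, and
    non-pregnant nulliparae are excluded.
    """
    if hasattr(record, "_asdict"):
        record = record._asdict()
    df = pd.DataFrame([dict(record)])
    years, _ = _interval_years(df)
    y = years.iloc[0]
    return None if np.isnan(y) else int(y)


def tabulate_distribution(records: pd.DataFrame, label: str = "") -> OpenIntervalDistribution:
    """Tabulate the open-interval distribution of a survey."""
    years, reasons = _interval_years(records)
    eligible = years.notna()
    if not eligible.any():
        raise EmptyInputError("no eligible records to tabulate")
    counts = np.bincount(years[eligible].astype(int) - 1, minlength=N_INTERVALS)
    exclusions = reasons[reasons != ""].value_counts().to_dict()
    return OpenIntervalDistribution(label, counts, exclusions)


def composition_by_interval(records: pd.DataFrame, axis: str) -> IntervalComposition:
    """Decompose each interval year by age group or by parity.

    Age axis: shares of the seven 5-year age groups within each interval,
    and the mean age (years) per interval.  Parity axis: shares of
    parities 1–5 and 6+ (top-coded for display), and the mean of true
    parity per interval; pregnant nulliparae belong to no displayed
    parity category and are counted in a note instead.
    """
    if axis not in ("age", "parity"):
        raise DomainError(f"axis must be 'age' or 'parity', got {axis!r}")
    years, _ = _interval_years(records)
    eligible = years.notna()
    if not eligible.any():
        raise EmptyInputError("no eligible records")
    sub = records[eligible].copy()
    sub["interval_year"] = years[eligible].astype(int)

    notes: list[str] = []
    if axis == "age":
        sub["category"] = sub["age_years"].astype(int).map(age_group_label)
        categories = AGE_GROUPS
        value = sub["age_years"].astype(float)
    else:
        parity = sub["parity"].astype(int)
        sub["category"] = np.where(parity >= 6, "6+", parity.astype(str))
        categories = PARITY_CATEGORIES
        n_p0 = int((parity == 0).sum())
        if n_p0:
            notes.append(f"{n_p0} pregnant nulliparae excluded from parity shares")
        value = parity.astype(float)

    shown = sub[sub["category"].isin(categories)]
    tab = pd.crosstab(shown["category"], shown["interval_year"])
    tab = tab.reindex(index=categories, columns=range(1, N_INTERVALS + 1),
                      fill_value=0)
    n_per = tab.sum(axis=0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = 100.0 * tab / tab.sum(axis=0)
    empty = [int(k) for k in range(1, N_INTERVALS + 1) if n_per[k - 1] == 0]
    shares.loc[:, empty] = np.nan

    means = np.full(N_INTERVALS, np.nan)
    grouped = value.groupby(sub["interval_year"]).mean()
    means[grouped.index.to_numpy() - 1] = grouped.to_numpy()
    return IntervalComposition(axis, shares, means, n_per, empty, notes)


def age_parity_table(records: pd.DataFrame) -> AgeParityTable:
    """Parity distribution (0–5, 6+) within age groups, with true means.

    Unlike interval tabulation this includes parity-0 women; eligibility
    is currently married and aged 15–49.
    """
    sub = records[
        records["currently_married"].astype(bool)
        & records["age_years"].between(15, 49)
    ].copy()
    if sub.empty:
        raise EmptyInputError("no married women aged 15-49")
    parity = sub["parity"].astype(int)
    sub["age_group"] = sub["age_years"].astype(int).map(age_group_label)
    sub["pcat"] = np.where(parity >= 6, "p6plus", "p" + parity.astype(str))

    tab = pd.crosstab(sub["age_group"], sub["pcat"])
    cols = ["p0", "p1", "p2", "p3", "p4", "p5", "p6plus"]
    tab = tab.reindex(index=AGE_GROUPS, columns=cols, fill_value=0)
    counts = tab.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * tab.div(counts, axis=0)
    means = parity.groupby(sub["age_group"]).mean().reindex(AGE_GROUPS)
    empty = [g for g in AGE_GROUPS if counts[g] == 0]
    return AgeParityTable(pct, means, counts, empty)


def mean_parity_from_printed_row(percentages) -> float:
    """Mean parity implied by a printed 7-cell percent row (0–5, 6+).

    The open-ended 6+ column is coded at parity 6, so the result is a
    lower bound on the true mean wherever that cell is non-zero; rows
    with an empty 6+ cell reconstruct the printed mean exactly.  Rounded
    to 2 decimals for comparison with printed values.
    """
    p = np.asarray(percentages, dtype=float)
    if p.shape != (7,):
        raise DomainError(f"expected 7 percentages, got shape {p.shape}")
    if (p < 0).any():
        raise DomainError("negative percentage")
    if abs(p.sum() - 100) > 0.5:
        raise DomainError(f"percentages sum to {p.sum():.2f}, expected 100 ± 0.5")
    return round(float(np.dot(np.arange(7), p)) / 100.0, 2)


def mean_open_interval(dist_or_records) -> float:
    """Mean open interval in years.

    From microdata: the mean of exact months/12 over eligible women, with
    pregnant women contributing 0.5 years (the midpoint of the first-year
    bin they are assigned to).  From a binned distribution: the mean of
    bin midpoints, Σ (k − 0.5)·pₖ/100.
    """
    if isinstance(dist_or_records, OpenIntervalDistribution):
        d = dist_or_records
        midpoints = d.interval_years - 0.5
        return float(np.dot(midpoints, d.proportions))
    records = dist_or_records
    years, _ = _interval_years(records)
    eligible = years.notna()
    if not eligible.any():
        raise EmptyInputError("no eligible records")
    sub = records[eligible]
    pregnant = sub["currently_pregnant"].astype(bool)
    exact = (sub["interview_cmc"] - sub["last_birth_cmc"]) / 12.0
    contrib = exact.where(~pregnant, 0.5)
    return float(contrib.mean())
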