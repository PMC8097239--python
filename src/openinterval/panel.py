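"""Cross-survey panel analyses.

Correlates fitted power-model parameters with fertility measures across
surveys, relates fertility to the mean open interval, and measures
within-country time trends across repeat surveys.  Signed Pearson r is
reported alongside r² throughout, matching the convention of printed
tables that label signed correlations "R²".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation; returns (signed r, r²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UndefinedCorrelationError("series must be 1-d and equal length")
    if len(x) < 3:
        raise UndefinedCorrelationError(f"need >= 3 points, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant series")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


@dataclass
class AssociationSummary:
    """Named correlation pairs plus analysis notes."""

    pairs: list[tuple] = field(default_factory=list)  # (x, y, r, r², n)
    notes: list[str] = field(default_factory=list)

    def add(self, x_name: str, y_name: str, x, y) -> None:
        r, r2 = pearson(x, y)
        self.pairs.append((x_name, y_name, r, r2, len(x)))

    def get(self, x_name: str, y_name: str) -> tuple[float, float]:
        for xn, yn, r, r2, _ in self.pairs:
            if {xn, yn} == {x_name, y_name}:
                return r, r2
        raise KeyError(f"no pair ({x_name}, {y_name})")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.pairs, columns=["x", "y", "pearson_r", "r_squared", "n"]
        )
        return df


@dataclass
class TrendResult:
    """Within-country time-trend slopes across repeat surveys."""

    country: str
    first_interval_slope: float       # percentage points per calendar year
    dtfr_dinterval_slope: float       # TFR change per year of mean interval
    n_surveys: int


def panel_correlations(panel: pd.DataFrame) -> AssociationSummary:
    """Correlations among (a, b) and fertility rates over a cleaned panel.

    Expects columns ``a`` (positive level), ``b`` (signed, negative),
    ``tfr`` and ``gfr``; computes the five pairs (a,b), (a,TFR), (b,TFR),
    (a,GFR), (b,GFR).  With descending interval curves the a-correlations
    with fertility are positive and the b-correlations negative.
    """
    out = AssociationSummary()
    out.add("a", "b", panel["a"], panel["b"])
    for rate in ("tfr", "gfr"):
        out.add("a", rate, panel["a"], panel[rate])
        out.add("b", rate, panel["b"], panel[rate])
    if "b_corrected" in panel.columns and panel["b_corrected"].any():
        labels = panel.loc[panel["b_corrected"], "survey_label"].tolist()
        out.notes.append(f"decimal-shift b correction applied to: {labels}")
    return out


def fertility_vs_interval(panel: pd.DataFrame) -> AssociationSummary:
    """Correlate TFR/GFR/CEB with the mean open interval across surveys.

    ``panel`` needs a ``mean_interval`` column (years) and whichever of
    ``tfr``, ``gfr``, ``ceb`` are available; absent or empty measures are
    skipped with a note.  The relationship is curvilinear — the slope
    flattens at long intervals as fertility nears replacement — so a
    quadratic-in-interval term is tested and its significance noted.
    """
    out = AssociationSummary()
    x = panel["mean_interval"]
    for rate in ("tfr", "gfr", "ceb"):
        if rate not in panel.columns or panel[rate].dropna().empty:
            out.notes.append(f"{rate} unavailable; pair skipped")
            continue
        sub = panel[[rate, "mean_interval"]].dropna()
        out.add("mean_interval", rate, sub["mean_interval"], sub[rate])
    if "tfr" in panel.columns and panel["tfr"].notna().sum() >= 4:
        import statsmodels.api as sm

        sub = panel[["tfr", "mean_interval"]].dropna()
        X = sm.add_constant(
            np.column_stack([sub["mean_interval"], sub["mean_interval"] ** 2])
        )
        fit = sm.OLS(sub["tfr"], X).fit()
        p_quad = float(fit.pvalues.iloc[-1])
        shape = "significant" if p_quad < 0.05 else "not significant"
        out.notes.append(
            f"quadratic mean-interval term p={p_quad:.3g} ({shape}): "
            "curvilinearity check for the TFR relation"
        )
    return out


def _slope(x, y) -> float:
    return float(np.polyfit(np.asarray(x, float), np.asarray(y, float), 1)[0])


def repeat_survey_trends(surveys: pd.DataFrame,
                         first_vs_last: bool = False,
                         ) -> tuple[list[TrendResult], dict, list[str]]:
    """Per-country trend slopes across repeat surveys.

    ``surveys`` needs columns ``country, mid_year, first_interval_pct,
    tfr, mean_interval``; countries with a single survey are excluded
    with a note.  ``first_interval_slope`` regresses the first-interval
    percentage on survey mid-year; ``dtfr_dinterval_slope`` regresses TFR
    on the mean open interval across the country's surveys (all surveys
    in one least-squares fit, or endpoints only if ``first_vs_last``).
    Returns (results, summary, notes) where summary counts negative
    ΔTFR/Δinterval slopes and gives their median and mean.
    """
    results: list[TrendResult] = []
    notes: list[str] = []
    for country, grp in surveys.groupby("country", sort=True):
        if len(grp) < 2:
            notes.append(f"{country}: single survey, excluded from trends")
            continue
        grp = grp.sort_values("mid_year")
        if first_vs_last:
            grp = grp.iloc[[0, -1]]
        fi_slope = _slope(grp["mid_year"], grp["first_interval_pct"])
        if np.ptp(grp["mean_interval"].to_numpy()) == 0:
            dtfr = 0.0
            notes.append(f"{country}: mean interval constant; slope set to 0")
        else:
            dtfr = _slope(grp["mean_interval"], grp["tfr"])
        results.append(TrendResult(country, fi_slope, dtfr, len(grp)))
    slopes = np.array([r.dtfr_dinterval_slope for r in results])
    summary = {
        "n_countries": len(results),
        "n_negative_dtfr_slopes": int((slopes < 0).sum()) if len(slopes) else 0,
        "median_dtfr_slope": float(np.median(slopes)) if len(slopes) else np.nan,
        "mean_dtfr_slope": float(np.mean(slopes)) if len(slopes) else np.nan,
    }
    return results, summary, notes
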