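"""Curve models for the open-interval distribution.

The central model is the two-parameter power curve

    y(x) = a · x^(−b),   x = interval year 1..20,

with y the proportion of women in interval year x: ``a`` is the level of
the curve at x = 1 (the share pregnant or within a year of a birth) and
``b`` the magnitude of the downward slope; both rise with fertility.
Three comparators are fitted on the same 20 bins: exponential
y = a·e^(cx), logarithmic y = c + d·ln x, and a degree-2 polynomial.

Parameters are estimated by ordinary least squares after the standard
linearizing transforms (log–log for the power curve, semi-log for the
exponential), the spreadsheet-trendline convention.  Zero bins are
dropped from log fits and counted in a diagnostics field.  To keep the
families comparable, every fit reports R² on the original proportion
scale (1 − SS_res/SS_tot over all 20 bins) alongside the R² of the
fitting space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError
from .tabulate import N_INTERVALS, OpenIntervalDistribution

FAMILIES = ("power", "exponential", "logarithmic", "polynomial")

_N_PARAMS = {"power": 2, "exponential": 2, "logarithmic": 2, "polynomial": 3}


@dataclass
class CurveFit:
    """One fitted family: parameters, predictions and fit statistics."""

    family: str
    params: dict
    fitted: np.ndarray
    r2_original: float
    r2_transformed: float
    n_dropped_zero_bins: int = 0

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.family]

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "power":
            return p["a"] * x ** (-p["b"])
        if self.family == "exponential":
            return p["a"] * np.exp(p["c"] * x)
        if self.family == "logarithmic":
            return p["c"] + p["d"] * np.log(x)
        return p["c0"] + p["c1"] * x + p["c2"] * x**2


def _proportions(dist) -> np.ndarray:
    """Bin values to fit: proportions for a distribution object; raw
    arrays are taken on whatever scale they come in (percent input gives
    a level 100× the proportion-scale level, slopes are scale-free)."""
    if isinstance(dist, OpenIntervalDistribution):
        return dist.proportions
    y = np.asarray(dist, dtype=float)
    if y.shape != (N_INTERVALS,):
        raise InsufficientDataError(f"expected {N_INTERVALS} bins, got {y.shape}")
    if (y < 0).any():
        raise InsufficientDataError("negative bin values")
    return y


def _r_squared(y, fitted) -> float:
    y = np.asarray(y, dtype=float)
    resid = y - np.asarray(fitted, dtype=float)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot < 1e-30:
        # degenerate flat input: a perfect constant fit scores 1
        return 1.0 if ss_res < 1e-30 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_power(dist) -> CurveFit:
    """Fit y = a·x^(−b) by least squares on (ln x, ln y).

    ``a`` is in proportion units (multiply by 100 for percent);
    ``b`` is stored as a positive magnitude for a descending curve.
    """
    y = _proportions(dist)
    x = np.arange(1, N_INTERVALS + 1, dtype=float)
    pos = y > 0
    if pos.sum() < 3:
        raise InsufficientDataError("power fit needs >= 3 positive bins")
    slope, intercept = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
    a, b = float(np.exp(intercept)), float(-slope)
    fitted = a * x ** (-b)
    return CurveFit(
        "power",
        {"a": a, "b": b},
        fitted,
        _r_squared(y, fitted),
        _r_squared(np.log(y[pos]), np.log(fitted[pos])),
        int((~pos).sum()),
    )


def fit_exponential(dist) -> CurveFit:
    """Fit y = a·e^(cx) by least squares on (x, ln y)."""
    y = _proportions(dist)
    x = np.arange(1, N_INTERVALS + 1, dtype=float)
    pos = y > 0
    if pos.sum() < 3:
        raise InsufficientDataError("exponential fit needs >= 3 positive bins")
    c, loga = np.polyfit(x[pos], np.log(y[pos]), 1)
    a = float(np.exp(loga))
    fitted = a * np.exp(c * x)
    return CurveFit(
        "exponential",
        {"a": a, "c": float(c)},
        fitted,
        _r_squared(y, fitted),
        _r_squared(np.log(y[pos]), np.log(fitted[pos])),
        int((~pos).sum()),
    )


def fit_logarithmic(dist) -> CurveFit:
    """Fit y = c + d·ln x by ordinary least squares (no transform of y)."""
    y = _proportions(dist)
    x = np.arange(1, N_INTERVALS + 1, dtype=float)
    d, c = np.polyfit(np.log(x), y, 1)
    fitted = c + d * np.log(x)
    r2 = _r_squared(y, fitted)
    return CurveFit("logarithmic", {"c": float(c), "d": float(d)}, fitted, r2, r2)


def fit_polynomial(dist) -> CurveFit:
    """Fit y = c0 + c1·x + c2·x² by ordinary least squares."""
    y = _proportions(dist)
    x = np.arange(1, N_INTERVALS + 1, dtype=float)
    if len(y) < 4:
        raise InsufficientDataError("polynomial fit needs >= 4 bins")
    c2, c1, c0 = np.polyfit(x, y, 2)
    fitted = c0 + c1 * x + c2 * x**2
    r2 = _r_squared(y, fitted)
    return CurveFit(
        "polynomial", {"c0": float(c0), "c1": float(c1), "c2": float(c2)},
        fitted, r2, r2,
    )


_FITTERS = {
    "power": fit_power,
    "exponential": fit_exponential,
    "logarithmic": fit_logarithmic,
    "polynomial": fit_polynomial,
}


@dataclass
class ModelComparison:
    """All families fitted to one distribution, ranked by original-scale R²."""

    fits: list[CurveFit]
    errors: dict = field(default_factory=dict)

    @property
    def best(self) -> CurveFit:
        return self.fits[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "family": f.family,
                    "r2_original": f.r2_original,
                    "r2_transformed": f.r2_transformed,
                    "n_params": f.n_params,
                    **{f"param_{k}": v for k, v in f.params.items()},
                }
                for i, f in enumerate(self.fits)
            ]
        )


def compare_models(dist, families=FAMILIES) -> ModelComparison:
    """Fit the requested families and rank by R² on the proportion scale.

    Ties are broken in favour of fewer parameters.  A family whose fit
    raises is recorded in ``errors`` and the comparison continues.
    """
    fits, errors = [], {}
    for family in families:
        try:
            fits.append(_FITTERS[family](dist))
        except Exception as exc:  # noqa: BLE001 - propagate per-family, continue
            errors[family] = str(exc)
    if not fits:
        raise InsufficientDataError("no family could be fitted")
    fits.sort(key=lambda f: (-round(f.r2_original, 12), f.n_params, f.family))
    return ModelComparison(fits, errors)
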