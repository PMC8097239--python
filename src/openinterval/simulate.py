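"""Reproductive-history microsimulation and direct samplers.

``simulate_survey`` steps a synthetic cohort of women month by month
through marriage, conception, gestation, postpartum infecundability,
contraception and sterility onset, then takes a single cross-sectional
census, emitting survey-style records (one per woman) with full birth
histories.  Because each woman's entire reproductive life is simulated
under fixed rates before the census, the sampled population is in the
stable state the renewal relations assume: the census date is
exchangeable with any other under the same rates.

Mechanics, per month of age while alive in the model (ages 15–49):

* a woman is exposed when married, not pregnant, not postpartum
  infecund, and not yet sterile;
* conception is Bernoulli at ``monthly_fecundability`` × an age-profile
  multiplier × (1 − effectiveness·using) × (1 − spousal-absence factor);
* ``using`` contraception means she has reached her desired parity and
  belongs to the using fraction (``contraceptive_prevalence``); imperfect
  effectiveness generates unplanned births, the source of the long
  right tail of parity distributions under low desired family size;
* a birth follows ``gestation_months`` after conception, then
  ``postpartum_infecundable_months`` of infecundability (lactational
  amenorrhea);
* sterility onset is drawn from a piecewise-constant per-month hazard by
  5-year age group and is absorbing.

Ages at the census follow a stable-population density proportional to
exp(−r·age) with growth rate ``annual_growth_rate``; this reproduces the
thinning of older cohorts that shapes the tail of the open-interval
curve.  Women never married by the census are emitted with
``currently_married = False`` so both the married tabulation universe
and the all-women fertility-rate universe can be formed.

Randomness: one master seed; per-woman streams are spawned by counter
(NumPy ``SeedSequence.spawn``), so enlarging ``cohort_size`` extends the
cohort without reshuffling earlier women.

Two direct samplers support fit-recovery and renewal experiments:
``sample_power_law_survey`` (multinomial draws from a power-law
20-bin distribution) and ``sample_stationary_renewal`` (backward and
forward recurrence times of a renewal process at stationary inspection
times).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .tabulate import N_INTERVALS, OpenIntervalDistribution

AGE_MIN_YEARS = 15
AGE_MAX_YEARS = 49
_A0 = AGE_MIN_YEARS * 12          # age grid start, months
_A1 = (AGE_MAX_YEARS + 1) * 12    # age grid end (exclusive)
_N_MONTHS = _A1 - _A0

#: Default per-month sterility-onset hazard by 5-year age group 15-19..45-49.
#: Calibrated so secondary sterility is rare before 30 and common by the
#: late forties; early onsets are one source of very long open intervals.
DEFAULT_STERILITY_HAZARD = (1e-4, 2e-4, 5e-4, 1.5e-3, 4e-3, 1.2e-2, 3e-2)

#: Default fecundability multiplier by 5-year age group (adolescent
#: subfecundity and the decline after the mid-thirties).
DEFAULT_FECUNDABILITY_PROFILE = (0.70, 1.00, 1.00, 0.90, 0.75, 0.50, 0.25)

MARRIAGE_AGES = np.arange(15, 36)          # support of marriage_age_distribution
DESIRED_PARITIES = np.arange(0, 13)        # support of desired_parity_distribution


def _discretized_normal(support: np.ndarray, mean: float, sd: float) -> np.ndarray:
    w = np.exp(-0.5 * ((support - mean) / sd) ** 2)
    return w / w.sum()


@dataclass
class SimulationConfig:
    """All knobs of the monthly-step reproductive microsimulation."""

    monthly_fecundability: float
    postpartum_infecundable_months: int
    contraceptive_prevalence: float
    contraceptive_effectiveness: float
    desired_parity_distribution: np.ndarray
    marriage_age_distribution: np.ndarray
    cohort_size: int
    seed: int = 0
    gestation_months: int = 9
    sterility_onset_hazard: tuple = DEFAULT_STERILITY_HAZARD
    fecundability_age_profile: tuple = DEFAULT_FECUNDABILITY_PROFILE
    annual_growth_rate: float = 0.02
    spousal_absence_factor: float = 0.0
    #: coefficient of variation of a per-woman multiplier on fecundability
    #: (gamma-distributed with mean 1); between-couple heterogeneity in
    #: conception risk is what fattens the long-interval tail.
    fecundability_cv: float = 0.6
    survey_age_range: tuple = (AGE_MIN_YEARS, AGE_MAX_YEARS)
    survey_cmc: int = 1416  # December 2017

    def __post_init__(self) -> None:
        self.desired_parity_distribution = np.asarray(
            self.desired_parity_distribution, dtype=float
        )
        self.marriage_age_distribution = np.asarray(
            self.marriage_age_distribution, dtype=float
        )
        self.validate()

    def validate(self) -> None:
        def check_prob(name):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")

        if not 0 <= self.monthly_fecundability <= 1:
            raise ConfigurationError(
                f"monthly_fecundability must be in [0, 1], got {self.monthly_fecundability}"
            )
        for name in ("contraceptive_prevalence", "contraceptive_effectiveness",
                     "spousal_absence_factor"):
            check_prob(name)
        for name, support in (
            ("desired_parity_distribution", DESIRED_PARITIES),
            ("marriage_age_distribution", MARRIAGE_AGES),
        ):
            v = getattr(self, name)
            if len(v) != len(support):
                raise ConfigurationError(
                    f"{name} must have length {len(support)}, got {len(v)}"
                )
            if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must be a probability vector")
        if self.cohort_size < 1:
            raise ConfigurationError(f"cohort_size must be >= 1, got {self.cohort_size}")
        if self.postpartum_infecundable_months < 0:
            raise ConfigurationError("postpartum_infecundable_months must be >= 0")
        if self.gestation_months < 1:
            raise ConfigurationError("gestation_months must be >= 1")
        if len(self.sterility_onset_hazard) != 7 or any(
            h < 0 for h in self.sterility_onset_hazard
        ):
            raise ConfigurationError(
                "sterility_onset_hazard needs 7 nonnegative per-month hazards"
            )
        if len(self.fecundability_age_profile) != 7 or any(
            not 0 <= m <= 1 for m in self.fecundability_age_profile
        ):
            raise ConfigurationError(
                "fecundability_age_profile needs 7 multipliers in [0, 1]"
            )
        if self.annual_growth_rate < 0:
            raise ConfigurationError("annual_growth_rate must be >= 0")
        if self.fecundability_cv < 0:
            raise ConfigurationError("fecundability_cv must be >= 0")


@dataclass
class RegimePreset:
    """A named fertility regime: a label plus a full configuration."""

    name: str
    config: SimulationConfig


def _make_config(fecundability, ppi, prevalence, effectiveness, desired_mean,
                 desired_sd, marriage_mean, marriage_sd, growth, cohort_size,
                 seed, cv=0.6) -> SimulationConfig:
    return SimulationConfig(
        monthly_fecundability=fecundability,
        postpartum_infecundable_months=ppi,
        contraceptive_prevalence=prevalence,
        contraceptive_effectiveness=effectiveness,
        desired_parity_distribution=_discretized_normal(
            DESIRED_PARITIES, desired_mean, desired_sd
        ),
        marriage_age_distribution=_discretized_normal(
            MARRIAGE_AGES, marriage_mean, marriage_sd
        ),
        annual_growth_rate=growth,
        fecundability_cv=cv,
        cohort_size=cohort_size,
        seed=seed,
    )


def high_fertility_preset(cohort_size: int = 20_000, seed: int = 0) -> RegimePreset:
    """Niger-like natural-fertility regime: early near-universal marriage,
    long lactational infecundability, large desired families, little
    contraception, fast population growth, wide between-couple variation
    in conception risk (TFR around 7)."""
    return RegimePreset(
        "high_fertility",
        _make_config(0.09, 13, 0.22, 0.92, 8.5, 2.0, 17.0, 2.0, 0.03,
                     cohort_size, seed, cv=0.9),
    )


def transitional_fertility_preset(cohort_size: int = 20_000, seed: int = 0
                                  ) -> RegimePreset:
    """Colombia-like transitional regime: later marriage, short
    breastfeeding, a two-child norm enforced by high-prevalence,
    high-effectiveness contraception (TFR around 2)."""
    return RegimePreset(
        "transitional_fertility",
        _make_config(0.115, 6, 0.95, 0.995, 1.8, 1.2, 24.0, 3.0, 0.008,
                     cohort_size, seed, cv=0.6),
    )


PRESETS = {
    "niger": high_fertility_preset,
    "colombia": transitional_fertility_preset,
}


def regime_ladder(n_regimes: int = 12, cohort_size: int = 4000, seed: int = 0
                  ) -> list[RegimePreset]:
    """A ladder of regimes interpolating the transitional → high presets.

    Used for cross-regime panels: fertility rises monotonically along the
    ladder through joint movement of desired family size, contraceptive
    prevalence and effectiveness, breastfeeding duration, marriage age,
    growth rate and conception-risk heterogeneity, spanning roughly
    TFR 1.5 at step 0 to 7.5 at the last step.
    """
    if n_regimes < 2:
        raise ConfigurationError("need at least 2 regimes")
    presets = []
    for i in range(n_regimes):
        t = i / (n_regimes - 1)
        presets.append(
            RegimePreset(
                f"regime_{i:02d}",
                _make_config(
                    fecundability=0.11 - 0.01 * t,
                    ppi=int(round(5 + 8 * t)),
                    prevalence=0.97 - 0.79 * t,
                    effectiveness=0.995 - 0.075 * t,
                    desired_mean=1.3 + 8.2 * t,
                    desired_sd=1.2 + 0.8 * t,
                    marriage_mean=26.0 - 9.5 * t,
                    marriage_sd=3.0 - 1.0 * t,
                    growth=0.005 + 0.027 * t,
                    cohort_size=cohort_size,
                    seed=seed + i,
                    cv=0.6 + 0.25 * t,
                ),
            )
        )
    return presets


# ---------------------------------------------------------------------------
# The monthly-step engine


def _sample_truncated_exponential(u: np.ndarray, span: float, rate: float
                                  ) -> np.ndarray:
    """Inverse CDF of an exponential truncated to [0, span)."""
    if rate <= 0:
        return u * span
    z = 1.0 - np.exp(-rate * span)
    return -np.log1p(-u * z) / rate


def simulate_survey(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a cohort and take a cross-sectional survey.

    Returns one row per woman with the survey schema columns
    (``woman_id, interview_cmc, age_years, parity, last_birth_cmc,
    currently_pregnant, currently_married``) plus ``birth_cmcs``, the full
    birth history as a semicolon-separated CMC list.  Identical
    configurations (including seed) yield identical output.
    """
    config.validate()
    n = config.cohort_size
    rng_streams = np.random.SeedSequence(config.seed).spawn(n)
    # Per-woman uniforms in a fixed order: 7 static draws then one per
    # month of the age grid (conception).
    u = np.empty((n, 7 + _N_MONTHS))
    for w, ss in enumerate(rng_streams):
        u[w] = np.random.Generator(np.random.PCG64(ss)).random(7 + _N_MONTHS)

    lo, hi = config.survey_age_range
    span = (hi + 1 - lo) * 12.0
    # Stable-population age density ∝ exp(-r·age): older cohorts entered
    # the population when it was smaller by a factor e^{-r·Δ}.
    age_offset = _sample_truncated_exponential(
        u[:, 0], span, config.annual_growth_rate / 12.0
    )
    survey_age_m = lo * 12 + np.floor(age_offset).astype(np.int64)

    marr_year = np.searchsorted(
        np.cumsum(config.marriage_age_distribution), u[:, 1], side="right"
    )
    marriage_age_m = (MARRIAGE_AGES[marr_year] * 12
                      + np.floor(u[:, 2] * 12).astype(np.int64))

    desired = DESIRED_PARITIES[
        np.searchsorted(np.cumsum(config.desired_parity_distribution),
                        u[:, 3], side="right")
    ]
    contraceptive_user = u[:, 4] < config.contraceptive_prevalence

    hazard_by_month = np.repeat(
        np.asarray(config.sterility_onset_hazard, dtype=float), 60
    )[:_N_MONTHS]
    cum_hazard = np.cumsum(hazard_by_month)
    sterile_age_m = _A0 + np.searchsorted(cum_hazard, -np.log(u[:, 5]))

    profile_by_month = np.repeat(
        np.asarray(config.fecundability_age_profile, dtype=float), 60
    )[:_N_MONTHS]
    if config.fecundability_cv > 0:
        from scipy import stats as _stats

        k = 1.0 / config.fecundability_cv**2
        frailty = _stats.gamma.ppf(u[:, 6], a=k, scale=1.0 / k)
    else:
        frailty = np.ones(n)
    base_p = np.minimum(
        config.monthly_fecundability
        * (1.0 - config.spousal_absence_factor)
        * frailty,
        1.0,
    )
    p_using = base_p * (1.0 - config.contraceptive_effectiveness)

    parity = np.zeros(n, dtype=np.int64)
    birth_due = np.full(n, -1, dtype=np.int64)      # age-month of pending birth
    postpartum_until = np.zeros(n, dtype=np.int64)
    conc_w: list[np.ndarray] = []
    conc_m: list[np.ndarray] = []

    for a in range(_A0, _A1):
        col = a - _A0
        delivering = birth_due == a
        if delivering.any():
            parity[delivering] += 1
            postpartum_until[delivering] = a + config.postpartum_infecundable_months
            birth_due[delivering] = -1
        using = contraceptive_user & (parity >= desired)
        p = profile_by_month[col] * np.where(using, p_using, base_p)
        exposed = (
            (a >= marriage_age_m)
            & (birth_due < 0)
            & (a >= postpartum_until)
            & (a < sterile_age_m)
        )
        conceiving = exposed & (u[:, 7 + col] < p)
        if conceiving.any():
            idx = np.nonzero(conceiving)[0]
            birth_due[idx] = a + config.gestation_months
            conc_w.append(idx)
            conc_m.append(np.full(idx.size, a, dtype=np.int64))

    if conc_w:
        woman = np.concatenate(conc_w)
        conception = np.concatenate(conc_m)
    else:
        woman = np.empty(0, dtype=np.int64)
        conception = np.empty(0, dtype=np.int64)
    birth = conception + config.gestation_months

    # Truncate each woman's history at her own survey age.
    s_at = survey_age_m[woman]
    born = birth <= s_at
    pregnant_ev = (conception <= s_at) & (birth > s_at)

    parity_out = np.zeros(n, dtype=np.int64)
    np.add.at(parity_out, woman[born], 1)
    last_birth_age = np.full(n, -1, dtype=np.int64)
    np.maximum.at(last_birth_age, woman[born], birth[born])
    pregnant_out = np.zeros(n, dtype=bool)
    pregnant_out[woman[pregnant_ev]] = True

    woman_birth_cmc = config.survey_cmc - survey_age_m
    last_birth_cmc = np.where(
        last_birth_age >= 0, woman_birth_cmc + last_birth_age, -1
    )

    histories = [""] * n
    if born.any():
        order = np.lexsort((birth[born], woman[born]))
        bw, bm = woman[born][order], birth[born][order]
        cmcs = woman_birth_cmc[bw] + bm
        hist_df = pd.DataFrame({"w": bw, "cmc": cmcs.astype(str)})
        for w, s in hist_df.groupby("w")["cmc"].agg(";".join).items():
            histories[w] = s

    records = pd.DataFrame(
        {
            "woman_id": [f"w{w:06d}" for w in range(n)],
            "interview_cmc": config.survey_cmc,
            "age_years": survey_age_m // 12,
            "parity": parity_out,
            "last_birth_cmc": pd.arrays.IntegerArray(
                last_birth_cmc.astype(np.int64), mask=last_birth_age < 0
            ),
            "currently_pregnant": pregnant_out,
            "currently_married": survey_age_m >= marriage_age_m,
            "birth_cmcs": histories,
        }
    )
    return records


# ---------------------------------------------------------------------------
# Direct samplers


def sample_power_law_survey(a: float, b: float, n: int,
                            seed: int | None = None) -> OpenIntervalDistribution:
    """Multinomial survey of n women from the power model a·x^(−b).

    Cell probabilities over interval years x = 1..20 are proportional to
    x^(−b) (the level parameter ``a`` fixes the printed scale, not the
    shape); counts sum to n.
    """
    if a <= 0 or b <= 0:
        raise DomainError(f"a and b must be positive, got a={a}, b={b}")
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    x = np.arange(1, N_INTERVALS + 1, dtype=float)
    p = x ** (-b)
    p /= p.sum()
    counts = np.random.default_rng(seed).multinomial(n, p)
    return OpenIntervalDistribution(f"power(a={a:g}, b={b:g}, n={n})", counts)


def sample_stationary_renewal(closed_interval_sampler, n: int,
                              burn_in_events: int = 50,
                              seed: int | None = None,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Backward and forward recurrence times at stationary inspections.

    Runs ``n`` independent renewal processes whose inter-event durations
    come from ``closed_interval_sampler(size, rng)`` and inspects each at
    a random time T drawn uniformly on [T₀, 2T₀], where T₀ is
    ``burn_in_events`` mean durations — long after process start, so the
    inspected interval is length-biased as in a cross-sectional survey.
    Returns ``(backward, forward)`` arrays of length n.
    """
    if burn_in_events < 50:
        raise DomainError("burn_in_events must be >= 50")
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)

    pilot = np.asarray(closed_interval_sampler(2000, rng), dtype=float)
    if (pilot <= 0).any() or not np.isfinite(pilot).all():
        raise DomainError("closed-interval sampler yielded non-positive or "
                          "non-finite durations")
    mu = pilot.mean()
    t0 = burn_in_events * mu
    inspect = t0 * (1.0 + rng.random(n))

    m = int(np.ceil(2.2 * burn_in_events + 10 * np.sqrt(burn_in_events))) + 5
    draws = np.asarray(closed_interval_sampler(n * m, rng), dtype=float)
    if (draws <= 0).any():
        raise DomainError("closed-interval sampler yielded non-positive durations")
    cum = np.cumsum(draws.reshape(n, m), axis=1)
    # top up the rare rows whose cumulative time has not reached T yet
    while (short := cum[:, -1] <= inspect).any():
        extra = np.asarray(
            closed_interval_sampler(int(short.sum()) * m, rng), dtype=float
        ).reshape(-1, m)
        if (extra <= 0).any():
            raise DomainError("closed-interval sampler yielded non-positive durations")
        cum = np.hstack([cum, np.zeros_like(cum)])
        cum[short, m:] = cum[short, m - 1, None] + np.cumsum(extra, axis=1)
        cum[~short, m:] = np.inf
        m = cum.shape[1]

    idx = np.sum(cum < inspect[:, None], axis=1)
    rows = np.arange(n)
    prev = np.where(idx > 0, cum[rows, np.maximum(idx - 1, 0)], 0.0)
    backward = inspect - prev
    forward = cum[rows, idx] - inspect
    return backward, forward
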