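"""Synthetic dated scratch densities with seasonal structure.

The generator reproduces the two sources of variability seen in dated
reference collections: (i) heterogeneity among individuals that died on the
same date (sex, age, health) and (ii) a season-dependent mean density — high
in spring/summer when abrasive graze dominates the diet, low in fall/winter.
The seasonal mean is a single-harmonic cosine of day-of-year, the minimal
model with that ordinal structure; individual noise is normal, truncated at
zero.  Day-of-death windows assemble the three duration scenarios:

* **A** — deaths spanning one month up to one season (window <= 92 days);
* **B** — deaths spanning four months up to a year (120–365 days);
* **C** — two separated short events in non-consecutive (opposite) seasons.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from . import config
from ._calendar import YEAR_DAYS, day_of_year, month_day, season_of, seasons_consecutive
from .records import IndividualRecord

__all__ = [
    "Scenario",
    "SeasonalDietModel",
    "Window",
    "default_model",
    "seasonal_mean",
    "simulate_event",
    "simulate_scenario",
]


class Scenario(str, enum.Enum):
    """Mortality-event duration category."""

    A = "A"  #: one month up to one season
    B = "B"  #: four months up to a year
    C = "C"  #: two short events in non-consecutive seasons

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SeasonalDietModel:
    """Parameters mapping a death date to an expected scratch density.

    All densities are in scratches per 0.16 mm^2.  ``peak_day`` is the
    day-of-year of the seasonal maximum in the Northern Hemisphere; for a
    Southern-Hemisphere population the phase is shifted by half a year.
    """

    baseline: float = config.DEFAULT_SEASONAL_MODEL["baseline"]
    amplitude: float = config.DEFAULT_SEASONAL_MODEL["amplitude"]
    peak_day: int = config.DEFAULT_SEASONAL_MODEL["peak_day"]
    individual_sd: float = config.DEFAULT_SEASONAL_MODEL["individual_sd"]
    hemisphere: str = config.DEFAULT_SEASONAL_MODEL["hemisphere"]

    def __post_init__(self):
        if self.baseline <= 0:
            raise ValueError("baseline must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 1 <= self.peak_day <= YEAR_DAYS:
            raise ValueError("peak_day must be in 1..365")
        if self.individual_sd <= 0:
            raise ValueError("individual_sd must be > 0")
        if self.hemisphere not in ("north", "south"):
            raise ValueError("hemisphere must be 'north' or 'south'")


def default_model(**overrides) -> SeasonalDietModel:
    """The calibrated default model (see :mod:`mortwear.config`)."""
    return replace(SeasonalDietModel(), **overrides) if overrides else SeasonalDietModel()


def seasonal_mean(day_of_year: int, model: SeasonalDietModel) -> float:
    """Expected scratch density on a given day of year.

    ``baseline + amplitude * cos(2*pi*(day - peak_day)/365)``, with the phase
    shifted by 182 days in the Southern Hemisphere.
    """
    if not 1 <= day_of_year <= YEAR_DAYS:
        raise ValueError(f"day_of_year {day_of_year} not in 1..365")
    day = day_of_year
    if model.hemisphere == "south":
        day = day - 182
    return model.baseline + model.amplitude * math.cos(
        2.0 * math.pi * (day - model.peak_day) / YEAR_DAYS
    )


def _draw_densities(mu: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Normal draws truncated at zero (negligible truncation for defaults)."""
    a = (0.0 - mu) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size, random_state=rng)


def simulate_event(
    dates,
    n_per_date: int,
    model: SeasonalDietModel,
    seed: int | np.random.Generator,
    sample_id: str = "sim",
    id_offset: int = 0,
) -> list[IndividualRecord]:
    """Simulate individual records for deaths on the given (month, day) dates.

    For each date, ``n_per_date`` densities are drawn from a normal with mean
    :func:`seasonal_mean` and SD ``model.individual_sd``, truncated at zero.
    Each density is split into two identical area counts.  Deterministic for
    a fixed seed.
    """
    if n_per_date < 1:
        raise ValueError("n_per_date must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    k = id_offset
    for month, day in dates:
        doy = day_of_year(month, day)  # validates the date
        mu = seasonal_mean(doy, model)
        dens = _draw_densities(mu, model.individual_sd, n_per_date, rng)
        for d in dens:
            records.append(
                IndividualRecord(
                    specimen_id=f"{sample_id}-{k:04d}",
                    sample_id=sample_id,
                    species="synthetic",
                    death_month=month,
                    death_day=day,
                    count_area1=float(d),
                    count_area2=float(d),
                    hemisphere=model.hemisphere,
                )
            )
            k += 1
    return records


@dataclass(frozen=True)
class Window:
    """A death-date window: ``length`` days starting at day-of-year ``start``
    (windows may wrap past the end of the year)."""

    start: int
    length: int

    def __post_init__(self):
        if not 1 <= self.start <= YEAR_DAYS:
            raise ValueError("start must be in 1..365")
        if not 1 <= self.length <= YEAR_DAYS:
            raise ValueError("length must be in 1..365")

    def days(self, n: int) -> list[int]:
        """n days of year evenly spread over the window."""
        if n == 1:
            offs = [self.length // 2]
        else:
            offs = [round(i * (self.length - 1) / (n - 1)) for i in range(n)]
        return [(self.start - 1 + o) % YEAR_DAYS + 1 for o in offs]

    @property
    def mid_day(self) -> int:
        return (self.start - 1 + self.length // 2) % YEAR_DAYS + 1

    def season(self, hemisphere: str = "north") -> str:
        """Season of the window midpoint."""
        return season_of(month_day(self.mid_day)[0], hemisphere)


def _window_dates(window: Window, n: int):
    return [month_day(d) for d in window.days(n)]


def simulate_scenario(
    label: Scenario | str,
    n: int,
    model: SeasonalDietModel,
    windows,
    seed: int | np.random.Generator,
    proportion: float = 0.5,
    sample_id: str | None = None,
) -> list[IndividualRecord]:
    """Simulate one mortality event of a given duration scenario.

    Parameters
    ----------
    windows : Window or (Window, Window)
        A single window for scenarios A and B; for C, the pair of short
        windows (their seasons must be non-consecutive).
    n : int
        Total number of individuals; death dates are spread evenly over the
        window(s).  For C, ``proportion`` is the fraction assigned to the
        warmer window (the one with the higher expected density).
    """
    label = Scenario(label)
    if n < 2:
        raise ValueError("n must be >= 2")
    if n < config.DEFAULT_MIN_SIZE:
        import warnings

        warnings.warn(
            f"n={n} is below the minimum training sub-sample size "
            f"({config.DEFAULT_MIN_SIZE}); the resulting SD is biased low",
            stacklevel=2,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sid = sample_id or f"sim-{label.value}"

    if label in (Scenario.A, Scenario.B):
        if isinstance(windows, (tuple, list)):
            (window,) = windows
        else:
            window = windows
        if label is Scenario.A and window.length > 92:
            raise ValueError(f"scenario A window must be <= 92 days, got {window.length}")
        if label is Scenario.B and not 120 <= window.length <= 365:
            raise ValueError(f"scenario B window must be 120..365 days, got {window.length}")
        return simulate_event(_window_dates(window, n), 1, model, rng, sample_id=sid)

    # scenario C: two short events in opposite seasons
    w1, w2 = windows
    if w1.length > 92 or w2.length > 92:
        raise ValueError("scenario C component events must each span <= 92 days")
    s1, s2 = w1.season(model.hemisphere), w2.season(model.hemisphere)
    if seasons_consecutive(s1, s2):
        raise ValueError(
            f"scenario C requires non-consecutive seasons, got {s1!r} and {s2!r}"
        )
    if not 0.0 < proportion < 1.0:
        raise ValueError("proportion must be strictly between 0 and 1")
    warm, cold = (w1, w2)
    if seasonal_mean(w2.mid_day, model) > seasonal_mean(w1.mid_day, model):
        warm, cold = (w2, w1)
    n_warm = max(1, min(n - 1, round(proportion * n)))
    recs = simulate_event(_window_dates(warm, n_warm), 1, model, rng, sample_id=sid)
    recs += simulate_event(
        _window_dates(cold, n - n_warm), 1, model, rng, sample_id=sid, id_offset=n_warm
    )
    return recs
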