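"""Fixed 365-day calendar and meteorological season helpers.

Leap days are ignored throughout: mortality-event durations are resolved at
the month/season scale, where a single day is irrelevant.
"""

from __future__ import annotations

DAYS_IN_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
YEAR_DAYS = 365

# cumulative days before each month (1-based month index)
_CUM = [0]
for _d in DAYS_IN_MONTH:
    _CUM.append(_CUM[-1] + _d)

#: meteorological seasons in the Northern Hemisphere (month triplets)
SEASON_OF_MONTH_NORTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

#: pairs of non-consecutive (opposite) seasons
OPPOSITE_SEASON = {
    "winter": "summer", "summer": "winter",
    "spring": "autumn", "autumn": "spring",
}


def valid_date(month: int, day: int) -> bool:
    return 1 <= month <= 12 and 1 <= day <= DAYS_IN_MONTH[month - 1]


def day_of_year(month: int, day: int) -> int:
    """1-based day of year on the fixed 365-day calendar."""
    if not valid_date(month, day):
        raise ValueError(f"invalid date: month={month}, day={day}")
    return _CUM[month - 1] + day


def month_day(doy: int) -> tuple[int, int]:
    """Inverse of :func:`day_of_year` (``doy`` taken modulo 365)."""
    doy = (doy - 1) % YEAR_DAYS + 1
    for m in range(1, 13):
        if doy <= _CUM[m]:
            return m, doy - _CUM[m - 1]
    raise AssertionError("unreachable")


def season_of(month: int, hemisphere: str = "north") -> str:
    """Meteorological season of a month, flipped for the Southern Hemisphere."""
    if hemisphere not in ("north", "south"):
        raise ValueError(f"hemisphere must be 'north' or 'south', got {hemisphere!r}")
    if hemisphere == "south":
        month = (month + 5) % 12 + 1
    return SEASON_OF_MONTH_NORTH[month]


def seasons_consecutive(s1: str, s2: str) -> bool:
    """True unless the two seasons are separated by an intervening season."""
    return OPPOSITE_SEASON[s1] != s2
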