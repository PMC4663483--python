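"""Individual death records and published sample aggregates.

A record is one specimen: where and when it died (to day or month resolution)
and the scratch counts in one or two standard 0.16 mm^2 enamel areas.
Records travel as plain UTF-8 CSV with a fixed header contract
(:data:`RECORD_COLUMNS`); missing day-of-death or second-area count are
empty fields, never zeros.

The module also embeds, as in-memory fixtures, the published (SD, CV, N)
coordinates of the ten extant mass-mortality reference samples and the eleven
Palaeolithic test samples, so the classifier can be exercised without any
external data.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields

from ._calendar import DAYS_IN_MONTH, day_of_year

__all__ = [
    "IndividualRecord",
    "SampleAggregate",
    "RecordParseError",
    "RECORD_COLUMNS",
    "read_records",
    "write_records",
    "load_reference_tables",
    "extant_samples",
    "fossil_samples",
    "reference_sample",
]

#: CSV header contract for individual records, in column order.
RECORD_COLUMNS = (
    "specimen_id",
    "sample_id",
    "species",
    "death_year",
    "death_month",
    "death_day",
    "count_area1",
    "count_area2",
    "hemisphere",
)

_MANDATORY = ("specimen_id", "sample_id", "species", "death_month", "count_area1")


class RecordParseError(ValueError):
    """A data row violated the record contract; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class IndividualRecord:
    """One specimen's dated death and scratch counts.

    ``death_day`` may be missing (month-level resolution); such records are
    placed mid-month (day 15) for any date arithmetic.  ``count_area2`` may be
    missing for teeth with a single countable area.
    """

    specimen_id: str
    sample_id: str
    species: str
    death_month: int
    count_area1: float
    death_year: int | None = None
    death_day: int | None = None
    count_area2: float | None = None
    hemisphere: str = "north"

    def __post_init__(self):
        if not 1 <= self.death_month <= 12:
            raise ValueError(f"death_month {self.death_month} not in 1..12")
        if self.death_day is not None and not (
            1 <= self.death_day <= DAYS_IN_MONTH[self.death_month - 1]
        ):
            raise ValueError(
                f"death_day {self.death_day} invalid for month {self.death_month}"
            )
        for name in ("count_area1", "count_area2"):
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.hemisphere not in ("north", "south"):
            raise ValueError(f"hemisphere must be 'north' or 'south', got {self.hemisphere!r}")

    @property
    def day_of_year(self) -> int:
        """Day of death on the fixed 365-day calendar (mid-month if day unknown)."""
        return day_of_year(self.death_month, self.death_day if self.death_day is not None else 15)


@dataclass(frozen=True)
class SampleAggregate:
    """Published per-sample variability coordinates (as printed, not recomputed)."""

    sample_id: str
    species: str
    locality: str
    duration_label: str
    n: int
    sd: float
    cv: float
    fossil: bool = False

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0 or self.cv < 0:
            raise ValueError("sd and cv must be >= 0")


def _parse_row(row: dict, rownum: int) -> IndividualRecord:
    def get(name):
        v = row.get(name)
        return v.strip() if isinstance(v, str) else v

    for name in _MANDATORY:
        if not get(name):
            raise RecordParseError(rownum, f"missing mandatory value {name!r}")

    def as_int(name):
        v = get(name)
        if not v:
            return None
        try:
            return int(v)
        except ValueError:
            raise RecordParseError(rownum, f"{name}={v!r} is not an integer") from None

    def as_float(name):
        v = get(name)
        if not v:
            return None
        try:
            return float(v)
        except ValueError:
            raise RecordParseError(rownum, f"{name}={v!r} is not a number") from None

    try:
        return IndividualRecord(
            specimen_id=get("specimen_id"),
            sample_id=get("sample_id"),
            species=get("species"),
            death_year=as_int("death_year"),
            death_month=as_int("death_month"),
            death_day=as_int("death_day"),
            count_area1=as_float("count_area1"),
            count_area2=as_float("count_area2"),
            hemisphere=get("hemisphere") or "north",
        )
    except ValueError as exc:
        raise RecordParseError(rownum, str(exc)) from None


def read_records(path, **dialect) -> list[IndividualRecord]:
    """Read individual records from a CSV file.

    Parameters
    ----------
    path : path-like
        CSV file with a header row naming at least the mandatory columns
        (specimen_id, sample_id, species, death_month, count_area1).
    **dialect
        Extra keyword arguments forwarded to :class:`csv.DictReader`
        (e.g. ``delimiter=";"``).

    Raises
    ------
    ValueError
        If a mandatory column is absent from the header (file-level), or — as
        :class:`RecordParseError` — if a row is malformed (row-level, with the
        offending row number).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, **dialect)
        header = reader.fieldnames or []
        missing = [c for c in _MANDATORY if c not in header]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {missing}")
        return [_parse_row(row, i) for i, row in enumerate(reader, start=2)]


def write_records(records, path) -> None:
    """Write records as CSV under the :data:`RECORD_COLUMNS` header contract.

    Floats are written with :func:`repr` so a read/write round trip reproduces
    every value bit-identically; missing values become empty fields.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_COLUMNS)
        for rec in records:
            row = []
            for f in RECORD_COLUMNS:
                v = getattr(rec, f)
                if v is None:
                    row.append("")
                elif isinstance(v, float):
                    row.append(repr(v))
                else:
                    row.append(v)
            writer.writerow(row)


# --- published reference coordinates -------------------------------------
# Ten extant samples from documented mass-mortality events (duration known
# from field records) and eleven Middle/Upper Pleistocene samples used to
# test the classifier.  Values as printed; CV is a dimensionless ratio.

_EXTANT = (
    ("1", "Rangifer tarandus", "Qamanirjuaq population (Canada)", "years", 473, 4.555, 0.359),
    ("2a", "Cervus elaphus", "Mount Saint Helens (Washington, USA)", "1 day", 63, 1.054, 0.089),
    ("2b", "Cervus elaphus", "Pierce and Lewis Counties (Washington, USA)", "years", 13, 2.800, 0.159),
    ("3a", "Antilocapra americana", "Green River (Wyoming, USA)", "1 day", 89, 0.823, 0.094),
    ("3b", "Antilocapra americana", "Lamont and Rawlins Counties (Wyoming, USA)", "years", 71, 3.152, 0.314),
    ("4", "Odocoileus hemionus", "Cache La Poudre River (Colorado, USA)", "years", 49, 4.706, 0.261),
    ("5", "Cervus elaphus", "Isle of Rum (Scotland, UK)", "season", 174, 1.843, 0.155),
    ("6", "Cervus nippon", "Kinkazan Island (Japan)", "season", 69, 2.242, 0.122),
    ("7", "Lama guanicoe", "Cardiel lake (Patagonia, Argentina)", "season", 91, 2.246, 0.176),
    ("8", "Equus quagga", "West of Mount Rumuruti (Kenya)", "nd", 28, 3.952, 0.137),
)

_FOSSIL = (
    ("A1", "Rangifer tarandus", "Portel-Ouest, level F", 30, 3.097, 0.122),
    ("A2", "Equus ferus", "Portel-Ouest, level F", 27, 3.910, 0.178),
    ("A3", "Cervus elaphus", "Portel-Ouest, level F", 21, 2.764, 0.147),
    ("A4", "Bos/Bison", "Portel-Ouest, level F", 25, 2.459, 0.107),
    ("B1", "Cervus elaphus", "Abric Romani, level K", 14, 6.970, 0.350),
    ("B2", "Cervus elaphus", "Abric Romani, level M", 19, 2.629, 0.092),
    ("C1", "Rangifer tarandus", "Salzgitter Lebenstedt", 81, 1.827, 0.170),
    ("D1", "Bison priscus", "Taubach", 22, 4.134, 0.242),
    ("E1", "Equus ferus", "Caune de l'Arago, level G", 38, 5.705, 0.174),
    ("E2", "Cervus elaphus", "Caune de l'Arago, level J", 27, 6.795, 0.329),
    ("E3", "Rangifer tarandus", "Caune de l'Arago, level L", 30, 3.121, 0.142),
)


def extant_samples() -> list[SampleAggregate]:
    """The ten extant mass-mortality reference samples."""
    return [
        SampleAggregate(sid, sp, loc, dur, n, sd, cv, fossil=False)
        for sid, sp, loc, dur, n, sd, cv in _EXTANT
    ]


def fossil_samples() -> list[SampleAggregate]:
    """The eleven Palaeolithic samples used to test the classifier."""
    return [
        SampleAggregate(sid, sp, loc, "nd", n, sd, cv, fossil=True)
        for sid, sp, loc, n, sd, cv in _FOSSIL
    ]


def load_reference_tables() -> list[SampleAggregate]:
    """All 21 published sample aggregates (10 extant + 11 fossil)."""
    return extant_samples() + fossil_samples()


def reference_sample(sample_id: str) -> SampleAggregate:
    """Look up one published aggregate by id (e.g. ``"3a"`` or ``"D1"``)."""
    for agg in load_reference_tables():
        if agg.sample_id == sample_id:
            return agg
    raise KeyError(f"unknown sample id {sample_id!r}")


def reference_frame():
    """The reference tables as a :class:`pandas.DataFrame`."""
    import pandas as pd

    return pd.DataFrame(
        [{f.name: getattr(a, f.name) for f in fields(SampleAggregate)} for a in load_reference_tables()]
    )
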