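"""Parsing and cleaning of month-resolution residential histories.

Cohort members reported every address they lived at with FROM/TO month and
year.  The cleaning rules applied here:

* a residence begins on the first day of its FROM month and ends on the last
  day of its TO month (only month and year were collected);
* a missing FROM month defaults to 1 July and a missing TO month to 30 June
  (the year midpoint, so the error is equally likely to over- or
  under-state residence time);
* a FROM date before the subject's date of birth is replaced by the DOB,
  provided the DOB falls inside the exposure window; subjects born after the
  window contribute nothing and their records are dropped;
* records missing a FROM or TO *year* carry no usable information and are
  dropped;
* surviving intervals are clipped to the exposure window (Jul 1952 –
  Dec 1988 by default, the coverage of the release timeline).

Dates inherited from the original SAS extracts are day counts from the SAS
origin 1960-01-01; :func:`sas_date_decode` converts them.
"""
from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SAS_ORIGIN = date(1960, 1, 1)

WINDOW_START = date(1952, 7, 1)
WINDOW_END = date(1988, 12, 31)

FLAG_DEFAULTED_FROM_MONTH = "defaulted_from_month"
FLAG_DEFAULTED_TO_MONTH = "defaulted_to_month"
FLAG_DOB_OVERRIDE = "dob_override"
FLAG_DROPPED_MISSING_YEAR = "dropped_missing_year"
FLAG_DROPPED_UNMAPPABLE = "dropped_unmappable"
FLAG_DROPPED_OUTSIDE_WINDOW = "dropped_outside_window"
FLAG_DROPPED_INVERTED = "dropped_inverted"


def sas_date_decode(days: int) -> date:
    """Date encoded as a signed day count from the SAS origin 1960-01-01."""
    return SAS_ORIGIN + timedelta(days=int(days))


def _last_day(year: int, month: int) -> date:
    return date(year, month, calendar.monthrange(year, month)[1])


@dataclass(frozen=True)
class ResidenceRecord:
    """One raw residence report; ``None`` marks a missing field."""

    subject_id: str
    sector_id: str | None
    from_year: int | None
    from_month: int | None
    to_year: int | None
    to_month: int | None


@dataclass(frozen=True)
class CleanedResidence:
    """A residence interval surviving all cleaning rules."""

    subject_id: str
    sector_id: str
    start: date
    end: date
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class DropDecision:
    subject_id: str
    reason: str


def clean_record(
    record: ResidenceRecord | CleanedResidence,
    dob: date | None,
    grid=None,
    window: tuple[date, date] = (WINDOW_START, WINDOW_END),
) -> CleanedResidence | DropDecision:
    """Apply all cleaning rules to one record.

    Cleaning is idempotent: a :class:`CleanedResidence` re-enters only the
    clipping stage and comes back unchanged.
    """
    win_lo, win_hi = window
    if isinstance(record, CleanedResidence):
        start, end, flags = record.start, record.end, set(record.flags)
        sector = record.sector_id
    else:
        if record.from_year is None or record.to_year is None:
            return DropDecision(record.subject_id, FLAG_DROPPED_MISSING_YEAR)
        sector = record.sector_id
        if sector is None or (grid is not None and sector not in grid):
            return DropDecision(record.subject_id, FLAG_DROPPED_UNMAPPABLE)
        flags = set()
        if record.from_month is None:
            start = date(int(record.from_year), 7, 1)
            flags.add(FLAG_DEFAULTED_FROM_MONTH)
        else:
            start = date(int(record.from_year), int(record.from_month), 1)
        if record.to_month is None:
            end = date(int(record.to_year), 6, 30)
            flags.add(FLAG_DEFAULTED_TO_MONTH)
        else:
            end = _last_day(int(record.to_year), int(record.to_month))
        if end < start:
            return DropDecision(record.subject_id, FLAG_DROPPED_INVERTED)

    if dob is not None and start < dob:
        if dob > win_hi:
            return DropDecision(record.subject_id, FLAG_DROPPED_OUTSIDE_WINDOW)
        start = dob
        flags.add(FLAG_DOB_OVERRIDE)

    start = max(start, win_lo)
    end = min(end, win_hi)
    if end < start:
        return DropDecision(record.subject_id, FLAG_DROPPED_OUTSIDE_WINDOW)
    return CleanedResidence(
        subject_id=record.subject_id,
        sector_id=sector,
        start=start,
        end=end,
        flags=frozenset(flags),
    )


@dataclass
class Subject:
    subject_id: str
    dob: date | None
    residences: list[CleanedResidence] = field(default_factory=list)

    def resident_months(self, year: int) -> set[int]:
        """Calendar months of ``year`` covered by any residence (any-day rule)."""
        months: set[int] = set()
        for r in self.residences:
            for m in range(1, 13):
                if r.start <= _last_day(year, m) and r.end >= date(year, m, 1):
                    months.add(m)
        return months


def occupancy_fraction(record: CleanedResidence, year: int) -> tuple[float, tuple[int, ...]]:
    """Fraction of ``year`` covered by the record, with the resident months.

    A month counts as resident if the interval covers any day of it.
    """
    months = tuple(
        m
        for m in range(1, 13)
        if record.start <= _last_day(year, m) and record.end >= date(year, m, 1)
    )
    return len(months) / 12.0, months


# ---------------------------------------------------------------------------
# Cohort-level cleaning and reporting
# ---------------------------------------------------------------------------

@dataclass
class CleaningReport:
    """Missingness accounting for raw records, plus survival counts."""

    n_residences: int = 0
    missing_from_month: int = 0
    missing_to_month: int = 0
    missing_from_year: int = 0
    missing_to_year: int = 0
    n_subjects: int = 0
    subjects_missing_from_month: int = 0
    subjects_missing_to_month: int = 0
    subjects_missing_from_year: int = 0
    subjects_missing_to_year: int = 0
    n_residences_dropped: int = 0
    n_subjects_removed: int = 0
    drop_reasons: dict = field(default_factory=dict)
    n_overlapping_pairs: int = 0

    @property
    def n_residences_retained(self) -> int:
        return self.n_residences - self.n_residences_dropped

    @property
    def n_subjects_retained(self) -> int:
        return self.n_subjects - self.n_subjects_removed

    def percentages(self) -> dict[str, float]:
        def pct(k: int, n: int) -> float:
            return 100.0 * k / n if n else 0.0

        return {
            "missing_from_month": pct(self.missing_from_month, self.n_residences),
            "missing_to_month": pct(self.missing_to_month, self.n_residences),
            "missing_from_year": pct(self.missing_from_year, self.n_residences),
            "missing_to_year": pct(self.missing_to_year, self.n_residences),
            "subjects_missing_from_month": pct(self.subjects_missing_from_month, self.n_subjects),
            "subjects_missing_to_month": pct(self.subjects_missing_to_month, self.n_subjects),
            "subjects_missing_from_year": pct(self.subjects_missing_from_year, self.n_subjects),
            "subjects_missing_to_year": pct(self.subjects_missing_to_year, self.n_subjects),
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        rows = [
            ("residences_total", self.n_residences, 100.0),
            ("residences_missing_from_month", self.missing_from_month, pct["missing_from_month"]),
            ("residences_missing_to_month", self.missing_to_month, pct["missing_to_month"]),
            ("residences_missing_from_year", self.missing_from_year, pct["missing_from_year"]),
            ("residences_missing_to_year", self.missing_to_year, pct["missing_to_year"]),
            ("residences_dropped", self.n_residences_dropped, None),
            ("residences_retained", self.n_residences_retained, None),
            ("subjects_total", self.n_subjects, 100.0),
            ("subjects_missing_from_month", self.subjects_missing_from_month, pct["subjects_missing_from_month"]),
            ("subjects_missing_to_month", self.subjects_missing_to_month, pct["subjects_missing_to_month"]),
            ("subjects_missing_from_year", self.subjects_missing_from_year, pct["subjects_missing_from_year"]),
            ("subjects_missing_to_year", self.subjects_missing_to_year, pct["subjects_missing_to_year"]),
            ("subjects_removed", self.n_subjects_removed, None),
            ("subjects_retained", self.n_subjects_retained, None),
        ]
        return pd.DataFrame(rows, columns=["category", "count", "percent"])


def cleaning_report(
    records: Sequence[ResidenceRecord],
    dobs: Mapping[str, date | None] | None = None,
    grid=None,
    window: tuple[date, date] = (WINDOW_START, WINDOW_END),
) -> tuple[list[Subject], CleaningReport]:
    """Clean a raw record set and account for every missingness category."""
    dobs = dobs or {}
    report = CleaningReport()
    report.n_residences = len(records)
    by_subject: dict[str, list[ResidenceRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    report.n_subjects = len(by_subject)

    def _count_missing(recs: Iterable[ResidenceRecord], attr: str) -> int:
        return sum(1 for r in recs if getattr(r, attr) is None)

    report.missing_from_month = _count_missing(records, "from_month")
    report.missing_to_month = _count_missing(records, "to_month")
    report.missing_from_year = _count_missing(records, "from_year")
    report.missing_to_year = _count_missing(records, "to_year")
    for attr, field_name in (
        ("from_month", "subjects_missing_from_month"),
        ("to_month", "subjects_missing_to_month"),
        ("from_year", "subjects_missing_from_year"),
        ("to_year", "subjects_missing_to_year"),
    ):
        n = sum(1 for recs in by_subject.values() if _count_missing(recs, attr))
        setattr(report, field_name, n)

    subjects: list[Subject] = []
    for sid, recs in by_subject.items():
        dob = dobs.get(sid)
        cleaned: list[CleanedResidence] = []
        for r in recs:
            out = clean_record(r, dob, grid=grid, window=window)
            if isinstance(out, DropDecision):
                report.n_residences_dropped += 1
                report.drop_reasons[out.reason] = report.drop_reasons.get(out.reason, 0) + 1
            else:
                cleaned.append(out)
        # overlapping residences are kept, but logged
        ordered = sorted(cleaned, key=lambda c: c.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                report.n_overlapping_pairs += 1
                logger.info("subject %s: overlapping residences %s and %s", sid, a, b)
        if cleaned:
            subjects.append(Subject(subject_id=sid, dob=dob, residences=cleaned))
        else:
            report.n_subjects_removed += 1
    return subjects, report


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def _parse_dob(value) -> date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return sas_date_decode(int(value))
    except (TypeError, ValueError):
        return pd.Timestamp(value).date()


def load_residences_csv(
    path: str | Path,
) -> tuple[list[ResidenceRecord], dict[str, date | None]]:
    """Read a residence CSV.

    Expected columns: subject_id, dob, sector_id, from_year, from_month,
    to_year, to_month; empty cells mark missing values.  The dob column may
    hold ISO-8601 dates or SAS day counts (auto-detected per value).
    """
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str, "sector_id": str})
    required = {"subject_id", "dob", "sector_id", "from_year", "from_month", "to_year", "to_month"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"residence CSV missing columns {sorted(missing)}")

    def _opt_int(v) -> int | None:
        return None if pd.isna(v) else int(v)

    records = []
    dobs: dict[str, date | None] = {}
    for row in df.itertuples(index=False):
        sid = str(row.subject_id)
        dobs[sid] = _parse_dob(row.dob)
        sector = None if pd.isna(row.sector_id) else str(row.sector_id)
        records.append(
            ResidenceRecord(
                subject_id=sid,
                sector_id=sector,
                from_year=_opt_int(row.from_year),
                from_month=_opt_int(row.from_month),
                to_year=_opt_int(row.to_year),
                to_month=_opt_int(row.to_month),
            )
        )
    return records, dobs


def write_residences_csv(
    path: str | Path,
    records: Sequence[ResidenceRecord],
    dobs: Mapping[str, date | None],
) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "dob": dobs.get(r.subject_id).isoformat() if dobs.get(r.subject_id) else "",
            "sector_id": r.sector_id if r.sector_id is not None else "",
            "from_year": r.from_year if r.from_year is not None else "",
            "from_month": r.from_month if r.from_month is not None else "",
            "to_year": r.to_year if r.to_year is not None else "",
            "to_month": r.to_month if r.to_month is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
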