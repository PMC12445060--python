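"""Assemble sector×time concentration tables and per-subject exposures.

The pipeline composes the other modules: for every sector and every calendar
month of the study window it evaluates the sector-averaged plume model with
the month's joint-frequency wind table (wind ratios taken from the octet
reciprocal to the sector) and the month's release rate.  The annual value of
a sector-year is the mean of its 12 monthly values, so every subject resident
in a sector for a full calendar year sees the identical concentration.

Per-subject annual exposures average the monthly concentrations over the
months the subject was actually resident, and the subject's overall mean is
the duration-weighted mean of the annual values.  Exceedance statistics are
counted against a concentration threshold (the EPA indoor action level is
4 pCi·L⁻¹) either on any single annual value or on the overall mean.
Concentrations are the increment above natural background; background radon
is not added.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dispersion import (
    PCI_PER_L_FROM_CI_PER_M3,
    CalibrationParams,
    DispersionConfig,
    calibration_factor,
    diffusion_matrix,
)
from .meteorology import JointFrequencyTable, consolidate_16_to_8, wind_ratio_rose
from .residential_history import Subject, occupancy_fraction
from .sector_grid import SectorGrid, reciprocal_direction
from .source_term import EmissionTimeline

logger = logging.getLogger(__name__)

DEFAULT_YEARS = (1952, 1988)
EPA_ACTION_LEVEL = 4.0  # pCi·L⁻¹
EPA_RECOMMENDED_LEVEL = 2.0  # pCi·L⁻¹


@dataclass
class ExposureMatrix:
    """Concentrations (pCi·L⁻¹) on the (sector, calendar month) grid.

    ``monthly`` has shape (n_sectors, n_months) over the calendar months of
    ``years`` (Jan of the first year through Dec of the last); ``annual`` is
    the within-year mean, shape (n_sectors, n_years).
    """

    sector_ids: list[str]
    years: np.ndarray
    monthly: np.ndarray
    _pos: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.monthly = np.asarray(self.monthly, dtype=float)
        n_months = 12 * len(self.years)
        if self.monthly.shape != (len(self.sector_ids), n_months):
            raise ValueError("monthly grid shape does not match sectors × months")
        if (self.monthly < 0).any():
            raise ValueError("concentrations must be non-negative")
        self._pos = {sid: i for i, sid in enumerate(self.sector_ids)}

    @property
    def annual(self) -> np.ndarray:
        return self.monthly.reshape(len(self.sector_ids), len(self.years), 12).mean(axis=2)

    def _month_col(self, year: int, month: int) -> int:
        return (int(year) - int(self.years[0])) * 12 + int(month) - 1

    def monthly_value(self, sector_id: str, year: int, month: int) -> float:
        return float(self.monthly[self._pos[sector_id], self._month_col(year, month)])

    def annual_value(self, sector_id: str, year: int) -> float:
        return float(self.annual[self._pos[sector_id], int(year) - int(self.years[0])])

    def sector_row(self, sector_id: str) -> np.ndarray:
        return self.monthly[self._pos[sector_id]]

    def to_annual_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.annual, index=self.sector_ids, columns=self.years)
        df.index.name = "sector_id"
        out = df.reset_index().melt(id_vars="sector_id", var_name="year", value_name="pci_per_l")
        return out.sort_values(["sector_id", "year"]).reset_index(drop=True)

    def to_monthly_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_product([self.years, range(1, 13)], names=["year", "month"])
        df = pd.DataFrame(self.monthly, index=self.sector_ids, columns=cols)
        df.index.name = "sector_id"
        out = df.stack(["year", "month"], future_stack=True).rename("pci_per_l").reset_index()
        return out


def monthly_wind_ratio_stack(met_tables: Sequence[JointFrequencyTable]) -> np.ndarray:
    """Consolidated per-stability octet wind ratios, shape (12, 6, 8)."""
    if len(met_tables) != 12:
        raise ValueError(f"need 12 monthly met tables, got {len(met_tables)}")
    ordered = sorted(met_tables, key=lambda t: t.month)
    if [t.month for t in ordered] != list(range(1, 13)):
        raise ValueError("met tables must cover months 1..12 exactly once")
    return np.stack(
        [consolidate_16_to_8(wind_ratio_rose(t)).by_stability for t in ordered]
    )


def build_matrix(
    grid: SectorGrid,
    timeline: EmissionTimeline,
    met_tables: Sequence[JointFrequencyTable],
    calib: CalibrationParams | None = None,
    config: DispersionConfig | None = None,
    years: tuple[int, int] = DEFAULT_YEARS,
    quantile: str = "median",
) -> ExposureMatrix:
    """Evaluate the plume model on every (sector, calendar month) cell."""
    calib = calib or CalibrationParams()
    config = config or DispersionConfig()
    R8 = monthly_wind_ratio_stack(met_tables)  # (12, 6, 8)

    sector_ids = grid.ids()
    octet_idx = []
    distances = []
    from .meteorology import OCTETS

    for sid in sector_ids:
        octet, dist = grid.receptor_geometry(sid)
        octet_idx.append(OCTETS.index(reciprocal_direction(octet)))
        distances.append(dist)
    distances = np.asarray(distances)

    try:
        K = np.asarray(calibration_factor(calib, distances))
        D = diffusion_matrix(config, distances)  # (6, n_sectors)
    except ValueError as exc:
        raise ValueError(f"dispersion evaluation failed for sector grid: {exc}") from exc

    # per-sector, per-calendar-month meteorological factor Σ_s R_s·D_s
    met_factor = np.einsum("msi,si->im", R8[:, :, octet_idx], D)  # (n_sectors, 12)

    y0, y1 = years
    yrs = np.arange(y0, y1 + 1)
    q_per_s = np.array(
        [
            timeline.monthly_rate(y, m, quantile) / config.seconds_per_year
            for y in yrs
            for m in range(1, 13)
        ]
    )
    month_of_year = np.tile(np.arange(12), len(yrs))
    monthly = (
        K[:, None]
        * met_factor[:, month_of_year]
        * q_per_s[None, :]
        * config.phi_resid
        * config.phi_met
        * PCI_PER_L_FROM_CI_PER_M3
    )
    return ExposureMatrix(sector_ids=sector_ids, years=yrs, monthly=monthly)


# ---------------------------------------------------------------------------
# Per-subject exposure
# ---------------------------------------------------------------------------

@dataclass
class SubjectExposure:
    """Occupancy-weighted annual exposure series for one subject.

    ``annual`` maps year → mean concentration over the subject's resident
    sector-months of that year; ``weights`` maps year → resident months / 12
    (can exceed 1 when residences overlap).  ``mean`` is the
    duration-weighted mean of the annual values.
    """

    subject_id: str
    annual: dict[int, float]
    weights: dict[int, float]
    mean: float
    years_resident: float


def subject_mean_exposure(
    annual: Mapping[int, float], weights: Mapping[int, float]
) -> float:
    """Duration-weighted arithmetic mean of annual exposures (pCi·L⁻¹)."""
    total_w = sum(weights.values())
    if total_w <= 0:
        raise ValueError("subject has no resident time")
    return sum(annual[y] * weights[y] for y in annual) / total_w


def subject_exposure(matrix: ExposureMatrix, subject: Subject) -> SubjectExposure | None:
    """Annual series and mean for one subject; ``None`` if no resident time."""
    y0, y1 = int(matrix.years[0]), int(matrix.years[-1])
    conc_sum: dict[int, float] = {}
    month_count: dict[int, int] = {}
    for rec in subject.residences:
        if rec.sector_id not in matrix._pos:
            raise KeyError(f"subject {subject.subject_id}: unknown sector {rec.sector_id!r}")
        row = matrix.sector_row(rec.sector_id)
        for year in range(max(rec.start.year, y0), min(rec.end.year, y1) + 1):
            _, months = occupancy_fraction(rec, year)
            if not months:
                continue
            cols = [(year - y0) * 12 + m - 1 for m in months]
            conc_sum[year] = conc_sum.get(year, 0.0) + float(row[cols].sum())
            month_count[year] = month_count.get(year, 0) + len(months)
    if not month_count:
        return None
    annual = {y: conc_sum[y] / month_count[y] for y in month_count}
    weights = {y: month_count[y] / 12.0 for y in month_count}
    mean = subject_mean_exposure(annual, weights)
    return SubjectExposure(
        subject_id=subject.subject_id,
        annual=annual,
        weights=weights,
        mean=mean,
        years_resident=sum(weights.values()),
    )


def subject_annual_exposure(matrix: ExposureMatrix, subject: Subject, year: int) -> float:
    """Occupancy-weighted exposure of one subject in one year; 0 if not resident."""
    exp = subject_exposure(matrix, subject)
    if exp is None:
        return 0.0
    return exp.annual.get(int(year), 0.0)


@dataclass
class CohortExposures:
    """Exposure results for every subject with positive resident time."""

    subjects: list[SubjectExposure]
    n_excluded_no_residence: int = 0

    def means(self) -> np.ndarray:
        return np.array([s.mean for s in self.subjects])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "mean_pci_per_l": [s.mean for s in self.subjects],
                "years_resident": [s.years_resident for s in self.subjects],
                "max_annual_pci_per_l": [
                    max(s.annual.values()) if s.annual else np.nan for s in self.subjects
                ],
            }
        )

    def annual_frame(self) -> pd.DataFrame:
        rows = [
            {"subject_id": s.subject_id, "year": y, "pci_per_l": v, "fraction": s.weights[y]}
            for s in self.subjects
            for y, v in sorted(s.annual.items())
        ]
        return pd.DataFrame(rows, columns=["subject_id", "year", "pci_per_l", "fraction"])


def compute_cohort_exposures(
    matrix: ExposureMatrix, subjects: Sequence[Subject]
) -> CohortExposures:
    out: list[SubjectExposure] = []
    excluded = 0
    for subj in subjects:
        exp = subject_exposure(matrix, subj)
        if exp is None:
            excluded += 1
            logger.info("subject %s has zero resident time; excluded", subj.subject_id)
        else:
            out.append(exp)
    return CohortExposures(subjects=out, n_excluded_no_residence=excluded)


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

def exceedance_count(
    cohort: CohortExposures, threshold: float, mode: str = "any_year"
) -> tuple[int, float]:
    """Subjects above a concentration threshold, as (count, fraction).

    ``any_year`` counts subjects with at least one annual value above the
    threshold; ``overall_mean`` counts subjects whose duration-weighted mean
    exceeds it.
    """
    if mode not in ("any_year", "overall_mean"):
        raise ValueError(f"mode must be 'any_year' or 'overall_mean', got {mode!r}")
    if mode == "any_year":
        count = sum(
            1 for s in cohort.subjects if any(v > threshold for v in s.annual.values())
        )
    else:
        count = sum(1 for s in cohort.subjects if s.mean > threshold)
    n = len(cohort.subjects)
    return count, (count / n if n else 0.0)


def cohort_summary(cohort: CohortExposures) -> dict[str, float]:
    """Summary statistics of subject mean exposures (pCi·L⁻¹).

    Geometric statistics are computed on the strictly positive means; the
    number skipped is reported.  ``max_annual`` is the largest single annual
    value any subject received.
    """
    means = cohort.means()
    if means.size == 0:
        raise ValueError("cohort has no subjects with resident time")
    pos = means[means > 0]
    n_skipped = int(means.size - pos.size)
    if n_skipped:
        logger.info("geometric statistics skip %d non-positive means", n_skipped)
    if pos.size:
        logs = np.log(pos)
        gm = float(np.exp(logs.mean()))
        gsd = float(np.exp(logs.std(ddof=1))) if pos.size > 1 else float("nan")
    else:
        gm, gsd = float("nan"), float("nan")
    max_annual = max(
        (max(s.annual.values()) for s in cohort.subjects if s.annual), default=float("nan")
    )
    return {
        "n": int(means.size),
        "arithmetic_mean": float(means.mean()),
        "arithmetic_sd": float(means.std(ddof=1)) if means.size > 1 else float("nan"),
        "geometric_mean": gm,
        "gsd": gsd,
        "median": float(np.median(means)),
        "p95": float(np.percentile(means, 95)),
        "p99": float(np.percentile(means, 99)),
        "max_annual": float(max_annual),
        "n_nonpositive_excluded": n_skipped,
    }


def sector_ranking(matrix: ExposureMatrix, grid: SectorGrid, k: int = 10) -> pd.DataFrame:
    """Top-``k`` sectors by mean annual concentration over the study years.

    Because the matrix factorizes into a spatial and a temporal part, the
    Maximum/Mean ratio is identical across sectors.
    """
    means = matrix.annual.mean(axis=1)
    maxima = matrix.annual.max(axis=1)
    df = pd.DataFrame(
        {
            "sector_id": matrix.sector_ids,
            "octet": [grid[s].octet for s in matrix.sector_ids],
            "distance_m": [grid[s].distance for s in matrix.sector_ids],
            "mean_pci_per_l": means,
            "max_pci_per_l": maxima,
        }
    )
    df = df.sort_values(
        ["mean_pci_per_l", "sector_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return df.head(k)


def population_and_footprint(
    subjects: Sequence[Subject], grid: SectorGrid, matrix: ExposureMatrix
) -> dict[str, pd.DataFrame]:
    """Population time series, decade×sector populations, and octet footprint.

    * ``population_by_year`` — subjects resident any month of each study year;
    * ``population_by_sector_decade`` — subjects resident in each sector
      during each decade;
    * ``octet_mean_exposure`` — the exposure footprint: mean over each
      octet's sectors of the sector mean annual concentration.
    """
    y0, y1 = int(matrix.years[0]), int(matrix.years[-1])
    years = list(range(y0, y1 + 1))
    pop_year = {y: 0 for y in years}
    decade_sector: dict[tuple[int, str], set[str]] = {}
    for subj in subjects:
        resident_years = set()
        for rec in subj.residences:
            for year in range(max(rec.start.year, y0), min(rec.end.year, y1) + 1):
                frac, _ = occupancy_fraction(rec, year)
                if frac > 0:
                    resident_years.add(year)
                    decade = (year // 10) * 10
                    decade_sector.setdefault((decade, rec.sector_id), set()).add(
                        subj.subject_id
                    )
        for year in resident_years:
            pop_year[year] += 1

    population_by_year = pd.DataFrame(
        {"year": years, "population": [pop_year[y] for y in years]}
    )
    rows = [
        {"decade": d, "sector_id": s, "population": len(ids)}
        for (d, s), ids in sorted(decade_sector.items())
    ]
    population_by_sector_decade = pd.DataFrame(
        rows, columns=["decade", "sector_id", "population"]
    )
    sector_mean = pd.DataFrame(
        {
            "sector_id": matrix.sector_ids,
            "octet": [grid[s].octet for s in matrix.sector_ids],
            "mean_pci_per_l": matrix.annual.mean(axis=1),
        }
    )
    octet_mean = (
        sector_mean.groupby("octet", sort=False)["mean_pci_per_l"]
        .mean()
        .reset_index()
        .rename(columns={"mean_pci_per_l": "mean_sector_pci_per_l"})
    )
    return {
        "population_by_year": population_by_year,
        "population_by_sector_decade": population_by_sector_decade,
        "octet_mean_exposure": octet_mean,
    }
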