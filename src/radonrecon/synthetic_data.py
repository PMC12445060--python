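"""Synthetic cohorts, meteorology, and end-to-end scenario bundles.

The real residential-history data are access-restricted and the historical
joint-frequency wind tables live in an out-of-print agency report, so this
module generates stand-ins with the *structural* statistics that are on the
public record:

* residence records at month resolution with the documented missingness
  rates (8.49% missing FROM month, 7.55% missing TO month, 0.49%/0.72%
  missing FROM/TO year) and the occasional pre-birth FROM date;
* arrival/departure months near-uniform with a mild June/July excess and a
  Feb/Mar/Nov/Dec deficit;
* monthly joint-frequency tables that satisfy both normalization
  constraints exactly, with prevailing winds from the NW/W/SW, extra mass in
  the calm (<2 m·s⁻¹) speed class, and calmer summers than winters.

Everything is driven by a single integer seed through named substreams, so
the same seed always produces byte-identical outputs and adding a new
generator never perturbs existing draws.  Each generator also emits the
pre-injection ground truth so the cleaning stage can be validated exactly.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dispersion import CalibrationParams, DispersionConfig, save_config
from .meteorology import OCTETS, JointFrequencyTable, write_met_tables
from .residential_history import DropDecision, ResidenceRecord, clean_record
from .sector_grid import SectorGrid, default_grid
from .source_term import EmissionTimeline


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named stream derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Relative weights of arrival/departure months (Jan..Dec): June/July excess,
#: Feb/Mar/Nov/Dec deficit, otherwise near-uniform.
MOVE_MONTH_WEIGHTS = (1.0, 0.8, 0.8, 1.0, 1.0, 1.3, 1.3, 1.1, 1.0, 1.0, 0.8, 0.8)

#: Residential density bias toward the historically populous sectors.
POPULOUS_SECTOR_WEIGHTS: Mapping[str, float] = {
    "B09": 8.0, "B03": 3.0, "H02": 3.0, "B18": 2.5, "H08": 2.0,
    "H27": 2.0, "B05": 2.0, "H22": 2.0, "B37": 1.5, "B36": 1.5,
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Missingness probabilities default to the documented per-residence rates;
    ``move_rate`` (per-year relocation probability) and the decade
    ``population_growth`` multipliers are plain modelling choices.
    """

    n_subjects: int = 500
    seed: int = 0
    move_rate: float = 0.07
    missing_from_month_p: float = 0.0849
    missing_to_month_p: float = 0.0755
    missing_from_year_p: float = 0.0049
    missing_to_year_p: float = 0.0072
    dob_before_residence_p: float = 0.03
    population_growth: tuple[float, ...] = (0.7, 0.95, 1.2, 1.15)  # 1950s..1980s

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for name in (
            "move_rate", "missing_from_month_p", "missing_to_month_p",
            "missing_from_year_p", "missing_to_year_p", "dob_before_residence_p",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def _sector_weights(grid: SectorGrid) -> np.ndarray:
    w = np.array([POPULOUS_SECTOR_WEIGHTS.get(sid, 1.0) for sid in grid.ids()])
    return w / w.sum()


def generate_cohort(
    spec: CohortSpec, grid: SectorGrid | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (dirty records, clean ground truth) for one synthetic cohort.

    The dirty frame has the raw-CSV columns (missing cells empty); the truth
    frame holds the cleaned intervals of the same records *before*
    missingness injection, one row per surviving residence.
    """
    grid = grid or default_grid()
    rng = substream(spec.seed, "cohort")
    miss_rng = substream(spec.seed, "cohort-missingness")
    sector_ids = grid.ids()
    sector_p = _sector_weights(grid)
    month_p = np.array(MOVE_MONTH_WEIGHTS) / sum(MOVE_MONTH_WEIGHTS)
    decade_p = np.array(spec.population_growth, dtype=float)
    decade_p = decade_p / decade_p.sum()

    dirty_rows: list[dict] = []
    truth_rows: list[dict] = []
    dobs: dict[str, date] = {}
    for i in range(spec.n_subjects):
        sid = f"S{i:06d}"
        dob_year = int(rng.integers(1915, 1975))
        dob = date(dob_year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        dobs[sid] = dob

        decade = 1950 + 10 * int(rng.choice(4, p=decade_p))
        entry_year = max(decade + int(rng.integers(0, 10)), dob_year)
        entry_year = min(entry_year, 1988)
        cur = entry_year * 12 + int(rng.choice(12, p=month_p))  # flat month index

        records: list[ResidenceRecord] = []
        for _ in range(6):  # at most a handful of in-area addresses
            duration = int(rng.geometric(min(max(spec.move_rate, 1e-9) / 12.0, 1.0)))
            end = cur + max(duration, 1) - 1
            sector = str(rng.choice(sector_ids, p=sector_p))
            records.append(
                ResidenceRecord(
                    subject_id=sid,
                    sector_id=sector,
                    from_year=cur // 12,
                    from_month=cur % 12 + 1,
                    to_year=end // 12,
                    to_month=end % 12 + 1,
                )
            )
            if end >= 1989 * 12 or rng.random() < 0.35:
                break  # left the study area or past the window
            cur = end + 1

        for k, rec in enumerate(records):
            truth = clean_record(rec, dob, grid=grid)
            if not isinstance(truth, DropDecision):
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "sector_id": truth.sector_id,
                        "start": truth.start.isoformat(),
                        "end": truth.end.isoformat(),
                    }
                )
            # missingness / anomaly injection
            from_year = rec.from_year
            from_month = rec.from_month
            to_year = rec.to_year
            to_month = rec.to_month
            if k == 0 and miss_rng.random() < spec.dob_before_residence_p:
                # family moved in before the subject was born
                shift = int(miss_rng.integers(6, 48))
                pre = dob.year * 12 + dob.month - 1 - shift
                from_year, from_month = pre // 12, pre % 12 + 1
            if miss_rng.random() < spec.missing_from_month_p:
                from_month = None
            if miss_rng.random() < spec.missing_to_month_p:
                to_month = None
            if miss_rng.random() < spec.missing_from_year_p:
                from_year = None
            if miss_rng.random() < spec.missing_to_year_p:
                to_year = None
            dirty_rows.append(
                {
                    "subject_id": sid,
                    "dob": dob.isoformat(),
                    "sector_id": rec.sector_id,
                    "from_year": from_year,
                    "from_month": from_month,
                    "to_year": to_year,
                    "to_month": to_month,
                }
            )
    dirty = pd.DataFrame(
        dirty_rows,
        columns=["subject_id", "dob", "sector_id", "from_year", "from_month", "to_year", "to_month"],
    )
    truth = pd.DataFrame(truth_rows, columns=["subject_id", "sector_id", "start", "end"])
    return dirty, truth


# ---------------------------------------------------------------------------
# Meteorology generation
# ---------------------------------------------------------------------------

DEFAULT_PREVAILING_OCTETS: Mapping[str, float] = {
    "N": 1.0, "NE": 0.8, "E": 0.8, "SE": 0.9,
    "S": 1.0, "SW": 1.8, "W": 2.2, "NW": 2.0,
}


@dataclass(frozen=True)
class MetSpec:
    """Parameters of the synthetic joint-frequency table generator.

    ``calm_bias`` multiplies the weight of the calm (<2 m·s⁻¹) speed class;
    ``seasonal_amplitude`` tilts the speed distribution toward faster winds
    in winter and calmer winds in summer; ``noise`` adds multiplicative
    jitter before the exact renormalization.
    """

    seed: int = 0
    prevailing_octets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVAILING_OCTETS)
    )
    calm_bias: float = 2.0
    seasonal_amplitude: float = 0.3
    noise: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ValueError("seasonal_amplitude must be in [0, 1)")
        if self.calm_bias <= 0 or self.noise < 0:
            raise ValueError("calm_bias must be positive and noise non-negative")
        if set(self.prevailing_octets) != set(OCTETS):
            raise ValueError("prevailing_octets must weight all 8 octets")


def uniform_met_spec(seed: int = 0) -> MetSpec:
    """Fully symmetric spec: flat directions and speeds, no jitter."""
    return MetSpec(
        seed=seed,
        prevailing_octets={o: 1.0 for o in OCTETS},
        calm_bias=1.0,
        seasonal_amplitude=0.0,
        noise=0.0,
    )


_SPEED_BASE = np.array([0.30, 0.25, 0.20, 0.12, 0.08, 0.05])
_STABILITY_BASE = np.array([0.10, 0.12, 0.16, 0.30, 0.17, 0.15])


def generate_met(spec: MetSpec) -> list[JointFrequencyTable]:
    """Twelve monthly joint-frequency tables satisfying both normalizations."""
    rng = substream(spec.seed, "met")
    # direction-16 weights: octet weight at the octet direction, flanking
    # average at the intermediate directions
    octet_w = np.array([spec.prevailing_octets[o] for o in OCTETS])
    dir_w = np.empty(16)
    for i in range(8):
        dir_w[2 * i] = octet_w[i]
        dir_w[2 * i + 1] = 0.5 * (octet_w[i] + octet_w[(i + 1) % 8])

    if spec.calm_bias == 1.0:
        speed_base = np.full(6, 1.0 / 6.0)
    else:
        speed_base = _SPEED_BASE.copy()
        speed_base[0] *= spec.calm_bias
        speed_base /= speed_base.sum()
    tilt = np.linspace(-1.0, 1.0, 6)

    tables = []
    for month in range(1, 13):
        season = np.cos(2.0 * np.pi * (month - 1) / 12.0)  # +1 in Jan, −1 in Jul
        speed_w = speed_base * (1.0 + spec.seasonal_amplitude * season * tilt)
        speed_w = np.clip(speed_w, 1e-12, None)
        h = _STABILITY_BASE * np.clip(
            1.0 + spec.noise * rng.standard_normal(6), 1e-6, None
        )
        h /= h.sum()
        g = dir_w[None, :, None] * speed_w[None, None, :] * np.clip(
            1.0 + spec.noise * rng.standard_normal((6, 16, 6)), 1e-9, None
        )
        g /= g.sum(axis=(1, 2), keepdims=True)
        tables.append(JointFrequencyTable(month=month, class_freq=h, cond_freq=g))
    return tables


# ---------------------------------------------------------------------------
# Scenario bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioPaths:
    root: Path
    sectors: Path
    met_conditional: Path
    met_class: Path
    emissions: Path
    residences: Path
    truth: Path
    config: Path


def generate_scenario(
    out_dir: str | Path,
    cohort_spec: CohortSpec | None = None,
    met_spec: MetSpec | None = None,
    grid: SectorGrid | None = None,
    timeline: EmissionTimeline | None = None,
    calib: CalibrationParams | None = None,
    config: DispersionConfig | None = None,
) -> ScenarioPaths:
    """Write a complete input bundle that the ``reconstruct`` CLI consumes."""
    cohort_spec = cohort_spec or CohortSpec()
    met_spec = met_spec or MetSpec(seed=cohort_spec.seed)
    grid = grid or default_grid()
    timeline = timeline or EmissionTimeline.default()
    calib = calib or CalibrationParams()
    config = config or DispersionConfig()

    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    paths = ScenarioPaths(
        root=root,
        sectors=root / "sectors.csv",
        met_conditional=root / "met_conditional.csv",
        met_class=root / "met_class.csv",
        emissions=root / "emissions.csv",
        residences=root / "residences.csv",
        truth=root / "residences_truth.csv",
        config=root / "config.yaml",
    )
    grid.to_csv(paths.sectors)
    write_met_tables(generate_met(met_spec), paths.met_conditional, paths.met_class)
    timeline.to_csv(paths.emissions)
    dirty, truth = generate_cohort(cohort_spec, grid=grid)
    dirty.to_csv(paths.residences, index=False)
    truth.to_csv(paths.truth, index=False)
    save_config(paths.config, calib, config)
    return paths
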