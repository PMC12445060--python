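"""Monthly joint-frequency wind tables and wind-ratio roses.

A joint-frequency table for one calendar month cross-classifies wind
observations by Pasquill–Gifford stability class (A, most unstable, through
F, most stable), 16 compass directions (the direction the wind blows *from*)
and 6 speed classes with midpoints 1, 3, 5, 7, 9 and 11 m·s⁻¹ (the open
">10 m·s⁻¹" class is represented by 11).  The table is stored factored:

* ``class_freq``  — h_s, frequency of each stability class, summing to 1 per
  month;
* ``cond_freq``   — g_{q,d|s}, frequency of each (direction, speed) cell
  conditional on the stability class, summing to 1 over all 96 cells within
  each class.

The stability-adjusted joint frequency is f_{q,d,s} = h_s · g_{q,d|s}.
Dividing each cell by its class-midpoint speed and summing over speeds gives
the *wind ratio* (s·m⁻¹) per direction and stability class — the quantity a
sector-averaged plume model multiplies by the diffusion function.  Roses are
consolidated from 16 directions to the octet (8 directions) by splitting
every intermediate direction half-and-half between its flanking octet
directions, which conserves the total.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DIRECTIONS_16 = (
    "N", "NNE", "NE", "ENE", "E", "ESE", "SE", "SSE",
    "S", "SSW", "SW", "WSW", "W", "WNW", "NW", "NNW",
)
OCTETS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
STABILITY_CLASSES = ("A", "B", "C", "D", "E", "F")
SPEED_MIDPOINTS = (1.0, 3.0, 5.0, 7.0, 9.0, 11.0)

_NORM_TOL = 1e-9


class MetValidationError(ValueError):
    """A joint-frequency table violates a normalization or sign constraint."""


def _stab_index(s: str | int) -> int:
    if isinstance(s, str):
        return STABILITY_CLASSES.index(s)
    return int(s)


def _dir16_index(d: str | int) -> int:
    if isinstance(d, str):
        return DIRECTIONS_16.index(d)
    return int(d)


@dataclass
class JointFrequencyTable:
    """Factored monthly joint-frequency table.

    ``class_freq`` has shape (6,) over stability classes A..F; ``cond_freq``
    has shape (6, 16, 6) over (stability, direction16, speed class).
    """

    month: int
    class_freq: np.ndarray
    cond_freq: np.ndarray
    speed_midpoints: np.ndarray = field(
        default_factory=lambda: np.array(SPEED_MIDPOINTS)
    )

    def __post_init__(self) -> None:
        self.class_freq = np.asarray(self.class_freq, dtype=float)
        self.cond_freq = np.asarray(self.cond_freq, dtype=float)
        self.speed_midpoints = np.asarray(self.speed_midpoints, dtype=float)
        if not 1 <= self.month <= 12:
            raise MetValidationError(f"month must be 1..12, got {self.month}")
        if self.class_freq.shape != (6,) or self.cond_freq.shape != (6, 16, 6):
            raise MetValidationError(
                "class_freq must have shape (6,) and cond_freq (6, 16, 6)"
            )
        self.validate()

    def validate(self) -> None:
        if (self.class_freq < 0).any() or (self.cond_freq < 0).any():
            raise MetValidationError("frequencies must be non-negative")
        if abs(self.class_freq.sum() - 1.0) > _NORM_TOL:
            raise MetValidationError(
                f"stability-class frequencies sum to {self.class_freq.sum()!r}, not 1"
            )
        per_class = self.cond_freq.sum(axis=(1, 2))
        bad = np.abs(per_class - 1.0) > _NORM_TOL
        if bad.any():
            labels = [STABILITY_CLASSES[i] for i in np.nonzero(bad)[0]]
            raise MetValidationError(
                f"conditional frequencies do not sum to 1 within class(es) {labels}"
            )
        if (self.speed_midpoints <= 0).any():
            raise MetValidationError("speed midpoints must be positive")

    def joint(self) -> np.ndarray:
        """Stability-adjusted joint frequencies f_{q,d,s}, shape (6, 16, 6)."""
        return self.class_freq[:, None, None] * self.cond_freq


def stability_adjusted_frequency(
    table: JointFrequencyTable, s: str | int, d: str | int, q: int
) -> float:
    """f_{q,d,s} = h_s · g_{q,d|s} for one cell (``q`` is the 1-based speed class)."""
    si, di = _stab_index(s), _dir16_index(d)
    if not 1 <= int(q) <= 6:
        raise ValueError(f"speed class must be 1..6, got {q}")
    return float(table.class_freq[si] * table.cond_freq[si, di, int(q) - 1])


@dataclass(frozen=True)
class WindRatioRose:
    """Per-direction wind ratios (s·m⁻¹), broken down by stability class.

    ``by_stability`` has shape (6, n_directions); the plain rose is its sum
    over the stability axis.
    """

    directions: tuple[str, ...]
    by_stability: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.by_stability, dtype=float)
        object.__setattr__(self, "by_stability", arr)
        if arr.shape != (6, len(self.directions)):
            raise ValueError("by_stability must have shape (6, n_directions)")
        if (arr < 0).any():
            raise ValueError("wind ratios must be non-negative")

    @property
    def ratios(self) -> np.ndarray:
        return self.by_stability.sum(axis=0)

    def ratio(self, direction: str) -> float:
        return float(self.ratios[self.directions.index(direction)])

    def stability_ratios(self, direction: str) -> np.ndarray:
        """Wind ratios for one direction, one entry per stability class A..F."""
        return self.by_stability[:, self.directions.index(direction)].copy()

    def total(self) -> float:
        return float(self.ratios.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.ratios, index=list(self.directions), name="wind_ratio")


def wind_ratio_rose(table: JointFrequencyTable) -> WindRatioRose:
    """16-direction wind-ratio rose: ratio_d = Σ_s Σ_q f_{q,d,s} / u_q."""
    by_stab = (table.joint() / table.speed_midpoints[None, None, :]).sum(axis=2)
    return WindRatioRose(directions=DIRECTIONS_16, by_stability=by_stab)


def consolidate_16_to_8(rose16: WindRatioRose) -> WindRatioRose:
    """Fold intermediate directions half-and-half into the flanking octets.

    e.g. N ← N + ½·NNW + ½·NNE.  The total over directions is conserved.
    """
    if rose16.directions != DIRECTIONS_16:
        raise ValueError("expected a 16-direction rose")
    r = rose16.by_stability
    out = np.empty((6, 8))
    for i in range(8):
        main = 2 * i
        out[:, i] = r[:, main] + 0.5 * r[:, main - 1] + 0.5 * r[:, (main + 1) % 16]
    return WindRatioRose(directions=OCTETS, by_stability=out)


def annualize(monthly_roses: Sequence[WindRatioRose]) -> WindRatioRose:
    """Per-direction arithmetic mean over the 12 monthly roses."""
    if len(monthly_roses) != 12:
        raise ValueError(f"need exactly 12 monthly roses, got {len(monthly_roses)}")
    dirs = monthly_roses[0].directions
    if any(r.directions != dirs for r in monthly_roses):
        raise ValueError("monthly roses must share a direction set")
    mean = np.mean([r.by_stability for r in monthly_roses], axis=0)
    return WindRatioRose(directions=dirs, by_stability=mean)


def weighted_wind_velocity(table: JointFrequencyTable) -> tuple[pd.Series, float]:
    """Frequency-weighted wind velocity ("wind power"), m·s⁻¹.

    Per direction: Σ_s Σ_q f_{q,d,s} · u_q; overall is the sum over the 16
    directions.
    """
    per_dir = (table.joint() * table.speed_midpoints[None, None, :]).sum(axis=(0, 2))
    series = pd.Series(per_dir, index=list(DIRECTIONS_16), name="weighted_velocity")
    return series, float(per_dir.sum())


# ---------------------------------------------------------------------------
# CSV interface: long-format conditional frequencies + class-frequency table
# ---------------------------------------------------------------------------

def write_met_tables(
    tables: Sequence[JointFrequencyTable],
    cond_path: str | Path,
    class_path: str | Path,
) -> None:
    cond_rows = []
    class_rows = []
    for t in tables:
        for si, s in enumerate(STABILITY_CLASSES):
            class_rows.append({"month": t.month, "stability": s, "h": t.class_freq[si]})
            for di, d in enumerate(DIRECTIONS_16):
                for qi in range(6):
                    cond_rows.append(
                        {
                            "month": t.month,
                            "stability": s,
                            "direction16": d,
                            "speed_class": qi + 1,
                            "frequency": t.cond_freq[si, di, qi],
                        }
                    )
    pd.DataFrame(cond_rows).to_csv(cond_path, index=False)
    pd.DataFrame(class_rows).to_csv(class_path, index=False)


def load_met_tables(
    cond_path: str | Path, class_path: str | Path
) -> list[JointFrequencyTable]:
    """Read the 12 monthly tables; validation errors name the offending month."""
    cond = pd.read_csv(cond_path, comment="#")
    cls = pd.read_csv(class_path, comment="#")
    required = {"month", "stability", "direction16", "speed_class", "frequency"}
    if not required.issubset(cond.columns):
        raise MetValidationError(f"met CSV must have columns {sorted(required)}")
    if not {"month", "stability", "h"}.issubset(cls.columns):
        raise MetValidationError("class-frequency CSV must have columns month, stability, h")
    tables = []
    for month in range(1, 13):
        sub = cond[cond["month"] == month]
        subc = cls[cls["month"] == month]
        if sub.empty or subc.empty:
            raise MetValidationError(f"month {month} missing from met tables")
        h = np.zeros(6)
        for row in subc.itertuples(index=False):
            h[_stab_index(row.stability)] = row.h
        g = np.zeros((6, 16, 6))
        si = sub["stability"].map(_stab_index).to_numpy()
        di = sub["direction16"].map(_dir16_index).to_numpy()
        qi = sub["speed_class"].to_numpy(dtype=int) - 1
        if (qi < 0).any() or (qi > 5).any():
            raise MetValidationError(f"month {month}: speed_class outside 1..6")
        g[si, di, qi] = sub["frequency"].to_numpy(dtype=float)
        try:
            tables.append(JointFrequencyTable(month=month, class_freq=h, cond_freq=g))
        except MetValidationError as exc:
            raise MetValidationError(f"month {month}: {exc}") from exc
    return tables


def scale_speeds(table: JointFrequencyTable, k: float) -> JointFrequencyTable:
    """Return a copy with all speed-class midpoints multiplied by ``k``."""
    if k <= 0:
        raise ValueError("speed scale factor must be positive")
    return replace(table, speed_midpoints=table.speed_midpoints * k)
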