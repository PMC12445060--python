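"""Polar study grid: octet directions × concentric mile-interval rings.

The exposure domain is a 5-mile (8 km) circle around the source split into
100 sectors of roughly one square mile.  Each sector is identified by an
opaque id (the historical ids use ``B``/``H`` prefixes), one of the eight
octet directions, and a ring number 1–5; the receptor distance is the
ring midpoint rounded the way the historical tables print it, 1600·ring
metres.  Wind directions name where the wind blows *from*, so the wind that
exposes a sector comes from the reciprocal octet (180° away).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .meteorology import OCTETS

#: Ring spacing in metres (1 mile, rounded as in the historical tables).
RING_SPACING_M = 1600.0
N_RINGS = 5

_RECIPROCAL = {o: OCTETS[(i + 4) % 8] for i, o in enumerate(OCTETS)}


def reciprocal_direction(octet: str) -> str:
    """The octet 180° from ``octet`` (N↔S, NE↔SW, E↔W, SE↔NW)."""
    if octet not in _RECIPROCAL:
        raise ValueError(f"unknown octet {octet!r}")
    return _RECIPROCAL[octet]


@dataclass(frozen=True)
class Sector:
    id: str
    octet: str
    ring: int

    def __post_init__(self) -> None:
        if self.octet not in OCTETS:
            raise ValueError(f"sector {self.id}: unknown octet {self.octet!r}")
        if not 1 <= self.ring <= N_RINGS:
            raise ValueError(f"sector {self.id}: ring must be 1..{N_RINGS}")

    @property
    def distance(self) -> float:
        """Receptor distance from the source centre, metres."""
        return RING_SPACING_M * self.ring


class SectorGrid:
    """Lookup table sector id → :class:`Sector`."""

    def __init__(self, sectors: Iterable[Sector]):
        self.sectors: dict[str, Sector] = {}
        for s in sectors:
            if s.id in self.sectors:
                raise ValueError(f"duplicate sector id {s.id!r}")
            self.sectors[s.id] = s

    def __len__(self) -> int:
        return len(self.sectors)

    def __contains__(self, sector_id: str) -> bool:
        return sector_id in self.sectors

    def __getitem__(self, sector_id: str) -> Sector:
        return self.sectors[sector_id]

    def ids(self) -> list[str]:
        return list(self.sectors)

    def receptor_geometry(self, sector_id: str) -> tuple[str, float]:
        """(octet, distance in metres) of a sector; unknown ids are rejected."""
        if sector_id not in self.sectors:
            raise KeyError(f"unknown sector id {sector_id!r}")
        s = self.sectors[sector_id]
        return s.octet, s.distance

    def counts(self) -> pd.DataFrame:
        """Sector counts per (octet, ring)."""
        df = self.to_frame()
        return df.groupby(["octet", "ring"]).size().rename("n_sectors").reset_index()

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.sectors.values()],
                "octet": [s.octet for s in self.sectors.values()],
                "ring": [s.ring for s in self.sectors.values()],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SectorGrid":
        return cls(
            Sector(id=str(r.id), octet=str(r.octet), ring=int(r.ring))
            for r in df.itertuples(index=False)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SectorGrid":
        return cls.from_frame(pd.read_csv(path, comment="#"))


# Sector ids whose geometry is pinned by the historical summary tables
# (octet and, where printed, ring).  The full id→geometry mapping was never
# published; remaining ids are filled deterministically below.
_KNOWN_SECTORS: Mapping[str, tuple[str, int]] = {
    "B02": ("N", 1),
    "B03": ("NE", 1),
    "H01": ("E", 1),
    "H02": ("SE", 1),
    "H05": ("W", 1),
    "B08": ("NE", 2),
    "B09": ("NE", 2),
    "H07": ("SE", 2),
    "B16": ("NE", 3),
    "B17": ("NE", 3),
    # octet known from population tables; ring assignment is our convention
    "B05": ("NW", 1),
    "H22": ("SW", 1),
    "B37": ("N", 2),
    "H26": ("E", 2),
    "B36": ("NW", 2),
    "B18": ("E", 3),
    "H08": ("SE", 3),
    "H28": ("SE", 3),
    "H17": ("SE", 4),
    "H27": ("SE", 4),
    "H41": ("SE", 5),
}

# Sector quota per (ring): per-octet base count, plus extras for the octets
# that the populous side of the domain (NE/E/SE/SW) historically carried.
_RING_BASE = {1: 1, 2: 2, 3: 3, 4: 3, 5: 3}
_RING_EXTRA_OCTETS = {5: ("NE", "E", "SE", "SW")}


def default_grid() -> SectorGrid:
    """Deterministic 100-sector grid over 5 rings and 8 octets.

    Reproduces every (id, octet, distance) triple printed in the historical
    exposure and population tables and fills the remaining quota with
    synthetic ids.
    """
    quota: dict[tuple[str, int], int] = {}
    for ring, base in _RING_BASE.items():
        for octet in OCTETS:
            quota[(octet, ring)] = base
        for octet in _RING_EXTRA_OCTETS.get(ring, ()):
            quota[(octet, ring)] += 1
    assert sum(quota.values()) == 100

    sectors: list[Sector] = []
    filled: dict[tuple[str, int], int] = {k: 0 for k in quota}
    for sid, (octet, ring) in _KNOWN_SECTORS.items():
        sectors.append(Sector(id=sid, octet=octet, ring=ring))
        filled[(octet, ring)] += 1
        if filled[(octet, ring)] > quota[(octet, ring)]:
            raise AssertionError(f"quota exceeded for {(octet, ring)}")

    counter = 60  # synthetic filler ids start clear of the historical numbers
    prefixes = ("B", "H")
    for ring in sorted(_RING_BASE):
        for octet in OCTETS:
            while filled[(octet, ring)] < quota[(octet, ring)]:
                sid = f"{prefixes[counter % 2]}{counter // 2 + 60:02d}"
                counter += 1
                sectors.append(Sector(id=sid, octet=octet, ring=ring))
                filled[(octet, ring)] += 1
    return SectorGrid(sectors)
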