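"""Sector-averaged ground-level Gaussian plume model for an area source.

The long-term average concentration at a receptor in octet ``d`` at downwind
distance ``x`` during period ``t`` is

    X_{d,t}(x) = K·(x/ρ)^c · Σ_s R_s(d*) · D_s(x) · Q_t · φ_resid · φ_met

where ``K·(x/ρ)^c`` is an empirical calibration factor anchored at the source
radius ρ, ``R_s(d*)`` is the wind ratio (s·m⁻¹) for stability class ``s`` and
the wind direction *reciprocal* to the receptor octet, ``D_s(x)`` is the
sector-averaged diffusion function (m⁻²), and ``Q_t`` the release rate
converted from Ci·y⁻¹ to Ci·s⁻¹.  The residual and meteorological adjustment
factors φ are lognormal random variables with geometric mean 1; in this
discrete (non-stochastic) model they are fixed at 1.

The vertical dispersion length σ_z uses the Briggs open-country (rural)
interpolation formulas per stability class; lateral σ_y coefficients are also
provided so that an explicit disk-source quadrature can cross-check the
sector-averaged closed form.  The source (two adjacent storage silos) is
treated as a single ground-level circular area source of radius ρ = 50 m and,
for receptors beyond a floor of 2ρ, is evaluated as a sector-averaged point
source at the receptor distance.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .meteorology import STABILITY_CLASSES
from .source_term import SECONDS_PER_YEAR

#: pCi per Ci (1e12) divided by litres per cubic metre (1e3).
PCI_PER_L_FROM_CI_PER_M3 = 1.0e9


@dataclass(frozen=True)
class CalibrationParams:
    """Empirical calibration of the plume model against monitoring data.

    ln K is N(lnK_mean, lnK_sd²) and the distance exponent c is
    N(c_mean, c_sd²); the discrete model uses the central values only.
    ``rho`` is the equivalent source radius in metres.
    """

    lnK_mean: float = -0.44
    lnK_sd: float = 0.69
    c_mean: float = 0.19
    c_sd: float = 0.32
    rho: float = 50.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("source radius rho must be positive")
        if self.lnK_sd <= 0 or self.c_sd <= 0:
            raise ValueError("standard deviations must be positive")


def calibration_factor(params: CalibrationParams, x: float | np.ndarray) -> float | np.ndarray:
    """Central-value calibration factor exp(lnK)·(x/ρ)^c at distance ``x`` (m)."""
    x = np.asarray(x, dtype=float)
    if (x < params.rho).any():
        raise ValueError(
            f"receptor distance {x} is inside the source footprint (rho={params.rho} m)"
        )
    out = math.exp(params.lnK_mean) * (x / params.rho) ** params.c_mean
    return float(out) if out.ndim == 0 else out


# Briggs open-country sigma coefficients: sigma = a·x / (1 + b·x)^p
_BRIGGS_RURAL_SIGMA_Z: dict[str, tuple[float, float, float]] = {
    "A": (0.20, 0.0, 0.0),
    "B": (0.12, 0.0, 0.0),
    "C": (0.08, 0.0002, 0.5),
    "D": (0.06, 0.0015, 0.5),
    "E": (0.03, 0.0003, 1.0),
    "F": (0.016, 0.0003, 1.0),
}
_BRIGGS_RURAL_SIGMA_Y: dict[str, tuple[float, float, float]] = {
    "A": (0.22, 0.0001, 0.5),
    "B": (0.16, 0.0001, 0.5),
    "C": (0.11, 0.0001, 0.5),
    "D": (0.08, 0.0001, 0.5),
    "E": (0.06, 0.0001, 0.5),
    "F": (0.04, 0.0001, 0.5),
}

SIGMA_Z_SCHEMES: dict[str, dict[str, tuple[float, float, float]]] = {
    "briggs-rural": _BRIGGS_RURAL_SIGMA_Z,
}


@dataclass(frozen=True)
class DispersionConfig:
    """Numerical configuration of the diffusion machinery."""

    sigma_z_scheme: str = "briggs-rural"
    n_sectors: int = 8
    min_distance: float = 100.0  # 2·rho evaluation floor, metres
    seconds_per_year: float = SECONDS_PER_YEAR
    phi_resid: float = 1.0
    phi_met: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_z_scheme not in SIGMA_Z_SCHEMES:
            raise ValueError(
                f"unknown sigma_z scheme {self.sigma_z_scheme!r}; "
                f"available: {sorted(SIGMA_Z_SCHEMES)}"
            )
        if self.n_sectors <= 0 or self.min_distance <= 0:
            raise ValueError("n_sectors and min_distance must be positive")


def _sigma(coeffs: tuple[float, float, float], x: np.ndarray) -> np.ndarray:
    a, b, p = coeffs
    if b == 0.0:
        return a * x
    return a * x / (1.0 + b * x) ** p


def sigma_z(config: DispersionConfig, s: str, x: float | np.ndarray) -> float | np.ndarray:
    """Vertical dispersion length σ_z (m) for stability class ``s`` at ``x`` (m)."""
    if s not in STABILITY_CLASSES:
        raise ValueError(f"unknown stability class {s!r}")
    x = np.asarray(x, dtype=float)
    if (x < config.min_distance).any():
        raise ValueError(f"distance {x} below evaluation floor {config.min_distance} m")
    out = _sigma(SIGMA_Z_SCHEMES[config.sigma_z_scheme][s], x)
    return float(out) if out.ndim == 0 else out


def sigma_y(s: str, x: float | np.ndarray) -> float | np.ndarray:
    """Lateral dispersion length σ_y (m), Briggs open-country.

    Not used by the sector-averaged closed form (the lateral profile is
    spread uniformly over the sector); provided for explicit plume
    quadrature cross-checks.
    """
    if s not in STABILITY_CLASSES:
        raise ValueError(f"unknown stability class {s!r}")
    x = np.asarray(x, dtype=float)
    out = _sigma(_BRIGGS_RURAL_SIGMA_Y[s], x)
    return float(out) if out.ndim == 0 else out


def diffusion(config: DispersionConfig, s: str, x: float | np.ndarray) -> float | np.ndarray:
    """Sector-averaged ground-level diffusion function D_s(x), m⁻².

    D_s(x) = √(2/π) / (σ_z(s, x) · (2πx / n_sectors)): the crosswind-integrated
    ground-level Gaussian profile spread uniformly over the sector arc.
    """
    x = np.asarray(x, dtype=float)
    sz = np.asarray(sigma_z(config, s, x), dtype=float)
    arc = 2.0 * math.pi * x / config.n_sectors
    out = math.sqrt(2.0 / math.pi) / (sz * arc)
    return float(out) if out.ndim == 0 else out


def diffusion_matrix(config: DispersionConfig, x: Sequence[float]) -> np.ndarray:
    """D_s(x) for all six stability classes: shape (6, len(x))."""
    x = np.asarray(x, dtype=float)
    return np.vstack([diffusion(config, s, x) for s in STABILITY_CLASSES])


@dataclass(frozen=True)
class ConcentrationResult:
    """Ground-level Rn concentration at one receptor and period."""

    value: float  # pCi·L⁻¹
    by_stability: tuple[float, ...]  # per stability class A..F, pCi·L⁻¹
    direction: str | None = None
    distance: float | None = None
    period: object | None = None


def concentration(
    calib: CalibrationParams,
    config: DispersionConfig,
    wind_ratios: Sequence[float],
    Q: float,
    x: float,
    direction: str | None = None,
    period: object | None = None,
) -> ConcentrationResult:
    """Concentration (pCi·L⁻¹) from per-stability wind ratios and source rate.

    ``wind_ratios`` are the six per-stability wind ratios R_s (s·m⁻¹) for the
    wind direction reciprocal to the receptor octet; ``Q`` is the release rate
    in Ci·y⁻¹ and ``x`` the receptor distance in metres.
    """
    R = np.asarray(wind_ratios, dtype=float)
    if R.shape != (6,):
        raise ValueError("wind_ratios must give one value per stability class A..F")
    if (R < 0).any():
        raise ValueError("wind ratios must be non-negative")
    if Q < 0:
        raise ValueError("source rate Q must be non-negative")
    if x < calib.rho:
        raise ValueError(f"receptor distance {x} m is inside the source (rho={calib.rho})")
    k = calibration_factor(calib, x)
    D = np.array([diffusion(config, s, x) for s in STABILITY_CLASSES])
    q_per_s = Q / config.seconds_per_year
    per_stab = (
        k * R * D * q_per_s * config.phi_resid * config.phi_met * PCI_PER_L_FROM_CI_PER_M3
    )
    return ConcentrationResult(
        value=float(per_stab.sum()),
        by_stability=tuple(float(v) for v in per_stab),
        direction=direction,
        distance=x,
        period=period,
    )


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> tuple[CalibrationParams, DispersionConfig]:
    """Read calibration + dispersion settings from a YAML mapping.

    Missing keys fall back to the defaults of the two dataclasses.
    """
    raw: Mapping = yaml.safe_load(Path(path).read_text()) or {}
    calib_keys = {"lnK_mean", "lnK_sd", "c_mean", "c_sd", "rho"}
    disp_keys = {
        "sigma_z_scheme", "n_sectors", "min_distance",
        "seconds_per_year", "phi_resid", "phi_met",
    }
    unknown = set(raw) - calib_keys - disp_keys
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    calib = CalibrationParams(**{k: raw[k] for k in calib_keys & set(raw)})
    config = DispersionConfig(**{k: raw[k] for k in disp_keys & set(raw)})
    return calib, config


def save_config(
    path: str | Path, calib: CalibrationParams, config: DispersionConfig
) -> None:
    data = {
        "lnK_mean": calib.lnK_mean,
        "lnK_sd": calib.lnK_sd,
        "c_mean": calib.c_mean,
        "c_sd": calib.c_sd,
        "rho": calib.rho,
        "sigma_z_scheme": config.sigma_z_scheme,
        "n_sectors": config.n_sectors,
        "min_distance": config.min_distance,
        "seconds_per_year": config.seconds_per_year,
        "phi_resid": config.phi_resid,
        "phi_met": config.phi_met,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(calib: CalibrationParams, config: DispersionConfig) -> str:
    """Short stable digest of the numerical configuration, for output headers."""
    text = repr((calib, config)).encode()
    return hashlib.sha1(text).hexdigest()[:12]
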