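"""Synthetic observation tables with the structure the retrieval assumes.

The generator draws biomass, soil moisture and incidence angle uniformly
over configurable ranges (defaults mirror the calibration dataset's spans),
pushes them through the Water Cloud Model forward operator for HH and HV,
multiplies by unit-mean lognormal noise (speckle-like: multiplicative,
keeps backscatter positive), and derives NDVI by inverting a configured
vegetation-index model plus small additive noise.  Returning the generating
truth alongside the table enables parameter- and state-recovery tests at
arbitrary sample size and noise level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .datasets import ObservationRecord, ObservationTable
from .optical import OpticalModel
from .wcm import WCMCoefficients, wcm_forward

__all__ = ["SyntheticConfig", "generate", "DEFAULT_COEFS_HH", "DEFAULT_COEFS_HV"]

#: Plausible C-band corn coefficients: HH soil-dominated, HV vegetation-
#: dominated, so the two channels are complementary and the dual-pol system
#: has a unique in-domain solution; backscatter stays positive with
#: magnitudes like field data (HH ~0.08-0.26, HV ~0.004-0.06).
DEFAULT_COEFS_HH = WCMCoefficients(
    a=0.08, b=0.10, c=0.60, d=0.06, e1=0.30, e2=1.00, polarization="HH"
)
DEFAULT_COEFS_HV = WCMCoefficients(
    a=0.020, b=0.60, c=0.03, d=0.003, e1=0.60, e2=0.50, polarization="HV"
)

#: Exponential NDVI-biomass curve close to the packaged dataset's fit, with
#: coefficients keeping NDVI inside [-1, 1] over the default biomass span.
DEFAULT_OPTICAL_TRUE = OpticalModel(form="NDVI_EXP", a=4.5, b=-5.0)

MIN_POINTS = 6


@dataclass
class SyntheticConfig:
    """Generating conditions for one synthetic observation table."""

    n_points: int = 23
    biomass_range: tuple[float, float] = (0.04, 7.1)          # wet, kg m^-2
    soil_moisture_range: tuple[float, float] = (0.039, 0.379)  # m^3 m^-3
    incidence_range: tuple[float, float] = (21.025, 31.9592)   # degrees
    true_coefs_hh: WCMCoefficients = DEFAULT_COEFS_HH
    true_coefs_hv: WCMCoefficients = DEFAULT_COEFS_HV
    noise_cv: float = 0.05          # CV of multiplicative backscatter noise
    optical_true: OpticalModel = DEFAULT_OPTICAL_TRUE
    ndvi_noise_sd: float = 0.02
    dry_wet_ratio: float = 0.125    # dry biomass as a fraction of wet
    seed: int = 0

    def validate(self) -> None:
        if self.n_points < MIN_POINTS:
            raise ValueError(f"n_points must be >= {MIN_POINTS}, got {self.n_points}")
        for name in ("biomass_range", "soil_moisture_range", "incidence_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered (min < max), got {(lo, hi)}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.ndvi_noise_sd < 0:
            raise ValueError("ndvi_noise_sd must be non-negative")
        if not 0 < self.dry_wet_ratio <= 1:
            raise ValueError("dry_wet_ratio must lie in (0, 1]")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(n)
    s2 = np.log1p(cv ** 2)
    return np.exp(rng.normal(-s2 / 2.0, np.sqrt(s2), size=n))


def generate(config: SyntheticConfig) -> tuple[ObservationTable, dict[str, Any]]:
    """Draw one synthetic table plus the generating truth.

    Returns ``(table, truth)`` where ``truth`` holds the true coefficients,
    the per-point (biomass, soil moisture, incidence angle) draws and the
    noise-free backscatter, for recovery scoring.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_points

    wet = rng.uniform(*config.biomass_range, size=n)
    mv = rng.uniform(*config.soil_moisture_range, size=n)
    theta = rng.uniform(*config.incidence_range, size=n)

    sigma_hh_clean = wcm_forward(config.true_coefs_hh, wet, mv, theta)
    sigma_hv_clean = wcm_forward(config.true_coefs_hv, wet, mv, theta)
    if np.any(sigma_hh_clean <= 0) or np.any(sigma_hv_clean <= 0):
        raise ValueError(
            "true coefficients produce non-positive backscatter over the ranges"
        )
    sigma_hh = sigma_hh_clean * _lognormal_factors(rng, config.noise_cv, n)
    sigma_hv = sigma_hv_clean * _lognormal_factors(rng, config.noise_cv, n)

    ndvi = config.optical_true.invert(wet)
    ndvi = ndvi + rng.normal(0.0, config.ndvi_noise_sd, size=n) if config.ndvi_noise_sd else ndvi
    ndvi = np.clip(ndvi, -1.0, 1.0)

    dry = config.dry_wet_ratio * wet
    records = tuple(
        ObservationRecord(
            point_no=i + 1,
            dry_biomass=float(dry[i]),
            wet_biomass=float(wet[i]),
            soil_moisture=float(mv[i]),
            hh_backscatter=float(sigma_hh[i]),
            hv_backscatter=float(sigma_hv[i]),
            incidence_angle=float(theta[i]),
            ndvi=float(ndvi[i]),
        )
        for i in range(n)
    )
    n_cal = max(MIN_POINTS, int(round(n * 23 / 66))) if n > MIN_POINTS else n - 1
    table = ObservationTable(records=records, n_calibration=min(n_cal, n - 1))
    truth = {
        "coefs_hh": config.true_coefs_hh,
        "coefs_hv": config.true_coefs_hv,
        "optical_true": config.optical_true,
        "wet_biomass": wet,
        "dry_biomass": dry,
        "soil_moisture": mv,
        "incidence_angle": theta,
        "sigma_hh_clean": sigma_hh_clean,
        "sigma_hv_clean": sigma_hv_clean,
        "seed": config.seed,
    }
    return table, truth
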