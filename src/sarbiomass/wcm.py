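"""Water Cloud Model: forward backscatter, calibration, dual-pol inversion.

The Water Cloud Model (WCM) treats the corn canopy as a homogeneous cloud of
water droplets over a soil surface.  Total linear-power backscatter is the
sum of direct canopy scattering and soil scattering attenuated by the
two-way canopy transmissivity::

    sigma0 = A * L**E1 * cos(theta) * (1 - tau2) + (C * Mv + D) * tau2
    tau2   = exp(-2 * B * L**E2 / cos(theta))

with L the biomass (kg m^-2), Mv the volumetric soil moisture (m^3 m^-3),
theta the incidence angle and (A, B, C, D, E1, E2) empirical coefficients
fitted per polarization.  Calibration estimates the six coefficients from
ground-truthed points by damped nonlinear least squares; inversion solves
the calibrated HH and HV equations simultaneously for (L, Mv) at a new
observation, so biomass and soil moisture are retrieved with no ancillary
input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._optim import levenberg_marquardt
from .datasets import ObservationRecord

__all__ = [
    "WCMCoefficients",
    "CalibrationFit",
    "InversionResult",
    "InsufficientDataError",
    "wcm_forward",
    "calibrate_wcm",
    "invert_wcm",
    "invert_records",
    "WaterCloudModel",
    "DualPolInverter",
    "save_coefficients",
    "load_coefficients",
]

#: Calibrating six coefficients needs at least six points.
MIN_CALIBRATION_POINTS = 6

_COEF_NAMES = ("a", "b", "c", "d", "e1", "e2")

#: Jacobian condition number above which a retrieval is flagged unidentifiable.
_IDENTIFIABILITY_COND = 1e10


class InsufficientDataError(ValueError):
    """Fewer calibration points than model coefficients."""


@dataclass(frozen=True)
class WCMCoefficients:
    """The six WCM coefficients for one polarization.

    ``a`` scales canopy scattering, ``b`` the canopy attenuation, ``c`` and
    ``d`` are the soil term's moisture sensitivity and offset, and ``e1``,
    ``e2`` are the biomass exponents of the canopy and attenuation terms.
    """

    a: float
    b: float
    c: float
    d: float
    e1: float
    e2: float
    polarization: str = "HH"
    biomass_kind: str = "wet"

    def __post_init__(self) -> None:
        values = self.as_array()
        if not np.all(np.isfinite(values)):
            raise ValueError(f"coefficients must all be finite, got {values}")
        if self.polarization not in ("HH", "HV"):
            raise ValueError(f"polarization must be 'HH' or 'HV', got {self.polarization!r}")
        if self.biomass_kind not in ("wet", "dry"):
            raise ValueError(f"biomass_kind must be 'wet' or 'dry', got {self.biomass_kind!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e1, self.e2], dtype=float)

    @classmethod
    def from_array(
        cls, values: Sequence[float], polarization: str = "HH", biomass_kind: str = "wet"
    ) -> "WCMCoefficients":
        a, b, c, d, e1, e2 = (float(v) for v in values)
        return cls(a, b, c, d, e1, e2, polarization=polarization, biomass_kind=biomass_kind)


@dataclass
class CalibrationFit:
    """Result of fitting the six coefficients on calibration points."""

    coefficients: WCMCoefficients
    residuals: np.ndarray  # model minus observation, linear power
    sse: float
    iterations: int
    converged: bool
    seed: int
    restart_initial_sse: np.ndarray = field(default_factory=lambda: np.empty(0))
    restart_final_sse: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def best_initial_sse(self) -> float:
        """SSE of the best random starting draw (before any iteration)."""
        return float(np.min(self.restart_initial_sse))


@dataclass
class InversionResult:
    """Biomass and soil moisture retrieved from one dual-pol observation."""

    biomass: float
    soil_moisture: float
    converged: bool
    iterations: int
    residual_norm: float
    identifiable: bool = True
    physical: bool = True


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _forward(params: np.ndarray, L, Mv, cos_t):
    """Vectorized WCM; L may be any non-negative array, cos_t = cos(theta)."""
    a, b, c, d, e1, e2 = params
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        tau2 = np.exp(-2.0 * b * L ** e2 / cos_t)
        canopy = a * L ** e1 * cos_t * (1.0 - tau2)
        soil = (c * Mv + d) * tau2
        total = canopy + soil
    return total


def _jac_params(params: np.ndarray, L, Mv, cos_t) -> np.ndarray:
    """d sigma / d (a, b, c, d, e1, e2); shape (n, 6). Requires L > 0."""
    a, b, c, d, e1, e2 = params
    with np.errstate(over="ignore", invalid="ignore"):
        Le1 = L ** e1
        Le2 = L ** e2
        logL = np.log(L)
        tau2 = np.exp(-2.0 * b * Le2 / cos_t)
        soil_minus_canopy = (c * Mv + d) - a * Le1 * cos_t
        dtau_db = tau2 * (-2.0 * Le2 / cos_t)
        dtau_de2 = tau2 * (-2.0 * b * Le2 * logL / cos_t)
        cols = [
            Le1 * cos_t * (1.0 - tau2),          # d/dA
            dtau_db * soil_minus_canopy,          # d/dB
            Mv * tau2,                            # d/dC
            np.ones_like(tau2),                   # d/dD
            a * Le1 * logL * cos_t * (1.0 - tau2),  # d/dE1
            dtau_de2 * soil_minus_canopy,         # d/dE2
        ]
    return np.stack([np.broadcast_to(col, np.shape(tau2)) for col in cols], axis=-1)


def _jac_state(params: np.ndarray, L: float, Mv: float, cos_t: float) -> np.ndarray:
    """d sigma / d (L, Mv) for one point; the retrieval Jacobian (2,).

    Evaluated with the smooth even extension |L| so the root solver may pass
    through zero; the derivative picks up sign(L).
    """
    a, b, c, d, e1, e2 = params
    sgn = 1.0 if L >= 0 else -1.0
    Labs = abs(L)
    if Labs == 0.0:
        Labs = 1e-300
    tau2 = np.exp(-2.0 * b * Labs ** e2 / cos_t)
    dtau_dL = tau2 * (-2.0 * b * e2 * Labs ** (e2 - 1.0) / cos_t)
    dsig_dL = (
        a * e1 * Labs ** (e1 - 1.0) * cos_t * (1.0 - tau2)
        - a * Labs ** e1 * cos_t * dtau_dL
        + (c * Mv + d) * dtau_dL
    ) * sgn
    dsig_dMv = c * tau2
    return np.array([dsig_dL, dsig_dMv])


def wcm_forward(coefs, biomass, soil_moisture, incidence_angle):
    """Evaluate the WCM forward model in linear power units.

    Parameters may be scalars or broadcastable arrays; ``incidence_angle``
    is in degrees; ``coefs`` is a :class:`WCMCoefficients` or a length-6
    array ``(a, b, c, d, e1, e2)``.
    """
    params = coefs.as_array() if isinstance(coefs, WCMCoefficients) else np.asarray(coefs, float)
    L = np.asarray(biomass, dtype=float)
    Mv = np.asarray(soil_moisture, dtype=float)
    theta = np.asarray(incidence_angle, dtype=float)
    if np.any(L < 0):
        raise ValueError("biomass must be non-negative")
    if np.any((theta <= 0) | (theta >= 90)):
        raise ValueError("incidence angle must lie strictly between 0 and 90 degrees")
    if np.any(L == 0) and (params[4] <= 0 or params[5] <= 0):
        raise ValueError("biomass of exactly zero requires positive exponents e1 and e2")
    out = _forward(params, L, Mv, np.cos(np.radians(theta)))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("forward model evaluated to a non-finite value")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _records_to_arrays(
    records: Sequence[ObservationRecord], polarization: str, biomass_kind: str
):
    if polarization not in ("HH", "HV"):
        raise ValueError(f"polarization must be 'HH' or 'HV', got {polarization!r}")
    if biomass_kind not in ("wet", "dry"):
        raise ValueError(f"biomass_kind must be 'wet' or 'dry', got {biomass_kind!r}")
    L = np.array([getattr(r, f"{biomass_kind}_biomass") for r in records])
    Mv = np.array([r.soil_moisture for r in records])
    theta = np.array([r.incidence_angle for r in records])
    sigma = np.array(
        [getattr(r, f"{polarization.lower()}_backscatter") for r in records]
    )
    return L, Mv, theta, sigma


def _calibrate_arrays(
    L: np.ndarray,
    Mv: np.ndarray,
    theta: np.ndarray,
    sigma: np.ndarray,
    polarization: str,
    biomass_kind: str,
    seed: int,
    tol: float,
    max_iter: int,
    n_restarts: int,
) -> CalibrationFit:
    if len(L) < MIN_CALIBRATION_POINTS:
        raise InsufficientDataError(
            f"calibration needs at least {MIN_CALIBRATION_POINTS} points, got {len(L)}"
        )
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if np.any(sigma <= 0):
        raise ValueError(f"{polarization} backscatter must be strictly positive")
    if np.any(L <= 0):
        raise ValueError("calibration requires strictly positive biomass values")
    if np.ptp(L) == 0:
        warnings.warn(
            "all biomass values identical: the canopy coefficients are rank-deficient",
            RuntimeWarning,
            stacklevel=2,
        )
    cos_t = np.cos(np.radians(theta))

    def residual(p):
        return _forward(p, L, Mv, cos_t) - sigma

    def jacobian(p):
        return _jac_params(p, L, Mv, cos_t)

    rng = np.random.default_rng(seed)
    starts = rng.uniform(0.0, 1.0, size=(n_restarts, 6))
    best = None
    initial_sses = np.empty(n_restarts)
    final_sses = np.empty(n_restarts)
    for i, x0 in enumerate(starts):
        res = levenberg_marquardt(
            residual, jacobian, x0, max_iter=max_iter, sse_tol=tol
        )
        initial_sses[i] = res.initial_sse
        final_sses[i] = res.sse
        if best is None or res.sse < best.sse:
            best = res

    coefficients = WCMCoefficients.from_array(
        best.x, polarization=polarization, biomass_kind=biomass_kind
    )
    return CalibrationFit(
        coefficients=coefficients,
        residuals=best.residuals,
        sse=best.sse,
        iterations=best.n_iter,
        converged=best.converged,
        seed=seed,
        restart_initial_sse=initial_sses,
        restart_final_sse=final_sses,
    )


def calibrate_wcm(
    records: Sequence[ObservationRecord],
    polarization: str = "HH",
    biomass_kind: str = "wet",
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 100,
    n_restarts: int = 20,
) -> CalibrationFit:
    """Fit the six WCM coefficients to calibration points.

    Minimizes the sum of squared backscatter residuals by damped least
    squares.  Initial coefficients are drawn uniformly on (0, 1); with
    ``n_restarts`` > 1 the fit with the smallest SSE over all restarts is
    returned.  Each restart iterates until the SSE improvement drops below
    ``tol`` or ``max_iter`` iterations are reached.
    """
    records = list(records)
    L, Mv, theta, sigma = _records_to_arrays(records, polarization, biomass_kind)
    return _calibrate_arrays(
        L, Mv, theta, sigma, polarization, biomass_kind, seed, tol, max_iter, n_restarts
    )


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

def invert_wcm(
    coefs_hh: WCMCoefficients,
    coefs_hv: WCMCoefficients,
    sigma_hh: float,
    sigma_hv: float,
    incidence_angle: float,
    init_biomass: float = 1.0,
    init_soil_moisture: float = 0.2,
    tol: float = 1e-6,
    max_iter: int = 400,
    residual_tol: float = 1e-8,
) -> InversionResult:
    """Retrieve (biomass, soil moisture) from one HH/HV backscatter pair.

    Solves the two-equation system {sigma_hh(L, Mv) = obs_hh,
    sigma_hv(L, Mv) = obs_hv} by Levenberg-Marquardt from the starting
    point (``init_biomass``, ``init_soil_moisture``), stopping when the
    step between iterates falls below ``tol`` or after ``max_iter``
    iterations.  The solution is returned raw (no clamping); retrievals
    outside physical ranges carry ``physical=False``, and a near-singular
    retrieval Jacobian (e.g. vanishing biomass sensitivity) sets
    ``identifiable=False`` and ``converged=False``.
    """
    if coefs_hh.biomass_kind != coefs_hv.biomass_kind:
        raise ValueError(
            "HH and HV coefficients must be calibrated for the same biomass kind, "
            f"got {coefs_hh.biomass_kind!r} and {coefs_hv.biomass_kind!r}"
        )
    if sigma_hh <= 0 or sigma_hv <= 0:
        raise ValueError("observed backscatter must be strictly positive")
    if not 0 < incidence_angle < 90:
        raise ValueError("incidence angle must lie strictly between 0 and 90 degrees")

    p_hh = coefs_hh.as_array()
    p_hv = coefs_hv.as_array()
    cos_t = float(np.cos(np.radians(incidence_angle)))
    obs = np.array([sigma_hh, sigma_hv])

    def residual(v):
        L, Mv = v
        Labs = abs(L)  # smooth even extension keeps fractional powers real
        return np.array(
            [
                _forward(p_hh, Labs, Mv, cos_t),
                _forward(p_hv, Labs, Mv, cos_t),
            ]
        ) - obs

    def jacobian(v):
        L, Mv = v
        return np.stack(
            [_jac_state(p_hh, L, Mv, cos_t), _jac_state(p_hv, L, Mv, cos_t)]
        )

    res = levenberg_marquardt(
        residual,
        jacobian,
        np.array([init_biomass, init_soil_moisture]),
        max_iter=max_iter,
        step_tol=tol,
    )
    L, Mv = res.x
    # the solver works on the smooth even extension in L, so -L* and +L* are
    # the same root; report the physically meaningful non-negative branch
    L = abs(L)
    residual_norm = float(np.linalg.norm(res.residuals))
    J = jacobian(res.x)
    sv = np.linalg.svd(J, compute_uv=False)
    identifiable = bool(sv[-1] > 0 and sv[0] / sv[-1] < _IDENTIFIABILITY_COND)
    converged = bool(res.converged and residual_norm <= residual_tol and identifiable)
    physical = bool(0 <= Mv <= 1)
    return InversionResult(
        biomass=float(L),
        soil_moisture=float(Mv),
        converged=converged,
        iterations=res.n_iter,
        residual_norm=residual_norm,
        identifiable=identifiable,
        physical=physical,
    )


def invert_records(
    coefs_hh: WCMCoefficients,
    coefs_hv: WCMCoefficients,
    records: Sequence[ObservationRecord],
    **kwargs,
) -> list[InversionResult]:
    """Run :func:`invert_wcm` on every record; one result per record."""
    return [
        invert_wcm(
            coefs_hh,
            coefs_hv,
            r.hh_backscatter,
            r.hv_backscatter,
            r.incidence_angle,
            **kwargs,
        )
        for r in records
    ]


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator, RegressorMixin  # noqa: E402


class WaterCloudModel(BaseEstimator, RegressorMixin):
    """WCM backscatter regressor with six fitted coefficients.

    ``X`` has columns ``(biomass, soil_moisture, incidence_angle_deg)`` and
    ``y`` is linear-power backscatter.  ``fit`` runs multi-restart damped
    least squares; fitted coefficients live in ``coefficients_``.
    """

    def __init__(
        self,
        polarization: str = "HH",
        biomass_kind: str = "wet",
        tol: float = 1e-8,
        max_iter: int = 100,
        n_restarts: int = 20,
        random_state: int = 0,
    ):
        self.polarization = polarization
        self.biomass_kind = biomass_kind
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    @staticmethod
    def _validate_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(
                "X must be 2-D with columns (biomass, soil_moisture, incidence_angle)"
            )
        return X

    def fit(self, X, y):
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise ValueError("y must be 1-D and match the number of rows of X")
        fit = _calibrate_arrays(
            X[:, 0],
            X[:, 1],
            X[:, 2],
            y,
            polarization=self.polarization,
            biomass_kind=self.biomass_kind,
            seed=self.random_state,
            tol=self.tol,
            max_iter=self.max_iter,
            n_restarts=self.n_restarts,
        )
        self.fit_ = fit
        self.coefficients_ = fit.coefficients
        self.coef_ = fit.coefficients.as_array()
        self.sse_ = fit.sse
        self.n_iter_ = fit.iterations
        self.converged_ = fit.converged
        return self

    def predict(self, X):
        if not hasattr(self, "coefficients_"):
            raise AttributeError("WaterCloudModel must be fitted before predicting")
        X = self._validate_X(X)
        return wcm_forward(self.coefficients_, X[:, 0], X[:, 1], X[:, 2])


class DualPolInverter(BaseEstimator):
    """Simultaneous (biomass, soil moisture) retrieval from HH+HV pairs.

    ``predict(X)`` with columns ``(sigma_hh, sigma_hv, incidence_angle_deg)``
    returns an (n, 2) array of (biomass, soil_moisture); ``invert(X)``
    returns the full per-point :class:`InversionResult` diagnostics.
    """

    def __init__(
        self,
        coefs_hh: WCMCoefficients = None,
        coefs_hv: WCMCoefficients = None,
        init_biomass: float = 1.0,
        init_soil_moisture: float = 0.2,
        tol: float = 1e-6,
        max_iter: int = 400,
    ):
        self.coefs_hh = coefs_hh
        self.coefs_hv = coefs_hv
        self.init_biomass = init_biomass
        self.init_soil_moisture = init_soil_moisture
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X=None, y=None):
        """No-op validation hook: the inverter is configured, not trained."""
        if self.coefs_hh is None or self.coefs_hv is None:
            raise ValueError("both coefs_hh and coefs_hv must be provided")
        return self

    def invert(self, X) -> list[InversionResult]:
        self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(
                "X must be 2-D with columns (sigma_hh, sigma_hv, incidence_angle)"
            )
        return [
            invert_wcm(
                self.coefs_hh,
                self.coefs_hv,
                row[0],
                row[1],
                row[2],
                init_biomass=self.init_biomass,
                init_soil_moisture=self.init_soil_moisture,
                tol=self.tol,
                max_iter=self.max_iter,
            )
            for row in X
        ]

    def predict(self, X):
        results = self.invert(X)
        return np.array([[r.biomass, r.soil_moisture] for r in results])


# ---------------------------------------------------------------------------
# serialization: small key-value text files
# ---------------------------------------------------------------------------

def save_coefficients(
    coefs: WCMCoefficients, path: str | Path, seed: int | None = None, sse: float | None = None
) -> None:
    """Write coefficients to a flat ``key = value`` text file."""
    lines = [
        f"polarization = {coefs.polarization}",
        f"biomass_kind = {coefs.biomass_kind}",
    ]
    for name in _COEF_NAMES:
        lines.append(f"{name} = {getattr(coefs, name)!r}")
    if seed is not None:
        lines.append(f"seed = {seed}")
    if sse is not None:
        lines.append(f"sse = {sse!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_coefficients(path: str | Path) -> WCMCoefficients:
    """Read coefficients written by :func:`save_coefficients`."""
    fields = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    missing = [k for k in ("polarization", "biomass_kind", *_COEF_NAMES) if k not in fields]
    if missing:
        raise ValueError(f"coefficient file {path} is missing: {', '.join(missing)}")
    return WCMCoefficients(
        *(float(fields[k]) for k in _COEF_NAMES),
        polarization=fields["polarization"],
        biomass_kind=fields["biomass_kind"],
    )
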