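"""Vegetation-index biomass models and index computation.

Four empirical two-coefficient models relate a vegetation index to corn
biomass (wet or dry, kg m^-2):

=============  =========================
form           biomass =
=============  =========================
NDVI_EXP       a * exp(NDVI) + b
RTVI_LINEAR    a * RTVI + b
SR_LOG         a * ln(SR) + b
SRRE_LINEAR    a * SRre + b
=============  =========================

All four are linear in (a, b) once the index is transformed, so the damped
least-squares fit (random U(0,1) start, as for the Water Cloud Model) must
agree with closed-form ordinary least squares; tests enforce this.

Index formulas from surface reflectance are the literature-standard
defaults (NDVI = (NIR-Red)/(NIR+Red), SR = NIR/Red, SRre = NIR/RedEdge,
RTVI = 100*(NIR-RedEdge) - 10*(NIR-Green)) and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._optim import levenberg_marquardt

__all__ = [
    "FORMS",
    "OpticalModel",
    "OpticalBiomassModel",
    "predict_optical",
    "calibrate_optical",
    "compute_index",
    "save_optical_model",
    "load_optical_model",
]


def _transform_identity(vi: np.ndarray) -> np.ndarray:
    return vi


def _transform_exp(vi: np.ndarray) -> np.ndarray:
    return np.exp(vi)


def _transform_log(vi: np.ndarray) -> np.ndarray:
    if np.any(vi <= 0):
        raise ValueError("SR_LOG requires strictly positive index values")
    return np.log(vi)


#: form name -> transform phi such that biomass = a * phi(vi) + b
FORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "NDVI_EXP": _transform_exp,
    "RTVI_LINEAR": _transform_identity,
    "SR_LOG": _transform_log,
    "SRRE_LINEAR": _transform_identity,
}


@dataclass(frozen=True)
class OpticalModel:
    """A fitted vegetation-index biomass model."""

    form: str
    a: float
    b: float
    biomass_kind: str = "wet"
    fit_sse: float = 0.0
    iterations: int = 0

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; choose from {sorted(FORMS)}")
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("coefficients must be finite")
        if self.fit_sse < 0:
            raise ValueError("fit_sse must be non-negative")

    def predict(self, vi) -> np.ndarray:
        return predict_optical(self, vi)

    def invert(self, biomass) -> np.ndarray:
        """Index value mapping to the given biomass (used by the simulator)."""
        biomass = np.asarray(biomass, dtype=float)
        z = (biomass - self.b) / self.a
        if self.form == "NDVI_EXP":
            return np.log(z)
        if self.form == "SR_LOG":
            return np.exp(z)
        return z


def predict_optical(model: OpticalModel, vi):
    """Biomass predicted by a fitted model at index value(s) ``vi``."""
    vi = np.asarray(vi, dtype=float)
    out = model.a * FORMS[model.form](vi) + model.b
    return out if out.ndim else float(out)


def calibrate_optical(
    vi_values: Sequence[float],
    biomass_values: Sequence[float],
    form: str = "NDVI_EXP",
    biomass_kind: str = "wet",
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> OpticalModel:
    """Least-squares fit of (a, b) for one model form.

    Initial coefficients are drawn uniformly on (0, 1); iteration stops when
    the SSE improvement falls below ``tol`` or after ``max_iter`` iterations.
    Because every form is linear in its coefficients this converges to the
    ordinary-least-squares solution.
    """
    vi = np.asarray(vi_values, dtype=float)
    y = np.asarray(biomass_values, dtype=float)
    if vi.shape != y.shape or vi.ndim != 1:
        raise ValueError("index and biomass lists must be 1-D and equally long")
    if len(vi) < 2:
        raise ValueError("at least two points are needed to fit two coefficients")
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}; choose from {sorted(FORMS)}")
    phi = FORMS[form](vi)
    if np.ptp(phi) == 0:
        raise ValueError("constant index vector: the slope is rank-deficient")

    def residual(p):
        return p[0] * phi + p[1] - y

    def jacobian(p):
        return np.column_stack([phi, np.ones_like(phi)])

    rng = np.random.default_rng(seed)
    x0 = rng.uniform(0.0, 1.0, size=2)
    res = levenberg_marquardt(residual, jacobian, x0, max_iter=max_iter, sse_tol=tol)
    return OpticalModel(
        form=form,
        a=float(res.x[0]),
        b=float(res.x[1]),
        biomass_kind=biomass_kind,
        fit_sse=res.sse,
        iterations=res.n_iter,
    )


class OpticalBiomassModel(BaseEstimator, RegressorMixin):
    """scikit-learn wrapper around one vegetation-index biomass model."""

    def __init__(
        self,
        form: str = "NDVI_EXP",
        biomass_kind: str = "wet",
        tol: float = 1e-8,
        max_iter: int = 100,
        random_state: int = 0,
    ):
        self.form = form
        self.biomass_kind = biomass_kind
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be a 1-D vector of index values (or shape (n, 1))")
        return X

    def fit(self, X, y):
        vi = self._as_1d(X)
        model = calibrate_optical(
            vi,
            np.asarray(y, dtype=float),
            form=self.form,
            biomass_kind=self.biomass_kind,
            seed=self.random_state,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.model_ = model
        self.a_ = model.a
        self.b_ = model.b
        self.sse_ = model.fit_sse
        self.n_iter_ = model.iterations
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise AttributeError("OpticalBiomassModel must be fitted before predicting")
        return predict_optical(self.model_, self._as_1d(X))


# ---------------------------------------------------------------------------
# vegetation indices from surface reflectance
# ---------------------------------------------------------------------------

def _ndvi(b: Mapping[str, float]) -> float:
    den = b["nir"] + b["red"]
    if den == 0:
        raise ZeroDivisionError("NDVI denominator NIR+Red is zero")
    return (b["nir"] - b["red"]) / den


def _sr(b: Mapping[str, float]) -> float:
    if b["red"] == 0:
        raise ZeroDivisionError("SR denominator Red is zero")
    return b["nir"] / b["red"]


def _srre(b: Mapping[str, float]) -> float:
    if b["red_edge"] == 0:
        raise ZeroDivisionError("SRre denominator RedEdge is zero")
    return b["nir"] / b["red_edge"]


def _rtvi(b: Mapping[str, float]) -> float:
    return 100.0 * (b["nir"] - b["red_edge"]) - 10.0 * (b["nir"] - b["green"])


_INDEX_FUNCS: dict[str, tuple[Callable[[Mapping[str, float]], float], tuple[str, ...]]] = {
    "NDVI": (_ndvi, ("nir", "red")),
    "SR": (_sr, ("nir", "red")),
    "SRRE": (_srre, ("nir", "red_edge")),
    "RTVI": (_rtvi, ("nir", "red_edge", "green")),
}


def compute_index(
    reflectances: Mapping[str, float],
    index: str,
    formula: Callable[[Mapping[str, float]], float] | None = None,
) -> float:
    """Compute a vegetation index from per-band surface reflectance.

    ``reflectances`` maps band names (``green``, ``red``, ``red_edge``,
    ``nir``) to reflectance.  ``formula`` overrides the built-in default for
    sensors using a different variant of the index.
    """
    key = index.upper()
    if key not in _INDEX_FUNCS:
        raise ValueError(f"unknown index {index!r}; choose from {sorted(_INDEX_FUNCS)}")
    func, bands = _INDEX_FUNCS[key]
    if formula is not None:
        func = formula
    missing = [band for band in bands if band not in reflectances]
    if missing and formula is None:
        raise KeyError(f"missing band(s) for {key}: {', '.join(missing)}")
    return float(func(reflectances))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_optical_model(model: OpticalModel, path: str | Path, seed: int | None = None) -> None:
    """Write a fitted model to a flat ``key = value`` text file."""
    lines = [
        f"form = {model.form}",
        f"biomass_kind = {model.biomass_kind}",
        f"a = {model.a!r}",
        f"b = {model.b!r}",
        f"fit_sse = {model.fit_sse!r}",
        f"iterations = {model.iterations}",
    ]
    if seed is not None:
        lines.append(f"seed = {seed}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_optical_model(path: str | Path) -> OpticalModel:
    fields = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    required = ("form", "biomass_kind", "a", "b")
    missing = [k for k in required if k not in fields]
    if missing:
        raise ValueError(f"optical model file {path} is missing: {', '.join(missing)}")
    return OpticalModel(
        form=fields["form"],
        a=float(fields["a"]),
        b=float(fields["b"]),
        biomass_kind=fields["biomass_kind"],
        fit_sse=float(fields.get("fit_sse", 0.0)),
        iterations=int(fields.get("iterations", 0)),
    )
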