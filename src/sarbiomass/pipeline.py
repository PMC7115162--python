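"""End-to-end retrieval pipeline on one observation table.

Stages, mirroring how the method is applied in practice:

1. calibrate the Water Cloud Model for HH and HV on the calibration rows;
2. invert the calibrated dual-pol model for (biomass, soil moisture) at
   every point (calibration rows feed the transfer training, validation
   rows are the product);
3. fit the configured vegetation-index biomass models on calibration rows;
4. train the transfer network on calibration-row pairs (SAR estimate ->
   optical estimate);
5. apply the network (plus absolute value) to the validation-row SAR
   estimates.

Outputs: a per-validation-point CSV, serialized model files, and a run log
recording seeds, per-restart SSEs and solver exit diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import optical as _optical
from . import wcm as _wcm
from .datasets import ObservationTable, load_table
from .transfer import TransferNetwork, train_transfer

__all__ = ["RunConfig", "RunResult", "run_all"]

RESULT_COLUMNS = (
    "point_no",
    "sar_biomass",
    "sar_soil_moisture",
    "optical_biomass",
    "adjusted_biomass",
    "inversion_converged",
    "identifiable",
    "physical",
)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    input_path: str | Path
    n_calibration: int = 23
    biomass_kind: str = "wet"
    seed_calibration: int = 0
    seed_nn: int = 0
    calibration_tol: float = 1e-8
    calibration_max_iter: int = 100
    n_restarts: int = 20
    inversion_tol: float = 1e-6
    inversion_max_iter: int = 400
    optical_forms: tuple[str, ...] = ("NDVI_EXP",)
    nn_hidden: int = 10
    nn_train_fraction: float = 0.7
    nn_max_iter: int = 1000
    output_dir: str | Path = "sarbiomass_run"

    def validate(self) -> None:
        if self.calibration_tol <= 0 or self.inversion_tol <= 0:
            raise ValueError("solver tolerances must be positive")
        for name in ("calibration_max_iter", "inversion_max_iter", "nn_max_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.optical_forms:
            raise ValueError("at least one optical form is required")
        for form in self.optical_forms:
            if form not in _optical.FORMS:
                raise ValueError(f"unknown optical form {form!r}")


@dataclass
class RunResult:
    """Everything a run produced, for programmatic use."""

    table: ObservationTable
    fit_hh: _wcm.CalibrationFit
    fit_hv: _wcm.CalibrationFit
    inversions_calibration: list
    inversions_validation: list
    optical_models: dict
    network: TransferNetwork
    results: pd.DataFrame
    log_lines: list = dc_field(default_factory=list)


def _stage(name):
    def wrap(func):
        def inner(*args, **kwargs):
            try:
                return func(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def run_all(config: RunConfig, table: ObservationTable | None = None) -> RunResult:
    """Execute all pipeline stages and write outputs to ``output_dir``."""
    config.validate()
    log: list[str] = []
    if table is None:
        table = load_table(config.input_path, n_calibration=config.n_calibration)
    cal, val = table.split()
    log.append(f"input: {config.input_path} ({len(table)} rows, {len(cal)} calibration)")

    # stage 1: WCM calibration, both polarizations
    fits = {}
    for pol in ("HH", "HV"):
        fit = _stage(f"calibrate-wcm-{pol}")(_wcm.calibrate_wcm)(
            cal,
            polarization=pol,
            biomass_kind=config.biomass_kind,
            seed=config.seed_calibration,
            tol=config.calibration_tol,
            max_iter=config.calibration_max_iter,
            n_restarts=config.n_restarts,
        )
        fits[pol] = fit
        log.append(
            f"calibrate {pol} ({config.biomass_kind}): seed={fit.seed} "
            f"restarts={config.n_restarts} sse={fit.sse:.6e} "
            f"iterations={fit.iterations} converged={fit.converged}"
        )
        log.append(
            f"  per-restart sse: "
            + " ".join(f"{s:.4e}" for s in fit.restart_final_sse)
        )

    # stage 2: dual-pol inversion at every point
    invert = _stage("invert")(_wcm.invert_records)
    inv_cal = invert(
        fits["HH"].coefficients,
        fits["HV"].coefficients,
        cal,
        tol=config.inversion_tol,
        max_iter=config.inversion_max_iter,
    )
    inv_val = invert(
        fits["HH"].coefficients,
        fits["HV"].coefficients,
        val,
        tol=config.inversion_tol,
        max_iter=config.inversion_max_iter,
    )
    n_conv = sum(r.converged for r in inv_val)
    log.append(f"inversion: {n_conv}/{len(inv_val)} validation points converged")

    # stage 3: optical model fits on calibration rows (NDVI is the packaged index)
    vi_cal = np.array([r.ndvi for r in cal])
    biomass_cal = np.array([getattr(r, f"{config.biomass_kind}_biomass") for r in cal])
    optical_models = {}
    for form in config.optical_forms:
        model = _stage(f"fit-optical-{form}")(_optical.calibrate_optical)(
            vi_cal,
            biomass_cal,
            form=form,
            biomass_kind=config.biomass_kind,
            seed=config.seed_calibration,
            tol=config.calibration_tol,
            max_iter=config.calibration_max_iter,
        )
        optical_models[form] = model
        log.append(
            f"optical {form}: a={model.a:.6g} b={model.b:.6g} sse={model.fit_sse:.6e}"
        )

    # stage 4: transfer network on calibration-row (SAR, optical) estimate pairs
    primary_form = config.optical_forms[0]
    sar_cal = np.array([r.biomass for r in inv_cal])
    opt_cal = _optical.predict_optical(optical_models[primary_form], vi_cal)
    network = _stage("train-transfer")(train_transfer)(
        sar_cal,
        opt_cal,
        hidden=config.nn_hidden,
        train_fraction=config.nn_train_fraction,
        seed=config.seed_nn,
        max_iter=config.nn_max_iter,
    )
    log.append(
        f"transfer NN: {network.n_train_} train / {network.n_holdout_} holdout, "
        f"train_mse={network.train_mse_:.6e} holdout_mse={network.holdout_mse_:.6e} "
        f"iterations={network.n_iter_} seed={config.seed_nn}"
    )

    # stage 5: adjust validation SAR estimates
    sar_val = np.array([r.biomass for r in inv_val])
    adjusted = _stage("apply-transfer")(network.predict)(sar_val)
    vi_val = np.array([r.ndvi for r in val])
    opt_val = _optical.predict_optical(optical_models[primary_form], vi_val)

    results = pd.DataFrame(
        {
            "point_no": [r.point_no for r in val],
            "sar_biomass": sar_val,
            "sar_soil_moisture": [r.soil_moisture for r in inv_val],
            "optical_biomass": opt_val,
            "adjusted_biomass": adjusted,
            "inversion_converged": [r.converged for r in inv_val],
            "identifiable": [r.identifiable for r in inv_val],
            "physical": [r.physical for r in inv_val],
        },
        columns=list(RESULT_COLUMNS),
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results.csv", index=False)
    for pol, fit in fits.items():
        _wcm.save_coefficients(
            fit.coefficients, out / f"wcm_{pol.lower()}.txt", seed=fit.seed, sse=fit.sse
        )
    for form, model in optical_models.items():
        _optical.save_optical_model(
            model, out / f"optical_{form.lower()}.txt", seed=config.seed_calibration
        )
    network.to_json(out / "transfer.json")
    (out / "run.log").write_text("\n".join(log) + "\n")

    return RunResult(
        table=table,
        fit_hh=fits["HH"],
        fit_hv=fits["HV"],
        inversions_calibration=inv_cal,
        inversions_validation=inv_val,
        optical_models=optical_models,
        network=network,
        results=results,
        log_lines=log,
    )
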