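"""Growth-rate prediction from inferred unused fractions and relative turnover.

The un-utilized proteome fraction inferred from proteomics is quantitative
and can be forced directly into the model (as the dummy-protein fraction).
The inferred mean in-vivo turnover is only *relative* (0-1), so one
quantitative anchor is needed: the global turnover multiplier tau_ref is
calibrated so that the model, with the reference condition's unused
fraction forced, reproduces the reference condition's measured growth
rate.  Other conditions are then predicted with
``tau_c = tau_ref * rho_c / rho_ref`` where rho is the condition's mean
relative turnover.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy import stats

from .model import Environment, MEModel, ModelError, apply_turnover
from .solver import max_growth

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationError",
    "PredictionConfig",
    "PredictionReport",
    "calibrate_tau",
    "predict_growth",
    "predict_panel",
    "prediction_report",
]


class CalibrationError(ModelError):
    """The measured reference growth rate is unattainable at tau <= 1."""


@dataclass(frozen=True)
class PredictionConfig:
    """Inputs of the prediction stage, keyed by condition id."""

    reference_condition: str
    phi_unused: Mapping[str, float]
    rho: Mapping[str, float]
    mu_measured: Mapping[str, float]

    def __post_init__(self) -> None:
        ref = self.reference_condition
        for name, mapping in (
            ("phi_unused", self.phi_unused),
            ("rho", self.rho),
            ("mu_measured", self.mu_measured),
        ):
            if ref not in mapping:
                raise ModelError(f"reference condition {ref!r} missing from {name}")
        for cond, phi in self.phi_unused.items():
            if not 0 <= phi <= 1:
                raise ModelError(f"phi_unused[{cond!r}] must lie in [0, 1]")


@dataclass
class PredictionReport:
    """Predicted-vs-measured comparison across conditions."""

    mu_predicted: dict[str, float]
    mu_measured: dict[str, float]
    pearson_r: Optional[float]
    sample_sd_predicted: float
    sample_sd_measured: float
    degenerate: bool = False


def calibrate_tau(
    model: MEModel,
    env_ref: Environment,
    mu_ref: float,
    phi_unused_ref: float,
    *,
    mu_tol: float = 1e-5,
    tau_lo: float = 1e-6,
    max_iter: int = 60,
) -> float:
    """Bisection for the turnover multiplier reproducing the reference rate.

    Finds tau in (0, 1] such that the maximal growth rate of the
    tau-scaled model with the reference unused fraction forced equals
    ``mu_ref`` within ``mu_tol``.  A degenerate ``mu_ref = 0`` returns the
    lower bracket with a warning; an unattainable ``mu_ref`` raises with
    the diagnostic maximum at tau = 1.
    """

    def mu_at(tau: float) -> float:
        scaled = apply_turnover(model, tau)
        return max_growth(
            scaled, env_ref, forced_dummy_fraction=phi_unused_ref
        ).mu

    if mu_ref <= 0:
        logger.warning("calibration with mu_ref <= 0 is degenerate; returning %g", tau_lo)
        return tau_lo
    mu_hi = mu_at(1.0)
    if mu_hi < mu_ref - mu_tol:
        raise CalibrationError(
            f"mu_ref={mu_ref:.6g} unattainable: max growth at tau=1 is {mu_hi:.6g}"
        )
    lo, hi = tau_lo, 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        mu_mid = mu_at(mid)
        if abs(mu_mid - mu_ref) <= mu_tol:
            return mid
        if mu_mid < mu_ref:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)


def predict_growth(
    model: MEModel, env: Environment, phi_unused: float, tau: float
) -> float:
    """Maximal growth with kcats scaled by tau and the unused fraction forced."""
    scaled = apply_turnover(model, tau)
    return max_growth(scaled, env, forced_dummy_fraction=phi_unused).mu


def predict_panel(
    model: MEModel,
    envs: Mapping[str, Environment],
    config: PredictionConfig,
    *,
    mode: str = "per_condition",
    tau_ref: Optional[float] = None,
) -> tuple[dict[str, float], float]:
    """Predict growth rates for a condition panel.

    ``mode="per_condition"`` uses each condition's own inferred unused
    fraction and turnover (scaled off the calibrated reference);
    ``mode="reference_fixed"`` holds both at the reference values, which
    isolates the growth-rate variation attributable to the nutrient source
    alone.  Returns (predictions, tau_ref).
    """
    ref = config.reference_condition
    if tau_ref is None:
        tau_ref = calibrate_tau(
            model,
            envs[ref],
            config.mu_measured[ref],
            config.phi_unused[ref],
        )
    rho_ref = config.rho[ref]
    if rho_ref <= 0:
        raise ModelError("reference mean relative turnover must be > 0")
    predictions: dict[str, float] = {}
    for cond, env in envs.items():
        if mode == "per_condition":
            phi = config.phi_unused[cond]
            tau = tau_ref * config.rho[cond] / rho_ref
        elif mode == "reference_fixed":
            phi = config.phi_unused[ref]
            tau = tau_ref
        else:
            raise ModelError(f"unknown prediction mode {mode!r}")
        predictions[cond] = predict_growth(model, env, phi, tau)
    return predictions, tau_ref


def prediction_report(
    mu_predicted: Mapping[str, float], mu_measured: Mapping[str, float]
) -> PredictionReport:
    """Pearson correlation and sample SDs of predicted vs measured rates.

    Requires >= 3 common conditions.  A constant vector makes the
    correlation undefined; this is reported (``degenerate=True``) rather
    than raised.
    """
    common = sorted(set(mu_predicted) & set(mu_measured))
    if len(common) < 3:
        raise ModelError(f"need >= 3 conditions, got {len(common)}")
    pred = np.array([mu_predicted[c] for c in common])
    meas = np.array([mu_measured[c] for c in common])
    sd_pred = float(np.std(pred, ddof=1))
    sd_meas = float(np.std(meas, ddof=1))
    if sd_pred == 0 or sd_meas == 0:
        return PredictionReport(
            dict(zip(common, pred)),
            dict(zip(common, meas)),
            None,
            sd_pred,
            sd_meas,
            degenerate=True,
        )
    r = float(stats.pearsonr(pred, meas).statistic)
    return PredictionReport(
        dict(zip(common, pred)), dict(zip(common, meas)), r, sd_pred, sd_meas
    )
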