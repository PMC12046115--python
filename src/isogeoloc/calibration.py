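"""Tissue-environment calibration regression and tissue isoscapes.

Tissue isotope values y are regressed on environmental isoscape values e
extracted at each record's origin, by weighted least squares:

    minimize  sum_i w_i (y_i - alpha - beta * e_i)^2

The default weighting downweights densely sampled sites (w = 1 / number of
records at the site) so one barbershop transect cannot dominate the fit;
unit weights reproduce OLS exactly. The fit's slope/intercept turn the
environmental raster into a tissue isoscape mean surface, with the
residual standard error as the (spatially constant) prediction sd used by
the assignment posterior.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Dataset
from .isoscape import Raster, extract_at

__all__ = ["CalibrationFit", "TissueIsoscape", "calibrate", "rma_slope",
           "predict_tissue_isoscape", "site_frequency_weights"]


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationFit:
    """Weighted least-squares fit of tissue values on environmental values."""

    slope: float
    intercept: float
    r_squared: float
    rse: float
    residuals: np.ndarray
    weights: np.ndarray
    n: int
    dof: int
    env_values: np.ndarray
    tissue_values: np.ndarray
    record_ids: list[str]
    n_excluded_missing_env: int = 0

    def predict(self, env) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(env, dtype=float)

    def to_json(self) -> str:
        return json.dumps(
            {
                "slope": self.slope,
                "intercept": self.intercept,
                "r_squared": self.r_squared,
                "rse": self.rse,
                "n": self.n,
                "dof": self.dof,
                "n_excluded_missing_env": self.n_excluded_missing_env,
            },
            indent=2,
        )

    def residual_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.record_ids,
                "env_value": self.env_values,
                "tissue_value": self.tissue_values,
                "residual": self.residuals,
                "weight": self.weights,
            }
        )


@dataclass
class TissueIsoscape:
    """Predicted tissue surface: mean = alpha + beta * env, constant sd."""

    mean: Raster
    sd: Raster

    def __post_init__(self) -> None:
        valid = self.mean.valid_mask()
        if not np.all(self.sd.values[valid] > 0):
            raise CalibrationError("tissue isoscape sd must be positive on valid cells")


def site_frequency_weights(dataset: Dataset) -> np.ndarray:
    """w_i = 1 / (number of records sharing record i's site)."""
    counts = Counter(r.site_id for r in dataset)
    return np.array([1.0 / counts[r.site_id] for r in dataset], dtype=float)


def _wls(e: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Closed-form weighted least squares slope/intercept."""
    sw = w.sum()
    eb = (w * e).sum() / sw
    yb = (w * y).sum() / sw
    sxx = (w * (e - eb) ** 2).sum()
    if sxx <= 0:
        raise CalibrationError("zero variance in environmental values (collinear design)")
    beta = (w * (e - eb) * (y - yb)).sum() / sxx
    alpha = yb - beta * eb
    return alpha, beta


def calibrate(
    dataset: Dataset,
    env: Raster,
    weighting: str = "site_frequency",
) -> CalibrationFit:
    """Fit the tissue-environment weighted regression (calibration step).

    Environmental values are extracted at each record's coordinates
    (cell value, no interpolation); records falling on nodata cells are
    excluded and counted, never imputed. ``weighting`` is
    ``"site_frequency"`` (default; dense sites downweighted) or ``"unit"``
    (plain OLS).
    """
    if weighting not in ("site_frequency", "unit"):
        raise CalibrationError(f"unknown weighting policy {weighting!r}")
    records = list(dataset)
    if len(records) < 3:
        raise CalibrationError("need >= 3 records to calibrate")

    coords = dataset.coordinates()
    e_all = extract_at(env, coords)
    y_all = dataset.values()
    w_all = site_frequency_weights(dataset) if weighting == "site_frequency" else np.ones(len(records))

    ok = np.isfinite(e_all)
    n_excluded = int((~ok).sum())
    e, y, w = e_all[ok], y_all[ok], w_all[ok]
    ids = [r.sample_id for r, keep in zip(records, ok) if keep]
    n = len(e)
    if n < 3:
        raise CalibrationError(f"only {n} records with usable environmental values")

    alpha, beta = _wls(e, y, w)
    fitted = alpha + beta * e
    resid = y - fitted
    sse = float((w * resid**2).sum())
    yb = float((w * y).sum() / w.sum())
    sst = float((w * (y - yb) ** 2).sum())
    dof = n - 2
    rse = float(np.sqrt(sse / dof)) if dof > 0 else float("nan")
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return CalibrationFit(
        slope=float(beta),
        intercept=float(alpha),
        r_squared=float(r2),
        rse=rse,
        residuals=resid,
        weights=w,
        n=n,
        dof=dof,
        env_values=e,
        tissue_values=y,
        record_ids=ids,
        n_excluded_missing_env=n_excluded,
    )


def rma_slope(env_values, tissue_values) -> float:
    """Reduced major axis slope: sd(tissue)/sd(env), signed by the correlation.

    Appropriate when predictor and response carry comparable uncertainty;
    unlike OLS it is not attenuated by error in the x variable.
    """
    e = np.asarray(env_values, dtype=float)
    y = np.asarray(tissue_values, dtype=float)
    if len(e) < 2 or len(y) < 2 or len(e) != len(y):
        raise CalibrationError("need >= 2 paired values")
    se, sy = np.std(e, ddof=1), np.std(y, ddof=1)
    if se == 0 or sy == 0:
        raise CalibrationError("zero variance input to RMA slope")
    r = np.corrcoef(e, y)[0, 1]
    return float(np.sign(r) * sy / se) if r != 0 else float(sy / se)


def predict_tissue_isoscape(fit: CalibrationFit, env: Raster) -> TissueIsoscape:
    """Apply a calibration fit to the environmental raster.

    mean(x) = intercept + slope * env(x); sd(x) = RSE, spatially constant
    (isoscape prediction uncertainty is not folded in). Nodata propagates.
    A perfect fit (RSE 0) is floored at a tiny positive sd so the
    assignment posterior stays defined in the noiseless limit.
    """
    mean_vals = fit.intercept + fit.slope * env.values
    sd_floor = max(fit.rse, 1e-9)
    sd_vals = np.where(env.valid_mask(), sd_floor, np.nan)
    return TissueIsoscape(mean=env.copy_with(mean_vals), sd=env.copy_with(sd_vals))
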