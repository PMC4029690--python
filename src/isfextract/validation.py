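"""Linearity validation and Monte-Carlo error propagation.

Under stable blood glucose the permeation rate is proportional to the
diluted-sample glucose concentration, and the permeation rate is itself
proportional to skin conductance per unit area.  The model is therefore
validated on measured (or simulated) extractions by regressing the
diluted-sample glucose CS on the conductance per unit area G/A and reporting
the Pearson correlation: a tight linear relation supports the
conductance→permeation→volume chain.

The error budget propagates the three dominant noise sources —
resistance-measurement noise, diluted-sample assay noise, and the
blood-glucose-meter noise that enters once through calibration — to the
predicted blood glucose by Monte Carlo, using common random numbers across
the noise grid so the error surface is monotone in each axis per replicate,
not just in expectation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import ExtractionConfig, SkinPermeability

__all__ = [
    "LinearFitResult",
    "RecoveryStats",
    "fit_linearity",
    "recovery_stats",
    "error_budget",
]


@dataclass(frozen=True)
class LinearFitResult:
    """Ordinary least-squares fit of diluted glucose on conductance per area."""

    slope: float
    intercept: float
    pearson_r: float
    n_points: int


@dataclass(frozen=True)
class RecoveryStats:
    """Bias / RMSE / median relative error of estimates against ground truth."""

    bias: float
    rmse: float
    median_rel_error: float
    n: int


def fit_linearity(cs_values: Sequence[float],
                  g_over_a_values: Sequence[float]) -> LinearFitResult:
    """OLS of CS (mmol/L) on G/A (kΩ⁻¹·cm⁻²) with Pearson correlation.

    An intercept is fitted even though the model predicts a through-origin
    line, so deviation of the fitted intercept from zero stays observable.
    """
    y = np.asarray(cs_values, dtype=float)
    x = np.asarray(g_over_a_values, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("cs_values and g_over_a_values must be equal-length 1-D sequences")
    if y.size < 3:
        raise ValueError(f"need at least 3 points, got {y.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: zero variance in G/A")
    fit = stats.linregress(x, y)
    return LinearFitResult(slope=float(fit.slope), intercept=float(fit.intercept),
                           pearson_r=float(fit.rvalue), n_points=int(y.size))


def recovery_stats(true_values: Sequence[float],
                   estimated_values: Sequence[float]) -> RecoveryStats:
    """Bias, RMSE and median relative error of estimates vs ground truth."""
    true = np.asarray(true_values, dtype=float)
    est = np.asarray(estimated_values, dtype=float)
    if true.shape != est.shape or true.ndim != 1 or true.size < 1:
        raise ValueError("true and estimated values must be equal-length non-empty 1-D sequences")
    if np.any(true == 0):
        raise ValueError("relative error undefined: a true value is zero")
    err = est - true
    return RecoveryStats(
        bias=float(np.mean(err)),
        rmse=float(np.sqrt(np.mean(err**2))),
        median_rel_error=float(np.median(np.abs(err) / np.abs(true))),
        n=int(true.size),
    )


def error_budget(cfg: ExtractionConfig,
                 skin: SkinPermeability,
                 *,
                 sigma_r_grid: Sequence[float] = (0.0, 0.02, 0.05),
                 sigma_cs_grid: Sequence[float] = (0.0,),
                 sigma_cb_grid: Sequence[float] = (0.0,),
                 n_mc: int = 2000,
                 rb_median: float = 100.0,
                 rb_sigma_log: float = 0.25,
                 cb_true_range: tuple[float, float] = (4.0, 10.0),
                 seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo budget of predicted-glucose error over a noise grid.

    Each replicate is one (calibration extraction, prediction extraction)
    pair drawn from the synthetic skin model; for each grid point
    ``(sigma_r, sigma_cs, sigma_cb)`` lognormal noise of that size is applied
    to the measured resistances, the diluted-sample assays, and the
    calibration blood-glucose meter reading respectively, the one-point
    calibration is re-run, and the median relative error of the predicted
    blood glucose over replicates is recorded.

    One set of standard-normal draws is shared across grid points (common
    random numbers), so per replicate the error is non-decreasing along each
    noise axis and the reported surface is monotone at grid resolution.
    Replicates whose noisy calibration becomes infeasible
    (meter reading ≤ k·assay reading) are dropped and counted.

    Returns a DataFrame with columns ``sigma_r, sigma_cs, sigma_cb,
    median_rel_error, n_valid``.
    """
    grids = [np.asarray(g, dtype=float) for g in (sigma_r_grid, sigma_cs_grid, sigma_cb_grid)]
    if any(g.size == 0 for g in grids):
        raise ValueError("noise grids must be non-empty")
    if any((g < 0).any() for g in grids):
        raise ValueError("noise levels must be non-negative")
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")

    rng = np.random.default_rng(seed)
    lo, hi = cb_true_range

    def draw_sessions(n: int):
        cb = rng.uniform(lo, hi, size=n)
        r = rb_median * np.exp(rb_sigma_log * rng.standard_normal(n))
        x = skin.c1 / r
        cs = (cb / cfg.k) * x / (cfg.v_buffer + x)
        return cb, r, cs

    cb, r, cs = draw_sessions(n_mc)                # prediction extractions
    cb_cal, r_cal, cs_cal = draw_sessions(n_mc)    # paired calibration extractions
    # shared standard-normal draws, scaled per grid point
    z_r, z_r_cal, z_cs, z_cs_cal, z_cb = (rng.standard_normal(n_mc) for _ in range(5))

    rows = []
    for s_r, s_cs, s_cb in itertools.product(*grids):
        r_meas = r * np.exp(s_r * z_r)
        r_cal_meas = r_cal * np.exp(s_r * z_r_cal)
        cs_meas = cs * np.exp(s_cs * z_cs)
        cs_cal_meas = cs_cal * np.exp(s_cs * z_cs_cal)
        cb_cal_meas = cb_cal * np.exp(s_cb * z_cb)

        denom = cb_cal_meas - cfg.k * cs_cal_meas
        ok = denom > 0
        x_cal = cfg.k * cfg.v_buffer * cs_cal_meas[ok] / denom[ok]
        c1_hat = x_cal * r_cal_meas[ok]
        cb_pred = cfg.k * (1.0 + cfg.v_buffer * r_meas[ok] / c1_hat) * cs_meas[ok]
        rel_err = np.abs(cb_pred - cb[ok]) / cb[ok]
        rows.append({
            "sigma_r": float(s_r),
            "sigma_cs": float(s_cs),
            "sigma_cb": float(s_cb),
            "median_rel_error": float(np.median(rel_err)) if rel_err.size else math.nan,
            "n_valid": int(ok.sum()),
        })
    return pd.DataFrame(rows)
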