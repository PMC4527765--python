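"""Speed–dynamic-area coupling, Corrected Membrane Dynamics and persistence.

Dynamic Cell Area (DCA) rises approximately linearly with Cell Speed. A
single ordinary-least-squares fit pooled over all valid observations,

    DCA = k·speed + m,

defines Corrected Membrane Dynamics as the residual

    CMD = DCA − k·speed − m,

a speed-independent measure of how much membrane a cell keeps in dynamic
(protruding/retracting) domains relative to cells moving at the same speed.
By OLS construction CMD has zero mean and zero sample correlation with
speed.

This module also measures the net Δarea–speed coupling (fast cells shrink,
slow cells grow), per-trajectory speed autocorrelation (persistence of
speed), and the column-normalized conditional-density histograms used to
visualize these couplings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .masks import DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "CmdFit",
    "AutocorrResult",
    "fit_linear",
    "compute_cmd",
    "delta_area_coupling",
    "speed_autocorrelation",
    "trajectory_autocorrelation",
    "conditional_density",
]


@dataclass
class CmdFit:
    """Global linear fit of Dynamic Cell Area on Cell Speed."""

    k: float  # slope, μm² per (μm/min)
    m: float  # intercept, μm²
    n_obs: int
    pearson_r: float
    residuals: np.ndarray  # CMD per observation, μm²


def fit_linear(speed: np.ndarray, dca: np.ndarray) -> CmdFit:
    """OLS of dynamic cell area on speed; residuals are the CMD values."""
    speed = np.asarray(speed, float)
    dca = np.asarray(dca, float)
    ok = np.isfinite(speed) & np.isfinite(dca)
    speed, dca = speed[ok], dca[ok]
    if len(speed) < 3:
        raise ValueError("need at least 3 paired observations")
    if speed.std() == 0:
        raise ValueError("speed has zero variance; slope undefined")
    res = stats.linregress(speed, dca)
    residuals = dca - res.slope * speed - res.intercept
    return CmdFit(
        k=float(res.slope),
        m=float(res.intercept),
        n_obs=len(speed),
        pearson_r=float(res.rvalue),
        residuals=residuals,
    )


def compute_cmd(table: pd.DataFrame, fit: CmdFit | None = None) -> pd.DataFrame:
    """Add/overwrite the ``cmd`` column as the residual of the global fit.

    When ``fit`` is None it is computed from the table's valid rows. Rows
    with missing speed or dynamic area get NaN and are marked invalid.
    """
    out = table.copy()
    valid = out["valid"].to_numpy(bool) if "valid" in out else np.ones(len(out), bool)
    speed = out["cell_speed"].to_numpy(float)
    dca = out["dynamic_cell_area"].to_numpy(float)
    if fit is None:
        fit = fit_linear(speed[valid], dca[valid])
    cmd = dca - fit.k * speed - fit.m
    missing = ~(np.isfinite(speed) & np.isfinite(dca))
    cmd[missing] = np.nan
    out["cmd"] = cmd
    if "valid" in out:
        out.loc[missing, "valid"] = False
    return out


def delta_area_coupling(
    table: pd.DataFrame, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> tuple[float, float]:
    """Pearson r and OLS slope of net area change versus speed.

    Δarea = (protrusion_pixels − retraction_pixels)·pixel_size², μm² per
    frame. A negative r reproduces the observation that fast-moving cells
    tend to shrink while slow cells grow.
    """
    valid = table["valid"].to_numpy(bool) if "valid" in table else np.ones(len(table), bool)
    t = table[valid]
    delta = (
        t["protrusion_pixels"].to_numpy(float) - t["retraction_pixels"].to_numpy(float)
    ) * pixel_size_um**2
    speed = t["cell_speed"].to_numpy(float)
    ok = np.isfinite(delta) & np.isfinite(speed)
    res = stats.linregress(speed[ok], delta[ok])
    return float(res.rvalue), float(res.slope)


def trajectory_autocorrelation(
    series: np.ndarray, max_lag: int = 12, estimator: str = "biased"
) -> np.ndarray:
    """Zero-lag-normalized autocovariance of one speed series, lags 0..max_lag.

    Missing values are replaced by the trace mean before mean-centering.
    With the default ``'biased'`` estimator the coefficient at lag ℓ is
    Σₜ x(t)x(t+ℓ) / Σₜ x(t)² (sums not rescaled by the number of terms per
    lag, the default of the covariance routines common in signal-processing
    toolboxes); ``'unbiased'`` rescales each lag's sum by n/(n−ℓ).
    """
    if estimator not in ("biased", "unbiased"):
        raise ValueError("estimator must be 'biased' or 'unbiased'")
    x = np.asarray(series, float).copy()
    miss = ~np.isfinite(x)
    if miss.all():
        raise ValueError("series has no observed values")
    x[miss] = x[~miss].mean()
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("zero-variance series: autocorrelation undefined")
    n = len(x)
    coeffs = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        if lag >= n:
            coeffs[lag] = np.nan
            continue
        c = float(np.dot(x[: n - lag], x[lag:])) / denom
        if estimator == "unbiased":
            c *= n / (n - lag)
        coeffs[lag] = c
    return coeffs


@dataclass
class AutocorrResult:
    """Per-cell speed-persistence summary and its population coupling."""

    per_cell: pd.DataFrame  # cell_trace_id, mean_speed, mean_autocorr, acf_1..acf_L
    pearson_r: float  # corr(mean_autocorr, mean_speed) over cells
    p_value: float
    max_lag: int


def speed_autocorrelation(
    table: pd.DataFrame, max_lag: int = 12, min_length: int | None = None
) -> AutocorrResult:
    """Per-trajectory speed autocorrelation versus mean speed.

    For each cell trace (ordered by frame number) the autocorrelation
    coefficients at lags 1..max_lag are averaged into one persistence
    score; the population-level Pearson r between that score and the
    cell's mean speed quantifies whether fast cells sustain their speed.
    Traces shorter than ``min_length`` (default max_lag + 1) or with zero
    variance are excluded with a warning.
    """
    if min_length is None:
        min_length = max_lag + 1
    rows = []
    skipped = 0
    for cell, grp in table.groupby("cell_trace_id", sort=False):
        g = grp.sort_values("frame_number")
        s = g["cell_speed"].to_numpy(float)
        if len(s) < min_length:
            skipped += 1
            continue
        try:
            coeffs = trajectory_autocorrelation(s, max_lag)
        except ValueError:
            skipped += 1
            continue
        rec = {
            "cell_trace_id": cell,
            "mean_speed": float(np.nanmean(s)),
            "mean_autocorr": float(np.nanmean(coeffs[1:])),
        }
        rec.update({f"acf_{lag}": coeffs[lag] for lag in range(1, max_lag + 1)})
        rows.append(rec)
    if skipped:
        warnings.warn(f"{skipped} trace(s) excluded (too short or zero variance)")
    per_cell = pd.DataFrame(rows)
    if len(per_cell) >= 3:
        r, p = stats.pearsonr(per_cell["mean_autocorr"], per_cell["mean_speed"])
    else:
        r, p = np.nan, np.nan
    return AutocorrResult(per_cell=per_cell, pearson_r=float(r), p_value=float(p), max_lag=max_lag)


def conditional_density(
    x: np.ndarray,
    y: np.ndarray,
    x_bins: int | np.ndarray = 50,
    y_bins: int | np.ndarray = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """log10 of a bivariate histogram column-normalized within each x bin.

    Each x-bin's counts are normalized to total 1 before taking log10, so
    columns are comparable regardless of how many observations fall in
    them (the marginal density of x is divided out). Empty cells are NaN.

    Returns ``(matrix, x_edges, y_edges)`` with matrix shape
    (n_y_bins, n_x_bins).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    counts, x_edges, y_edges = np.histogram2d(x[ok], y[ok], bins=[x_bins, y_bins])
    col_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = counts / col_tot
        out = np.log10(norm)
    out[~np.isfinite(out)] = np.nan
    return out.T, x_edges, y_edges
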