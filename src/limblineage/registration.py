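"""Temporal registration of growth curves between replicate limbs.

Replicate limbs imaged at different temperatures develop at different
speeds; their cell-number growth curves can be superimposed by a single
linear rescaling of the time axis.  The scale factor is estimated by
least squares on the step-interpolated counts over a common evaluation
grid: a coarse scan over the admissible scale range followed by a local
golden-section refinement.  Only time is rescaled — counts are never
scaled, since the correction is for tempo, not size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .model import GrowthCurve

__all__ = [
    "ScaleFit",
    "resample_curve",
    "fit_temporal_scale",
    "read_curve_csv",
    "write_curve_csv",
]


@dataclass
class ScaleFit:
    """Result of a linear temporal registration.

    ``scale`` multiplies the moving curve's time axis to match the
    reference; ``residual`` is the sum of squared count differences on the
    evaluation ``grid``.
    """

    scale: float
    residual: float
    grid: np.ndarray


def resample_curve(curve: GrowthCurve, grid: np.ndarray) -> np.ndarray:
    """Step (previous-value) interpolation of counts onto ``grid``.

    Cell number is a piecewise-constant function of time, so queries
    between two events return the earlier event's count.  Grid points
    outside the curve's time span raise ``ValueError``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < curve.times[0] - 1e-9 or grid.max() > curve.times[-1] + 1e-9):
        raise ValueError("grid extends outside the curve's time span")
    idx = np.searchsorted(curve.times, grid + 1e-12, side="right") - 1
    idx = np.clip(idx, 0, len(curve.times) - 1)
    return curve.counts[idx]


def fit_temporal_scale(
    curve_ref: GrowthCurve,
    curve_mov: GrowthCurve,
    scale_bounds: tuple[float, float] = (0.5, 3.0),
    fit_span: tuple[float, float] | None = None,
    grid_step_hours: float = 0.5,
    scan_step: float = 0.01,
) -> ScaleFit:
    """Find the time-scale factor registering ``curve_mov`` onto ``curve_ref``.

    The moving curve's times are multiplied by the candidate scale; the
    objective is the squared count difference on a uniform grid over
    ``fit_span``.  With an explicit ``fit_span`` the grid is fixed and the
    objective is the plain sum of squares; by default the span adapts to
    each candidate scale — from 0 (the anchoring division) to the latest
    time inside both curves at that scale — and the objective is the mean
    square, so spans of different length stay comparable and the full
    overlap informs every candidate.  The scan step of 0.01 bounds the
    resolution of the estimate; a golden-section refinement around the
    scan optimum is kept only if it strictly improves the residual.
    """
    smin, smax = scale_bounds
    if not 0 < smin < smax:
        raise ValueError("scale_bounds must satisfy 0 < lower < upper")
    if fit_span is not None:
        lo, hi = fit_span
        if hi <= lo:
            raise ValueError("empty overlap between the curves on the fit span")
        grid = np.arange(lo, hi + 1e-9, grid_step_hours)
        ref_counts = resample_curve(curve_ref, grid)

        def objective(s: float) -> float:
            query = grid / s
            if (
                query.min() < curve_mov.times[0] - 1e-9
                or query.max() > curve_mov.times[-1] + 1e-9
            ):
                return np.inf
            return float(np.sum((ref_counts - resample_curve(curve_mov, query)) ** 2))

    else:
        lo0 = max(curve_ref.times[0], 0.0)

        def objective(s: float) -> float:
            hi = min(curve_ref.times[-1], s * curve_mov.times[-1])
            if hi <= lo0 or lo0 / s < curve_mov.times[0] - 1e-9:
                return np.inf
            grid = np.arange(lo0, hi + 1e-9, grid_step_hours)
            ref_counts = resample_curve(curve_ref, grid)
            return float(np.mean((ref_counts - resample_curve(curve_mov, grid / s)) ** 2))

        grid = np.arange(lo0, curve_ref.times[-1] + 1e-9, grid_step_hours)

    scales = np.arange(smin, smax + scan_step / 2, scan_step)
    residuals = np.array([objective(s) for s in scales])
    r_min = residuals.min()
    if not np.isfinite(r_min):
        raise ValueError("no admissible scale in bounds produces a valid overlap")
    # step curves make the objective piecewise constant; break exact ties
    # toward the unit scale (no correction when the data cannot tell)
    tied = np.flatnonzero(residuals <= r_min + 1e-12)
    best = int(tied[np.argmin(np.abs(scales[tied] - 1.0))])
    s_best, r_best = float(scales[best]), float(residuals[best])

    window = (
        float(scales[max(best - 1, 0)]),
        float(scales[min(best + 1, len(scales) - 1)]),
    )
    if window[1] > window[0]:
        res = minimize_scalar(
            lambda s: float(np.nan_to_num(objective(s), posinf=1e30)),
            bounds=window,
            method="bounded",
        )
        if res.success and res.fun < r_best:
            s_best, r_best = float(res.x), float(res.fun)
    return ScaleFit(scale=s_best, residual=r_best, grid=grid)


def read_curve_csv(path: str | Path) -> GrowthCurve:
    """Read a growth curve from a two-column CSV (time_hours, count)."""
    df = pd.read_csv(path)
    for col in ("time_hours", "count"):
        if col not in df.columns:
            raise ValueError(f"curve CSV missing column {col!r}")
    return GrowthCurve(times=df["time_hours"].to_numpy(), counts=df["count"].to_numpy())


def write_curve_csv(curve: GrowthCurve, path: str | Path) -> None:
    pd.DataFrame({"time_hours": curve.times, "count": curve.counts}).to_csv(path, index=False)
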