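"""Outlier Winsorization, robust scale estimation and missing-value imputation.

Copy number tracks carry frequent single-probe outliers (technical spikes or
very short biological events).  Least-squares segmentation is sensitive to
them, so observations are Winsorized before fitting: a running-median trend
is subtracted, the residual scale is estimated robustly via the MAD, and
residuals beyond ``tau * s`` are clipped to that bound.  The same module
provides the difference-based residual-SD estimate used to scale the
segmentation penalty per sample, and a nearest-neighbour mean imputation for
missing probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io import ArmPartition, CopyNumberTable, assign_arms

__all__ = [
    "WinsorParams",
    "ScaleEstimate",
    "psi_clip",
    "median_filter_trend",
    "mad_scale",
    "winsorize",
    "winsorize_values",
    "estimate_residual_sd",
    "impute_missing",
]

#: consistency factor making the MAD estimate the SD for Gaussian data
MAD_CONSTANT = 1.4826

#: floor applied to a degenerate (zero) scale estimate
SCALE_FLOOR = 1e-12


@dataclass(frozen=True)
class WinsorParams:
    """Winsorization settings.

    tau
        Clipping multiple: residuals are clipped at ``tau * s`` where ``s``
        is the MAD-based residual SD.  Typical values lie in [1.5, 3];
        default 2.5.
    k_trend
        Half-width (in probes) of the running-median trend window; the
        window at probe j is j-k..j+k, shrunk at the arm boundaries.
    iterate, n_iter
        Optional refinement: re-estimate the trend from a piecewise
        constant fit to the Winsorized values and clip again n_iter times.
    """

    tau: float = 2.5
    k_trend: int = 25
    iterate: bool = False
    n_iter: int = 1

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.k_trend < 1:
            raise ValueError("k_trend must be >= 1")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass(frozen=True)
class ScaleEstimate:
    """A robust SD estimate (log2-ratio units) with a method tag."""

    s: float
    method: str = "mad"

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("scale must be >= 0")


def psi_clip(x, theta: float):
    """Clip ``x`` to the interval [-theta, theta] (the Winsorizing transform)."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    return np.clip(x, -theta, theta)


def median_filter_trend(y, k: int) -> np.ndarray:
    """Running median of ``y`` with half-width ``k`` and shrinking edge windows.

    The window at index j is y[max(0, j-k) .. min(p-1, j+k)]; no padding is
    invented at the boundaries.  Even-sized windows use the average of the
    two central order statistics.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if k < 1:
        raise ValueError("k must be >= 1")
    p = y.size
    if p <= 2 * k + 1:
        return np.array([np.median(y[max(0, j - k): j + k + 1]) for j in range(p)])
    out = np.empty(p)
    win = np.lib.stride_tricks.sliding_window_view(y, 2 * k + 1)
    out[k: p - k] = np.median(win, axis=1)
    for j in range(k):
        out[j] = np.median(y[: j + k + 1])
        out[p - 1 - j] = np.median(y[p - 1 - j - k:])
    return out


def mad_scale(x) -> ScaleEstimate:
    """MAD-based SD estimate ``s = 1.4826 * median(|x - median(x)|)``."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    s = MAD_CONSTANT * float(np.median(np.abs(x - np.median(x))))
    return ScaleEstimate(s=s, method="mad")


def _floored_scale(s: float) -> float:
    if s <= 0:
        warnings.warn(
            "degenerate (zero) residual scale; flooring at 1e-12 — "
            "all residuals will be clipped to the trend",
            stacklevel=3,
        )
        return SCALE_FLOOR
    return s


def winsorize_values(y: np.ndarray, params: WinsorParams | None = None) -> np.ndarray:
    """Winsorize one observed (non-missing) sequence from a single arm.

    The trend is a running median, the residual scale the MAD estimate and
    values are replaced by ``trend + clip(residual, tau * s)``.  With
    ``params.iterate`` the trend is re-estimated ``n_iter`` times from a
    piecewise constant fit to the current Winsorized values.
    """
    params = params or WinsorParams()
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observed values per sample/arm")
    trend = median_filter_trend(y, params.k_trend)
    out = _clip_to_trend(y, trend, params.tau)
    if params.iterate:
        from .single import PenaltySpec, pcf_exact

        for _ in range(params.n_iter):
            fit = pcf_exact(out, PenaltySpec())
            out = _clip_to_trend(y, fit.fitted(), params.tau)
    return out


def _clip_to_trend(y: np.ndarray, trend: np.ndarray, tau: float) -> np.ndarray:
    resid = y - trend
    s = _floored_scale(mad_scale(resid).s)
    return trend + psi_clip(resid, tau * s)


def winsorize(
    table: CopyNumberTable,
    params: WinsorParams | None = None,
    arms: ArmPartition | None = None,
) -> CopyNumberTable:
    """Winsorize every sample/arm of a table; missing values stay missing."""
    params = params or WinsorParams()
    labels = assign_arms(table, arms) if arms is not None else None
    values = table.values.copy()
    for _, _, idx in table.iter_arms(labels):
        for i in range(table.n_samples):
            obs = idx[~np.isnan(values[i, idx])]
            if obs.size < 2:
                continue
            values[i, obs] = winsorize_values(values[i, obs], params)
    return CopyNumberTable(
        chrom=table.chrom, pos=table.pos, sample_ids=list(table.sample_ids), values=values
    )


def estimate_residual_sd(y) -> ScaleEstimate:
    """Difference-based robust residual SD for penalty scaling.

    For one arm the estimate is ``mad(diff(y)) / sqrt(2)``: lag-1
    differences cancel the piecewise constant signal (up to the few probes
    at true breakpoints, which the MAD ignores), so the estimate tracks the
    noise SD rather than the segment structure.  A list/tuple of per-arm
    sequences is aggregated as the median of the arm estimates.
    """
    if isinstance(y, (list, tuple)) and y and np.ndim(y[0]) >= 1:
        return ScaleEstimate(
            s=float(np.median([estimate_residual_sd(a).s for a in y])),
            method="diff-mad",
        )
    y = np.asarray(y, dtype=float)
    y = y[~np.isnan(y)]
    if y.size < 3:
        raise ValueError("need at least 3 non-missing values")
    s = mad_scale(np.diff(y)).s / np.sqrt(2.0)
    return ScaleEstimate(s=s, method="diff-mad")


def impute_missing(
    table: CopyNumberTable, arms: ArmPartition | None = None
) -> CopyNumberTable:
    """Replace missing probe values by the mean of the nearest observed
    neighbour on each side within the arm (one-sided at arm boundaries)."""
    labels = assign_arms(table, arms) if arms is not None else None
    values = table.values.copy()
    for chrom, arm, idx in table.iter_arms(labels):
        for i in range(table.n_samples):
            v = values[i, idx]
            if not np.isnan(v).any():
                continue
            values[i, idx] = impute_sequence(v, where=f"sample {table.sample_ids[i]}, {chrom}{arm}")
    return CopyNumberTable(
        chrom=table.chrom, pos=table.pos, sample_ids=list(table.sample_ids), values=values
    )


def impute_sequence(v: np.ndarray, where: str = "sequence") -> np.ndarray:
    """Nearest-observed-neighbour mean imputation of one arm's values."""
    v = np.asarray(v, dtype=float).copy()
    obs = np.flatnonzero(~np.isnan(v))
    if obs.size == 0:
        raise ValueError(f"{where}: all values missing; cannot impute")
    miss = np.flatnonzero(np.isnan(v))
    right = np.searchsorted(obs, miss)  # index of nearest observed to the right
    left = right - 1
    lval = np.where(left >= 0, v[obs[np.clip(left, 0, None)]], np.nan)
    rval = np.where(right < obs.size, v[obs[np.clip(right, None, obs.size - 1)]], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v[miss] = np.nanmean(np.vstack([lval, rval]), axis=0)
    return v
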