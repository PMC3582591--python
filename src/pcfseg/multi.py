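"""Joint multi-sample PCF: common breakpoints across samples.

The joint criterion is the sum over samples of the single-sample penalized
criterion evaluated at one common segmentation S, so every new segment
costs n * gamma.  The dynamic program is the single-sample recursion with
the candidate-cost vector summed over samples: at step k,

    d_k = - 1^T (A_k * A_k) / (k:1),    e_k = min(d_k + e_{k-1} + n*gamma),

where A_k holds per-sample running sums.  Because noise levels differ
between samples, each sample is by default divided by its difference-based
residual SD before fitting (and segment means are reported on the original
scale); optional user weights w_i multiply the normalized tracks, e.g. to
down-weight samples with low tumor content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import estimate_residual_sd
from .single import PenaltySpec, Segmentation, _backtrack, criterion_value

__all__ = ["MultiSegmentation", "multipcf", "summed_criterion"]


@dataclass
class MultiSegmentation:
    """A common segmentation of n tracks: shared starts, per-track means."""

    start_indices: np.ndarray
    means: np.ndarray  # (M, n)
    total_cost: float
    n_probes: int
    gamma_effective: float = field(default=np.nan)

    @property
    def n_segments(self) -> int:
        return self.start_indices.size

    @property
    def n_tracks(self) -> int:
        return self.means.shape[1]

    @property
    def lengths(self) -> np.ndarray:
        bounds = np.append(self.start_indices, self.n_probes + 1)
        return np.diff(bounds)

    def fitted(self) -> np.ndarray:
        """(n, p) per-probe fitted values."""
        return np.repeat(self.means.T, self.lengths, axis=1)

    def track(self, i: int) -> Segmentation:
        """View of one track as a single-sample segmentation."""
        return Segmentation(
            start_indices=self.start_indices,
            means=self.means[:, i],
            total_cost=np.nan,
            n_probes=self.n_probes,
        )


def _dp_multi(Y: np.ndarray, gamma_per_seg: float, kmin: int) -> np.ndarray:
    n, p = Y.shape
    A = np.zeros((n, p))
    e = np.empty(p + 1)
    e[0], e[1:] = 0.0, np.inf
    t = np.zeros(p + 1, dtype=np.int64)
    desc = np.arange(p, 0, -1, dtype=float)
    cand = np.empty(p)
    for k in range(1, p + 1):
        A[:, :k] += Y[:, k - 1][:, None]
        np.einsum("ij,ij->j", A[:, :k], A[:, :k], out=cand[:k])
        np.divide(cand[:k], desc[p - k:], out=cand[:k])
        np.subtract(e[:k], cand[:k], out=cand[:k])
        lim = max(k - kmin + 1, 0)
        if lim < k:
            cand[lim:k] = np.inf
        j = int(np.argmin(cand[:k]))
        e[k] = cand[j] + gamma_per_seg
        t[k] = j + 1
    return t


def _track_scales(Y: np.ndarray, weights) -> np.ndarray:
    n = Y.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w <= 0):
        raise ValueError("weights must be positive, one per sample")
    scale = np.empty(n)
    for i in range(n):
        try:
            s = estimate_residual_sd(Y[i]).s
        except ValueError:
            s = 0.0
        scale[i] = s if np.isfinite(s) and s > 0 else 1.0
    return w / scale


def multipcf(Y, penalty: PenaltySpec | None = None, weights=None) -> MultiSegmentation:
    """Optimal common segmentation of an (n, p) matrix of tracks.

    Minimizes the summed penalized criterion over segmentations shared by
    all samples, subject to the kmin constraint.  With ``penalty.normalize``
    each sample is pre-scaled by ``w_i / sd_i``; reported means are always
    arithmetic averages of the input values.
    """
    penalty = penalty or PenaltySpec()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = Y.shape
    if n == 0 or p == 0:
        raise ValueError("empty track matrix")
    if np.isnan(Y).any():
        raise ValueError("missing values present; impute per sample first")
    if penalty.normalize:
        factors = _track_scales(Y, weights)
    elif weights is not None:
        factors = np.asarray(weights, dtype=float)
        if factors.shape != (n,) or np.any(factors <= 0):
            raise ValueError("weights must be positive, one per sample")
    else:
        factors = np.ones(n)
    Ys = Y * factors[:, None]
    gamma_per_seg = n * penalty.gamma
    if p < penalty.kmin:
        warnings.warn(
            f"{p} probes is shorter than kmin={penalty.kmin}; returning one segment",
            stacklevel=2,
        )
        starts = np.array([1], dtype=np.int64)
    else:
        t = _dp_multi(Ys, gamma_per_seg, penalty.kmin)
        starts = _backtrack(t, p)
    bounds = np.append(starts - 1, p)
    sums = np.add.reduceat(Y, bounds[:-1], axis=1)
    means = (sums / np.diff(bounds)).T  # (M, n)
    cost = summed_criterion(starts, Ys, penalty.gamma)
    return MultiSegmentation(
        start_indices=starts,
        means=means,
        total_cost=cost,
        n_probes=p,
        gamma_effective=penalty.gamma,
    )


def summed_criterion(segmentation, Y, gamma: float) -> float:
    """Joint criterion: per-sample penalized criterion summed over samples."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    starts = (
        segmentation.start_indices
        if isinstance(segmentation, MultiSegmentation)
        else np.asarray(segmentation, dtype=np.int64)
    )
    return float(sum(criterion_value(starts, Y[i], gamma) for i in range(Y.shape[0])))
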