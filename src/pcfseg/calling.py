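"""Threshold-based aberration calling and frequency summaries.

After segmentation, each probe carries a fitted copy number level; probes
with fitted value above ``theta_plus`` are called gains, below
``-theta_minus`` losses, and everything else (including exact threshold
equality) normal.  Frequencies of gains/losses across samples summarize
recurrent aberrations, and a penalty-diagnostics table tabulates segment
counts and residual variance over a gamma grid to guide penalty choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .single import PenaltySpec, pcf_exact

__all__ = [
    "CallTrack",
    "call_aberrations",
    "aberration_frequencies",
    "gamma_diagnostics",
    "LOSS",
    "NORMAL",
    "GAIN",
]

LOSS, NORMAL, GAIN = -1, 0, 1
_LABELS = {LOSS: "loss", NORMAL: "normal", GAIN: "gain"}


@dataclass
class CallTrack:
    """Per-probe, per-sample three-way calls (-1 loss, 0 normal, +1 gain)."""

    calls: np.ndarray  # (n_samples, n_probes) int8
    theta_plus: float
    theta_minus: float

    @property
    def labels(self) -> np.ndarray:
        return np.vectorize(_LABELS.get)(self.calls)


def call_aberrations(
    fitted, theta_plus: float = 0.1, theta_minus: float | None = None
) -> CallTrack:
    """Classify fitted values: gain if > theta_plus, loss if < -theta_minus.

    ``theta_minus`` defaults to ``theta_plus``.  Inequalities are strict, so
    a value exactly at a threshold is called normal.
    """
    if theta_minus is None:
        theta_minus = theta_plus
    if theta_plus <= 0 or theta_minus <= 0:
        raise ValueError("calling thresholds must be > 0")
    z = np.atleast_2d(np.asarray(fitted, dtype=float))
    calls = np.zeros(z.shape, dtype=np.int8)
    calls[z > theta_plus] = GAIN
    calls[z < -theta_minus] = LOSS
    return CallTrack(calls=calls, theta_plus=theta_plus, theta_minus=theta_minus)


def aberration_frequencies(calls: CallTrack) -> pd.DataFrame:
    """Fraction of samples called gain / loss / normal at each probe."""
    c = calls.calls
    if c.size == 0:
        raise ValueError("empty call track")
    n = c.shape[0]
    return pd.DataFrame(
        {
            "gain.freq": (c == GAIN).sum(axis=0) / n,
            "loss.freq": (c == LOSS).sum(axis=0) / n,
            "normal.freq": (c == NORMAL).sum(axis=0) / n,
        }
    )


def gamma_diagnostics(
    y, gammas, kmin: int = 1, normalize: bool = True
) -> pd.DataFrame:
    """Segment count and residual variance of the PCF fit per penalty value.

    Residual variance is mean((y - fitted)^2); it is non-decreasing in
    gamma since larger penalties admit fewer segments.
    """
    y = np.asarray(y, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    if gammas.size == 0:
        raise ValueError("empty gamma grid")
    rows = []
    for g in np.sort(gammas):
        fit = pcf_exact(y, PenaltySpec(gamma=float(g), kmin=kmin, normalize=normalize))
        resid = y - fit.fitted()
        rows.append((float(g), fit.n_segments, float(np.mean(resid**2))))
    return pd.DataFrame(rows, columns=["gamma", "n.segments", "residual.variance"])
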