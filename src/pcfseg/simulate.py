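"""Synthetic data generators and brute-force oracles for the PCF family.

The generators reproduce the simulation designs the segmentation methods
are evaluated on: pure-noise null sequences (optionally with
contaminated-normal outliers), piecewise-constant profiles with known
breakpoints, and paired logR/BAF SNP tracks with allele-specific events.
The oracles solve the same penalized criteria by exhaustive enumeration at
small p, providing an implementation-independent correctness reference for
the dynamic programs, plus benchmark routines for null false-call rates,
contaminated-normal tail fractions, and the effect of Winsorization on
false breakpoint detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .preprocess import WinsorParams, mad_scale, winsorize_values
from .single import PenaltySpec, pcf_exact

__all__ = [
    "ContaminationSpec",
    "SimulatedProfile",
    "brute_force_pcf",
    "dp_reference",
    "simulate_null",
    "simulate_profile",
    "simulate_snp_tracks",
    "false_call_rate",
    "tail_fractions",
    "winsorization_study",
]


@dataclass(frozen=True)
class ContaminationSpec:
    """Contaminated-normal noise: N(0, sigma^2) with probability 1 - alpha,
    N(0, (d*sigma)^2) with probability alpha (typically alpha=0.05, d=3)."""

    alpha: float = 0.05
    d: float = 3.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        noise = rng.standard_normal(size) * self.sigma
        if self.alpha > 0:
            outlier = rng.random(size) < self.alpha
            noise[outlier] *= self.d
        return noise


@dataclass
class SimulatedProfile:
    """A generated track with its ground truth.

    breakpoints are the true 1-based segment start indices (first entry 1);
    levels the true segment means.  Regenerating with the same seed
    reproduces values bit-identically.
    """

    values: np.ndarray
    breakpoints: np.ndarray
    levels: np.ndarray
    seed: int | None = None
    baf: np.ndarray | None = None
    baf_levels: np.ndarray | None = field(default=None)


# ---------------------------------------------------------------------------
# exhaustive oracles


def _iter_segmentations(p: int, kmin: int):
    """All 1-based start-index tuples whose segments are each >= kmin long."""
    for m in range(p // kmin):
        for bp in combinations(range(2, p + 1), m):
            starts = (1,) + bp
            bounds = starts + (p + 1,)
            if all(bounds[i + 1] - bounds[i] >= kmin for i in range(len(starts))):
                yield np.asarray(starts, dtype=np.int64)


def brute_force_pcf(y, gamma: float, kmin: int = 1, max_p: int = 16):
    """Exhaustive minimizer of the penalized criterion; the oracle for the DP.

    ``y`` may be one sequence or an (n, p) matrix, in which case the summed
    multi-track criterion (penalty n*gamma per segment) is minimized.
    Returns ``(start_indices, cost)``; ties go to the lexicographically
    smallest breakpoint set.  Enumerates all 2^(p-1) segmentations, so p is
    capped at ``max_p``.
    """
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    n, p = Y.shape
    if p > max_p:
        raise ValueError(f"p={p} too large for exhaustive enumeration (max {max_p})")
    if p < kmin:
        starts = np.array([1], dtype=np.int64)
        return starts, _joint_cost(Y, starts, gamma)
    best_cost = np.inf
    best = None
    for starts in _iter_segmentations(p, kmin):
        cost = _joint_cost(Y, starts, gamma)
        if cost < best_cost - 1e-13 or (
            abs(cost - best_cost) <= 1e-13
            and best is not None
            and tuple(starts) < tuple(best)
        ):
            best_cost, best = cost, starts
    return best, float(best_cost)


def _joint_cost(Y: np.ndarray, starts: np.ndarray, gamma: float) -> float:
    bounds = np.append(starts - 1, Y.shape[1])
    total = 0.0
    for i in range(Y.shape[0]):
        sums = np.add.reduceat(Y[i], bounds[:-1])
        total += np.sum(Y[i] ** 2) - np.sum(sums**2 / np.diff(bounds))
    return float(total + Y.shape[0] * gamma * starts.size)


def dp_reference(y, gamma: float, kmin: int = 1):
    """Naive double-loop forward recursion; returns (e, t) for comparison
    with the vectorized dynamic program."""
    y = np.asarray(y, dtype=float)
    p = y.size
    e = np.empty(p + 1)
    e[0], e[1:] = 0.0, np.inf
    t = np.zeros(p + 1, dtype=np.int64)
    for k in range(1, p + 1):
        best, arg = np.inf, 1
        for j in range(1, k + 1):
            if k - j + 1 < kmin:
                continue
            seg = y[j - 1: k]
            d = -seg.sum() ** 2 / seg.size
            cost = d + e[j - 1] + gamma
            if cost < best:
                best, arg = cost, j
        e[k] = best
        t[k] = arg
    return e, t


# ---------------------------------------------------------------------------
# generators


def simulate_null(
    p: int,
    n_seq: int,
    contamination: ContaminationSpec | None = None,
    seed: int = 0,
) -> list[SimulatedProfile]:
    """iid noise sequences with no underlying aberrations (truth: 1 segment)."""
    if p < 1 or n_seq < 1:
        raise ValueError("p and n_seq must be >= 1")
    spec = contamination or ContaminationSpec(alpha=0.0)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_seq):
        out.append(
            SimulatedProfile(
                values=spec.draw(rng, p),
                breakpoints=np.array([1], dtype=np.int64),
                levels=np.zeros(1),
                seed=seed,
            )
        )
    return out


def simulate_profile(
    segment_spec,
    noise: ContaminationSpec | None = None,
    seed: int = 0,
) -> SimulatedProfile:
    """Piecewise-constant profile from (length, level) pairs plus noise."""
    lengths = np.asarray([s[0] for s in segment_spec], dtype=np.int64)
    levels = np.asarray([s[1] for s in segment_spec], dtype=float)
    if np.any(lengths < 1):
        raise ValueError("segment lengths must be >= 1")
    signal = np.repeat(levels, lengths)
    rng = np.random.default_rng(seed)
    noise_spec = noise or ContaminationSpec(alpha=0.0)
    values = signal + (noise_spec.draw(rng, signal.size) if noise_spec.sigma > 0 else 0)
    breakpoints = np.concatenate([[1], 1 + np.cumsum(lengths[:-1])]).astype(np.int64)
    return SimulatedProfile(
        values=values, breakpoints=breakpoints, levels=levels, seed=seed
    )


#: logR / mirrored-BAF heterozygote levels per event for an aberrant-cell
#: fraction rho in a diploid background (total copies / B-allele copies)
def _event_levels(event: str, rho: float) -> tuple[float, float]:
    if event == "balanced":
        return 0.0, 0.5
    if event == "hemizygous_loss":  # one copy lost: total 2 - rho
        total = 2 - rho
        return float(np.log2(total / 2)), (1 - rho) / total
    if event == "gain":  # one copy of B gained: total 2 + rho
        total = 2 + rho
        return float(np.log2(total / 2)), min(1 + rho, total - (1 + rho)) / total
    if event == "cnloh":  # copy-neutral LOH: total 2, B copies 1 + rho
        return 0.0, (1 - rho) / 2
    raise ValueError(f"unknown event {event!r}")


def simulate_snp_tracks(
    event_spec,
    noise: ContaminationSpec | None = None,
    seed: int = 0,
    baf_sd: float = 0.03,
    hom_fraction: float = 0.33,
    aberrant_fraction: float = 0.5,
) -> SimulatedProfile:
    """Paired logR/BAF tracks from (length, event) pairs.

    Events: ``balanced`` (logR 0, BAF 0.5), ``hemizygous_loss`` (logR down,
    BAF imbalanced), ``gain`` (logR up, BAF imbalanced) and ``cnloh``
    (copy-neutral loss of heterozygosity: logR unchanged, BAF imbalanced —
    the case detectable only through the BAF track).  ``aberrant_fraction``
    is the fraction of aberrant cells, which attenuates both tracks as in
    real tumor samples; a ``hom_fraction`` share of probes is germline
    homozygous with BAF near 0/1.  BAF values are clipped to [0, 1].
    """
    if not 0 < aberrant_fraction <= 1:
        raise ValueError("aberrant_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    noise_spec = noise or ContaminationSpec(alpha=0.0, sigma=0.15)
    lengths = np.asarray([s[0] for s in event_spec], dtype=np.int64)
    events = [s[1] for s in event_spec]
    pairs = [_event_levels(ev, aberrant_fraction) for ev in events]
    logr_levels = np.asarray([c[0] for c in pairs])
    baf_levels = np.asarray([c[1] for c in pairs])
    logr = np.repeat(logr_levels, lengths) + noise_spec.draw(rng, int(lengths.sum()))
    het = np.repeat(baf_levels, lengths)
    flip = rng.random(het.size) < 0.5  # which allele carries the imbalance
    baf = np.where(flip, het, 1 - het)
    hom = rng.random(het.size) < hom_fraction
    baf[hom] = np.where(rng.random(hom.sum()) < 0.5, 0.0, 1.0)
    baf = np.clip(baf + rng.standard_normal(het.size) * baf_sd, 0.0, 1.0)
    breakpoints = np.concatenate([[1], 1 + np.cumsum(lengths[:-1])]).astype(np.int64)
    return SimulatedProfile(
        values=logr,
        breakpoints=breakpoints,
        levels=logr_levels,
        seed=seed,
        baf=baf,
        baf_levels=baf_levels,
    )


# ---------------------------------------------------------------------------
# benchmark routines


def false_call_rate(
    gamma: float,
    p: int = 10_000,
    n_seq: int = 20,
    kmin: int = 1,
    seed: int = 0,
    contamination: ContaminationSpec | None = None,
) -> float:
    """Falsely called aberrations per 10,000 probes on pure-noise sequences.

    Each fitted segment beyond the first on a null sequence counts as one
    false aberration; the total is rescaled per 10,000 probes.  Fitting uses
    the exact algorithm with variance-normalized penalty.
    """
    profiles = simulate_null(p, n_seq, contamination=contamination, seed=seed)
    penalty = PenaltySpec(gamma=gamma, kmin=kmin, normalize=True)
    extra = sum(pcf_exact(prof.values, penalty).n_segments - 1 for prof in profiles)
    return extra / (n_seq * p) * 10_000


def tail_fractions(
    spec: ContaminationSpec, n: int = 10**6, seed: int = 0
) -> tuple[float, float]:
    """Percent of mixture draws beyond 3 and 5 MAD-estimated SD units.

    Draws n values from the contaminated normal, estimates
    s = 1.4826 * MAD from the draws themselves, and returns the exceedance
    percentages (|x| > 3s, |x| > 5s).
    """
    rng = np.random.default_rng(seed)
    x = spec.draw(rng, n)
    s = mad_scale(x).s
    a = np.abs(x)
    return (
        float(np.mean(a > 3 * s) * 100.0),
        float(np.mean(a > 5 * s) * 100.0),
    )


def _false_breakpoints(fit_starts: np.ndarray, true_starts: np.ndarray, tol: int) -> int:
    fitted = fit_starts[fit_starts > 1]
    truth = true_starts[true_starts > 1]
    if fitted.size == 0:
        return 0
    if truth.size == 0:
        return fitted.size
    dist = np.min(np.abs(fitted[:, None] - truth[None, :]), axis=1)
    return int(np.sum(dist > tol))


def winsorization_study(
    n_seq: int = 10,
    gamma: float = 8.0,
    kmin: int = 1,
    sigma: float = 0.3,
    contamination_alpha: float = 0.05,
    contamination_d: float = 3.0,
    match_tol: int = 3,
    seed: int = 0,
) -> dict[str, float]:
    """False-breakpoint rates on planted-aberration profiles, per 10,000
    probes, under clean noise, contaminated noise, and contaminated noise
    followed by Winsorization.

    Profiles are 2000 probes with a handful of broad aberrations (heights
    around 1 log2 unit at noise SD ``sigma``); a fitted breakpoint counts as
    false when no true breakpoint lies within ``match_tol`` probes.  The
    contaminated runs add 5%-probability outliers with a 3-fold SD
    inflation, the classical contaminated-normal robustness model.
    """
    segment_spec = [
        (400, 0.0), (100, 1.0), (400, 0.0), (50, -1.0),
        (300, 0.0), (150, 0.8), (600, 0.0),
    ]
    p = sum(s[0] for s in segment_spec)
    penalty = PenaltySpec(gamma=gamma, kmin=kmin, normalize=True)
    clean = ContaminationSpec(alpha=0.0, sigma=sigma)
    contam = ContaminationSpec(
        alpha=contamination_alpha, d=contamination_d, sigma=sigma
    )
    counts = {"clean": 0, "contaminated": 0, "winsorized": 0}
    for r in range(n_seq):
        prof_clean = simulate_profile(segment_spec, clean, seed=seed + r)
        prof_cont = simulate_profile(segment_spec, contam, seed=seed + 10_000 + r)
        for key, values in (
            ("clean", prof_clean.values),
            ("contaminated", prof_cont.values),
            ("winsorized", winsorize_values(prof_cont.values, WinsorParams())),
        ):
            fit = pcf_exact(values, penalty)
            counts[key] += _false_breakpoints(
                fit.start_indices, prof_clean.breakpoints, match_tol
            )
    scale = 10_000 / (n_seq * p)
    return {k: v * scale for k, v in counts.items()}
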