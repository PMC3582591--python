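"""Allele-specific PCF: joint segmentation of paired logR / BAF SNP tracks.

A change in total copy number shifts the logR track; a change in allelic
balance shifts the B-allele frequency away from 0.5.  Some compound events
(e.g. loss of one copy of allele A followed by gain of one copy of B) leave
logR unchanged and move only BAF, so breakpoints must be detected jointly
on both tracks.  Preprocessing mirrors BAF around 0.5, drops (germline)
homozygous probes whose mirrored BAF falls below a threshold, and pairs
each logR probe with its nearest retained BAF probe, averaging logR values
sharing a BAF probe.  The two reduced tracks are then segmented jointly
with the multi-sample algorithm (two tracks, penalty 2*gamma per segment,
per-track variance normalization so the differently-scaled tracks
contribute comparably).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .multi import MultiSegmentation, multipcf
from .single import PenaltySpec

__all__ = [
    "BafLogRPair",
    "AllelePcfResult",
    "mirror_baf",
    "filter_homozygous",
    "pair_logr_to_baf",
    "aspcf",
]


@dataclass
class BafLogRPair:
    """Paired, filtered BAF/logR tracks ready for joint segmentation.

    positions are the genomic coordinates of the retained (informative) BAF
    probes; y1 the mirrored BAF values, y2 the paired/averaged logR values
    (equal length m <= original probe count); map[j] gives, for each
    original logR probe j, the index into the retained probes it was paired
    with.
    """

    positions: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    map: np.ndarray

    def __post_init__(self) -> None:
        if not (self.y1.size == self.y2.size == self.positions.size):
            raise ValueError("positions, y1, y2 must have equal length")


def mirror_baf(b):
    """Mirror BAF values around 0.5 (b > 0.5 becomes 1 - b); NaN passes through."""
    b = np.asarray(b, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((b < 0) | (b > 1)):
            raise ValueError("BAF values must lie in [0, 1]")
    return np.where(b > 0.5, 1.0 - b, b)


def filter_homozygous(b_mirrored, theta_baf: float = 0.1) -> np.ndarray:
    """Retention mask over mirrored BAF values.

    Probes with mirrored BAF below ``theta_baf`` are treated as germline
    homozygous (uninformative) and dropped, as are missing values.  Use
    ``theta_baf=0`` when homozygous probes have already been set to NA from
    a matched normal genotype.
    """
    if not 0 <= theta_baf <= 0.5:
        raise ValueError("theta_baf must lie in [0, 0.5]")
    b = np.asarray(b_mirrored, dtype=float)
    with np.errstate(invalid="ignore"):
        return ~np.isnan(b) & (b >= theta_baf) if theta_baf > 0 else ~np.isnan(b)


def pair_logr_to_baf(
    logr: np.ndarray, positions: np.ndarray, baf_retained_positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each logR probe to its nearest retained BAF probe and average.

    Returns ``(r_tilde, map)`` where ``r_tilde[t]`` is the mean of the logR
    values paired with retained BAF probe t and ``map[j]`` the retained-probe
    index of logR probe j.  Equidistant ties go to the leftward probe; a BAF
    probe receiving no logR probe gets the single globally nearest logR
    value.
    """
    logr = np.asarray(logr, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    q = np.asarray(baf_retained_positions, dtype=np.int64)
    if q.size == 0:
        raise ValueError("no retained BAF probes")
    right = np.searchsorted(q, positions)
    left = np.clip(right - 1, 0, q.size - 1)
    right = np.clip(right, 0, q.size - 1)
    dl = np.abs(positions - q[left])
    dr = np.abs(q[right] - positions)
    assign = np.where(dl <= dr, left, right)  # tie -> leftward probe
    sums = np.bincount(assign, weights=logr, minlength=q.size)
    counts = np.bincount(assign, minlength=q.size)
    empty = counts == 0
    if empty.any():
        for tdx in np.flatnonzero(empty):
            j = int(np.argmin(np.abs(positions - q[tdx])))
            sums[tdx], counts[tdx] = logr[j], 1
    return sums / counts, assign


@dataclass
class AllelePcfResult:
    """Joint segmentation of a (mirrored BAF, paired logR) track pair.

    Segment boundaries are shared between the tracks by construction.
    start_indices / positions refer to the reduced (retained-BAF) grid;
    orig_start_indices maps each segment start back to the first original
    logR probe paired into its first BAF probe.
    """

    segmentation: MultiSegmentation
    pair: BafLogRPair
    orig_start_indices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        # pairing assignment is monotone, so the first original probe mapped
        # into reduced probe t is found by a sorted search
        starts0 = self.segmentation.start_indices - 1
        self.orig_start_indices = (
            np.searchsorted(self.pair.map, starts0, side="left").astype(np.int64) + 1
        )

    @property
    def baf_means(self) -> np.ndarray:
        return self.segmentation.means[:, 0]

    @property
    def logr_means(self) -> np.ndarray:
        return self.segmentation.means[:, 1]


def aspcf(
    logr,
    baf,
    positions=None,
    penalty: PenaltySpec | None = None,
    theta_baf: float = 0.1,
) -> AllelePcfResult:
    """Allele-specific PCF on one arm's paired logR/BAF tracks.

    Runs mirroring, homozygote filtering and nearest-probe pairing, then the
    two-track joint segmentation on the reduced grid.  ``positions`` default
    to the probe index when omitted.  logR values must be non-missing
    (impute first); BAF values may be missing at copy-number-only probes.
    """
    penalty = penalty or PenaltySpec()
    logr = np.asarray(logr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    if logr.size != baf.size:
        raise ValueError("logR and BAF tracks must share the probe grid")
    if np.isnan(logr).any():
        raise ValueError("missing logR values; impute before segmentation")
    positions = (
        np.arange(1, logr.size + 1, dtype=np.int64)
        if positions is None
        else np.asarray(positions, dtype=np.int64)
    )
    b = mirror_baf(baf)
    keep = filter_homozygous(b, theta_baf)
    if not keep.any():
        raise ValueError("no informative BAF probes after filtering")
    kept_pos = positions[keep]
    r_tilde, assign = pair_logr_to_baf(logr, positions, kept_pos)
    pair = BafLogRPair(positions=kept_pos, y1=b[keep], y2=r_tilde, map=assign)
    seg = multipcf(np.vstack([pair.y1, pair.y2]), penalty)
    return AllelePcfResult(segmentation=seg, pair=pair)
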