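"""Table-level segmentation: loop arms and samples, assemble SegmentTables.

These are the high-level entry points mirroring the typical workflow:
(optionally Winsorized) probe tables in, per-arm segmentations out, with
penalty normalization on by default and automatic switching to the fast
algorithm on very long arms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .allele import aspcf
from .fast import pcf_fast
from .io import ArmPartition, CopyNumberTable, SegmentTable, assign_arms
from .multi import multipcf
from .preprocess import impute_sequence
from .single import PenaltySpec, pcf_exact

__all__ = ["segment_single", "segment_multi", "segment_allele", "fitted_values"]

#: arm length above which the fast algorithm is used when fast="auto"
FAST_THRESHOLD = 15000


def _arm_labels(table: CopyNumberTable, arms: ArmPartition | None):
    return assign_arms(table, arms) if arms is not None else None


def _use_fast(fast, p: int) -> bool:
    if fast == "auto":
        return p > FAST_THRESHOLD
    return bool(fast)


def _prep(values: np.ndarray) -> np.ndarray:
    return impute_sequence(values) if np.isnan(values).any() else values


def segment_single(
    table: CopyNumberTable,
    penalty: PenaltySpec | None = None,
    arms: ArmPartition | None = None,
    fast: bool | str = "auto",
) -> SegmentTable:
    """Independent PCF of every sample on every chromosome arm."""
    penalty = penalty or PenaltySpec()
    labels = _arm_labels(table, arms)
    rows = []
    for chrom, arm, idx in table.iter_arms(labels):
        pos = table.pos[idx]
        for i, sid in enumerate(table.sample_ids):
            y = _prep(table.values[i, idx])
            fit = (
                pcf_fast(y, penalty) if _use_fast(fast, y.size) else pcf_exact(y, penalty)
            )
            bounds = np.append(fit.start_indices - 1, y.size)
            for m in range(fit.n_segments):
                rows.append(
                    (
                        sid,
                        chrom,
                        arm,
                        int(pos[bounds[m]]),
                        int(pos[bounds[m + 1] - 1]),
                        int(bounds[m + 1] - bounds[m]),
                        float(fit.means[m]),
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=["sampleID", "chrom", "arm", "start.pos", "end.pos", "n.probes", "mean"],
    )
    return SegmentTable(df=df)


def segment_multi(
    table: CopyNumberTable,
    penalty: PenaltySpec | None = None,
    arms: ArmPartition | None = None,
    weights=None,
) -> SegmentTable:
    """Joint PCF with common breakpoints across all samples, per arm."""
    penalty = penalty or PenaltySpec()
    labels = _arm_labels(table, arms)
    rows = []
    for chrom, arm, idx in table.iter_arms(labels):
        pos = table.pos[idx]
        Y = np.vstack([_prep(table.values[i, idx]) for i in range(table.n_samples)])
        fit = multipcf(Y, penalty, weights=weights)
        bounds = np.append(fit.start_indices - 1, Y.shape[1])
        for m in range(fit.n_segments):
            rows.append(
                (
                    "multi",
                    chrom,
                    arm,
                    int(pos[bounds[m]]),
                    int(pos[bounds[m + 1] - 1]),
                    int(bounds[m + 1] - bounds[m]),
                    *[float(v) for v in fit.means[m]],
                )
            )
    cols = ["sampleID", "chrom", "arm", "start.pos", "end.pos", "n.probes"]
    cols += [f"mean.{s}" for s in table.sample_ids]
    return SegmentTable(df=pd.DataFrame(rows, columns=cols))


def segment_allele(
    logr_table: CopyNumberTable,
    baf_table: CopyNumberTable,
    penalty: PenaltySpec | None = None,
    arms: ArmPartition | None = None,
    theta_baf: float = 0.1,
) -> SegmentTable:
    """Allele-specific PCF per sample per arm on paired logR/BAF tables.

    The two tables must share the probe grid and sample order; the output
    carries one ``mean.logR`` and one ``mean.BAF`` column, with coordinates
    mapped back to the original logR probes.
    """
    penalty = penalty or PenaltySpec()
    if not np.array_equal(logr_table.pos, baf_table.pos) or not np.array_equal(
        logr_table.chrom, baf_table.chrom
    ):
        raise ValueError("logR and BAF tables must share the probe grid")
    if logr_table.sample_ids != baf_table.sample_ids:
        raise ValueError("logR and BAF tables must share the sample list")
    labels = _arm_labels(logr_table, arms)
    rows = []
    for chrom, arm, idx in logr_table.iter_arms(labels):
        pos = logr_table.pos[idx]
        for i, sid in enumerate(logr_table.sample_ids):
            logr = _prep(logr_table.values[i, idx])
            res = aspcf(
                logr, baf_table.values[i, idx], positions=pos,
                penalty=penalty, theta_baf=theta_baf,
            )
            starts0 = res.orig_start_indices - 1
            bounds = np.append(starts0, logr.size)
            for m in range(res.segmentation.n_segments):
                rows.append(
                    (
                        sid,
                        chrom,
                        arm,
                        int(pos[bounds[m]]),
                        int(pos[bounds[m + 1] - 1]),
                        int(bounds[m + 1] - bounds[m]),
                        float(res.logr_means[m]),
                        float(res.baf_means[m]),
                    )
                )
    cols = [
        "sampleID", "chrom", "arm", "start.pos", "end.pos", "n.probes",
        "mean.logR", "mean.BAF",
    ]
    return SegmentTable(df=pd.DataFrame(rows, columns=cols))


def fitted_values(segments: SegmentTable, table: CopyNumberTable) -> np.ndarray:
    """Expand a single-sample SegmentTable to per-probe fitted values
    aligned with ``table`` (n_samples x n_probes)."""
    out = np.full((table.n_samples, table.n_probes), np.nan)
    sample_index = {s: i for i, s in enumerate(table.sample_ids)}
    for _, r in segments.df.iterrows():
        i = sample_index.get(r["sampleID"])
        if i is None:
            continue
        mask = (
            (table.chrom == r["chrom"])
            & (table.pos >= r["start.pos"])
            & (table.pos <= r["end.pos"])
        )
        out[i, mask] = r["mean"]
    return out
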