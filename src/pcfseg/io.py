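"""Probe-level and segment-level data containers and their TSV readers/writers.

The probe-level container (:class:`CopyNumberTable`) holds normalized log2
copy number ratios (or B-allele frequencies) on an ordered genomic probe
grid with one track per sample.  Segmentation results are returned as a
:class:`SegmentTable`, which can be written in a native tab-separated
dialect or as an IGV ``.seg`` file.  Chromosome arms are derived from a
centromere table (:class:`ArmPartition`); segmentation never crosses a
centromere.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .centromeres import HG19_CENTROMERES

__all__ = [
    "CopyNumberTable",
    "ArmPartition",
    "SegmentTable",
    "read_copynumber_table",
    "write_copynumber_table",
    "assign_arms",
    "write_segments",
    "read_segments",
]

NA_TOKEN = "NA"

#: canonical ordering of human chromosome labels; unknown labels sort after
#: these, alphabetically.
_CHROM_RANK = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def chromosome_sort_key(label: str) -> tuple[int, str]:
    return (_CHROM_RANK.get(label, 100), label)


def normalize_chromosome(label: str) -> str:
    """Strip a leading ``chr`` prefix; labels are otherwise kept verbatim."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


@dataclass
class CopyNumberTable:
    """Probe-by-sample matrix of log2 ratios (or BAF values) on a sorted grid.

    Parameters
    ----------
    chrom, pos
        Chromosome label and 1-based genomic coordinate per probe, strictly
        sorted by (chromosome, position) with no duplicates.
    sample_ids
        Ordered sample labels.
    values
        ``(n_samples, n_probes)`` float matrix; missing entries are NaN.
    """

    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        p = self.pos.size
        if self.chrom.size != p:
            raise ValueError("chrom and pos must have equal length")
        if self.values.shape != (len(self.sample_ids), p):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {p} probes"
            )
        keys = [(chromosome_sort_key(c), q) for c, q in zip(self.chrom, self.pos)]
        if any(keys[i] >= keys[i + 1] for i in range(p - 1)):
            raise ValueError("probes must be strictly sorted by (chrom, pos) with no duplicates")

    @property
    def n_probes(self) -> int:
        return self.pos.size

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def iter_chromosomes(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (chromosome label, boolean probe mask) in genome order."""
        seen: list[str] = []
        for c in self.chrom:
            if c not in seen:
                seen.append(c)
        for c in seen:
            yield c, self.chrom == c

    def iter_arms(self, arms: np.ndarray | None) -> Iterator[tuple[str, str, np.ndarray]]:
        """Yield (chrom, arm label, probe index array) in genome order.

        ``arms`` is a per-probe label array as produced by
        :func:`assign_arms`; ``None`` treats each whole chromosome as one arm
        labelled ``"q"``.
        """
        for c, mask in self.iter_chromosomes():
            idx = np.flatnonzero(mask)
            if arms is None:
                yield c, "q", idx
                continue
            labels = arms[idx]
            for a in ("p", "q"):
                sub = idx[labels == a]
                if sub.size:
                    yield c, a, sub

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos})
        for i, s in enumerate(self.sample_ids):
            df[s] = self.values[i]
        return df


@dataclass
class ArmPartition:
    """Centromere coordinates used to split chromosomes into p/q arms.

    A probe at position ``<= centromere`` belongs to the p arm, otherwise to
    the q arm.  ``whole_chromosome`` mode needs no coordinates and labels
    every probe ``"q"``.
    """

    centromeres: Mapping[str, int] = field(default_factory=dict)
    whole_chromosome: bool = False

    @classmethod
    def hg19(cls) -> "ArmPartition":
        """Built-in hg19 centromere table (UCSC cytoband midpoints)."""
        return cls(centromeres=dict(HG19_CENTROMERES))

    @classmethod
    def whole_chrom(cls) -> "ArmPartition":
        return cls(whole_chromosome=True)

    @classmethod
    def from_file(cls, source: str | Path | IO[str]) -> "ArmPartition":
        df = pd.read_csv(source, sep="\t", dtype={0: str})
        if df.shape[1] < 2:
            raise ValueError("centromere file needs columns: chrom, centromere_pos")
        cen = {
            normalize_chromosome(c): int(p)
            for c, p in zip(df.iloc[:, 0], df.iloc[:, 1])
        }
        return cls(centromeres=cen)


def assign_arms(table: CopyNumberTable, centromeres: ArmPartition | None) -> np.ndarray:
    """Label each probe with its chromosome arm ("p" or "q").

    Probes at positions less than or equal to the centromere coordinate are
    assigned to the p arm.  With ``centromeres=None`` or a whole-chromosome
    partition, all probes are labelled "q" (one arm per chromosome).
    """
    out = np.full(table.n_probes, "q", dtype=object)
    if centromeres is None or centromeres.whole_chromosome:
        return out
    for c, mask in table.iter_chromosomes():
        if c not in centromeres.centromeres:
            raise KeyError(
                f"chromosome {c!r} missing from the centromere table; "
                "use whole-chromosome mode or supply a centromere entry"
            )
        cen = centromeres.centromeres[c]
        out[mask & (table.pos <= cen)] = "p"
    return out


def read_copynumber_table(
    source: str | Path | IO[str], na_values: Sequence[str] = (NA_TOKEN,)
) -> CopyNumberTable:
    """Read a probe-by-sample TSV (columns: chrom, pos, one per sample).

    Chromosome labels have any leading ``chr`` stripped; rows are sorted by
    (chromosome, position).  Cells equal to one of ``na_values`` (default
    ``"NA"``, case-sensitive) become missing.  Any other non-numeric cell or
    a duplicated (chrom, pos) pair raises :class:`ValueError`.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError("expected at least columns: chrom, pos, one sample")
    chrom = np.array([normalize_chromosome(c) for c in df.iloc[:, 0]], dtype=object)
    try:
        pos = df.iloc[:, 1].astype(np.int64).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-integer position in column {df.columns[1]!r}: {exc}") from exc
    sample_ids = list(df.columns[2:])
    n, p = len(sample_ids), len(df)
    values = np.empty((n, p))
    for i, s in enumerate(sample_ids):
        col = df[s].to_numpy()
        missing = np.isin(col, list(na_values))
        try:
            values[i] = np.where(missing, "nan", col).astype(float)
        except ValueError:
            bad = next(
                j for j, v in enumerate(col)
                if not missing[j] and not _is_float(v)
            )
            raise ValueError(
                f"non-numeric value {col[bad]!r} at row {bad + 2}, column {s!r}"
            ) from None
    order = sorted(range(p), key=lambda j: (chromosome_sort_key(chrom[j]), pos[j]))
    order = np.asarray(order, dtype=np.int64)
    chrom, pos, values = chrom[order], pos[order], values[:, order]
    dup = [
        (chrom[j], pos[j])
        for j in range(p - 1)
        if chrom[j] == chrom[j + 1] and pos[j] == pos[j + 1]
    ]
    if dup:
        raise ValueError(f"duplicate (chrom, pos) entries: {dup[:5]}")
    return CopyNumberTable(chrom=chrom, pos=pos, sample_ids=sample_ids, values=values)


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def write_copynumber_table(table: CopyNumberTable, sink: str | Path | IO[str]) -> None:
    """Write the native probe-by-sample TSV (missing values as ``NA``)."""
    df = table.to_dataframe()
    df.to_csv(sink, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.10g")


# ---------------------------------------------------------------------------
# segments


@dataclass
class SegmentTable:
    """Per-sample (or common) segments with probe counts and mean levels.

    Wraps a DataFrame with columns ``sampleID, chrom, arm, start.pos,
    end.pos, n.probes`` and either a single ``mean`` column or one
    ``mean.<track>`` column per track for joint segmentations.  Within each
    (sample, chrom, arm) the segments are contiguous and cover every probe
    of the arm; ``start.pos``/``end.pos`` are the 1-based genomic positions
    of the first and last probe of the segment.
    """

    df: pd.DataFrame

    REQUIRED = ("sampleID", "chrom", "arm", "start.pos", "end.pos", "n.probes")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"SegmentTable missing columns: {missing}")
        if not self.mean_columns:
            raise ValueError("SegmentTable needs a 'mean' or 'mean.<track>' column")

    @property
    def mean_columns(self) -> list[str]:
        return [c for c in self.df.columns if c == "mean" or c.startswith("mean.")]

    def __len__(self) -> int:
        return len(self.df)


def write_segments(
    segments: SegmentTable, sink: str | Path | IO[str], format: str = "native"
) -> None:
    """Write segments as native TSV or in the IGV SEG dialect.

    The SEG dialect has columns ``sample, chrom, start, end, num_mark,
    seg.mean`` with one row per (sample, segment), grouped by sample; joint
    segmentations emit one row per track mean column.
    """
    if format == "native":
        segments.df.to_csv(sink, sep="\t", index=False, float_format="%.10g")
        return
    if format != "seg":
        raise ValueError(f"unknown segment format {format!r}")
    rows = []
    for col in segments.mean_columns:
        name_suffix = col[5:] if col.startswith("mean.") else None
        for _, r in segments.df.iterrows():
            sample = r["sampleID"] if name_suffix is None else name_suffix
            rows.append(
                (sample, r["chrom"], r["start.pos"], r["end.pos"], r["n.probes"], r[col])
            )
    out = pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "num_mark", "seg.mean"]
    ).sort_values("sample", kind="stable")
    out.to_csv(sink, sep="\t", index=False, float_format="%.10g")


def read_segments(source: str | Path | IO[str]) -> SegmentTable:
    """Read a native segment TSV written by :func:`write_segments`."""
    df = pd.read_csv(source, sep="\t", dtype={"chrom": str, "sampleID": str, "arm": str})
    return SegmentTable(df=df)
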