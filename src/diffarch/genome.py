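"""Genome coordinate backbone: bins, intervals, signal tracks, expression tables.

All coordinates are 0-based, half-open (BED-native). A "TSS" is the 1-bp
interval at a gene's annotated transcription start, strand-aware. bedGraph is
the supported interchange format for signal tracks; BigWig conversion is left
to the user.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "BinTable",
    "GenomicInterval",
    "SignalTrack",
    "interval_overlap",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_expression_table",
    "write_expression_table",
    "tss_position",
]

EXPRESSION_COLUMNS = [
    "gene", "chrom", "start", "end", "strand",
    "fpkm1", "fpkm2", "log2fc", "is_de",
]


class GenomeFormatError(ValueError):
    """Malformed genomic text input."""


@dataclass(frozen=True)
class BinTable:
    """Fixed-width partition of one chromosome into bins.

    Bins tile [0, size) without gaps or overlaps; the last bin may be short.
    """

    chrom: str
    size: int
    bin_width: int

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.size <= 0:
            raise ValueError("chromosome size must be positive")

    @property
    def n_bins(self) -> int:
        return -(-self.size // self.bin_width)

    def bin_index(self, pos: int) -> int:
        """Bin containing position ``pos`` (= floor(pos / bin_width))."""
        if pos < 0 or pos >= self.size:
            raise ValueError(f"position {pos} outside {self.chrom}:[0,{self.size})")
        return pos // self.bin_width

    def bin_start(self, i) -> int:
        return np.asarray(i) * self.bin_width

    def bin_end(self, i):
        return np.minimum((np.asarray(i) + 1) * self.bin_width, self.size)

    def bin_interval(self, i: int) -> "GenomicInterval":
        if i < 0 or i >= self.n_bins:
            raise ValueError(f"bin {i} out of range for {self.chrom}")
        return GenomicInterval(self.chrom, int(self.bin_start(i)), int(self.bin_end(i)))


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share >= 1 bp under half-open semantics."""
    return a.chrom == b.chrom and min(a.end, b.end) - max(a.start, b.start) >= 1


class SignalTrack:
    """Sorted, non-overlapping intervals with one numeric value each.

    Per chromosome, ``starts``/``ends``/``values`` are parallel arrays.
    Positions not covered by any interval have implicit value 0.
    """

    def __init__(self, data: Optional[dict] = None) -> None:
        # chrom -> (starts, ends, values), sorted by start, non-overlapping
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = data or {}

    @classmethod
    def from_arrays(cls, chrom_arrays: dict) -> "SignalTrack":
        t = cls()
        for chrom, (s, e, v) in chrom_arrays.items():
            t.add_chrom(chrom, np.asarray(s), np.asarray(e), np.asarray(v, dtype=float))
        return t

    def add_chrom(self, chrom, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(starts >= ends):
            raise GenomeFormatError(f"{chrom}: empty or inverted interval in track")
        if np.any(starts[1:] < ends[:-1]):
            raise GenomeFormatError(f"{chrom}: overlapping intervals in signal track")
        self._data[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def arrays(self, chrom: str):
        return self._data[chrom]

    def n_intervals(self) -> int:
        return sum(len(s) for s, _, _ in self._data.values())

    def mean_value(self, chrom: str, start: int, end: int) -> float:
        """Coverage-weighted mean signal over [start, end); gaps count as 0."""
        if end <= start:
            raise ValueError("empty query interval")
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        ov = (
            np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ).astype(float)
        return float(np.dot(ov, values[lo:hi]) / (end - start))

    def binned_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Mean signal in each [edges[k], edges[k+1]) window (vector form)."""
        edges = np.asarray(edges, dtype=np.int64)
        out = np.empty(len(edges) - 1)
        for k in range(len(edges) - 1):
            out[k] = self.mean_value(chrom, int(edges[k]), int(edges[k + 1]))
        return out

    def bin_values(self, bins: BinTable) -> np.ndarray:
        """Mean signal per bin of a BinTable."""
        edges = np.append(bins.bin_start(np.arange(bins.n_bins)), bins.size)
        return self.binned_means(bins.chrom, edges)

    def scale(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self._data.items()}
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _iter_data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into validated, sorted intervals."""
    out = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise GenomeFormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise GenomeFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
        try:
            out.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
        except ValueError as exc:
            raise GenomeFormatError(f"{path}:{lineno}: {exc}") from exc
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                cols += [iv.name or ".", "0", iv.strand or "."]
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack (overlaps rejected)."""
    per_chrom: dict[str, list] = {}
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise GenomeFormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise GenomeFormatError(f"{path}:{lineno}: malformed bedGraph fields") from exc
        if start >= end:
            raise GenomeFormatError(f"{path}:{lineno}: empty interval {start}-{end}")
        per_chrom.setdefault(fields[0], []).append((start, end, value))
    track = SignalTrack()
    for chrom, rows in per_chrom.items():
        arr = np.asarray(rows)
        track.add_chrom(chrom, arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms):
            starts, ends, values = track.arrays(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def tss_position(row) -> int:
    """Strand-aware transcription start of a gene row (start if +, end-1 if -)."""
    return int(row["start"]) if row["strand"] != "-" else int(row["end"]) - 1


def read_expression_table(path) -> pd.DataFrame:
    """Read a gene expression TSV with the canonical columns.

    Required columns: gene, chrom, start, end, strand, fpkm1, fpkm2, log2fc,
    is_de. FPKM must be non-negative; DE-flagged genes need a finite log2fc.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise GenomeFormatError(f"{path}: missing expression columns {missing}")
    df = df[EXPRESSION_COLUMNS].copy()
    df["is_de"] = df["is_de"].astype(bool)
    if (df[["fpkm1", "fpkm2"]] < 0).any().any():
        raise GenomeFormatError(f"{path}: negative FPKM values")
    bad = df["is_de"] & ~np.isfinite(df["log2fc"])
    if bad.any():
        raise GenomeFormatError(f"{path}: non-finite log2fc for DE genes")
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    out = df[EXPRESSION_COLUMNS].copy()
    out["is_de"] = out["is_de"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
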