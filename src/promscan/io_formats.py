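"""Readers and writers for the file formats the pipeline consumes and emits.

All coordinates are held internally as 0-based half-open intervals in genome
orientation (minus-strand features are *not* reversed), matching BED. The two
inputs that arrive in other conventions are converted on read:

* fixed-step wiggle is 1-based; ``start=11`` in a ``fixedStep`` header refers
  to 0-based position 10,
* bedGraph is already 0-based half-open.

CTSS input is a 4-column TSV ``chrom  pos0  strand  count`` with a 0-based
position. CAGE ctss dialects vary on this point; files produced elsewhere may
need a one-base shift before use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "CtssTrack",
    "PeakSet",
    "SignalTrack",
    "TranscriptModel",
    "CtssParseError",
    "read_ctss",
    "write_ctss",
    "read_peaks",
    "write_peaks",
    "read_signal",
    "write_bedgraph",
    "read_transcripts",
    "write_transcripts",
    "write_tss_table",
    "read_tss_table",
]

STRANDS = ("+", "-", ".")


class CtssParseError(ValueError):
    """Malformed CTSS input; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to_point(self, pos: int) -> int:
        """bp gap from a point to this interval; 0 if the point lies inside."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


@dataclass
class CtssTrack:
    """Stranded per-base counts of transcript 5' ends.

    ``entries`` maps (chrom, strand) to a pair of parallel arrays
    (positions sorted ascending, counts > 0).
    """

    entries: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @property
    def library_size(self) -> int:
        return int(sum(int(c.sum()) for _, c in self.entries.values()))

    @property
    def n_sites(self) -> int:
        return int(sum(len(p) for p, _ in self.entries.values()))

    def is_empty(self) -> bool:
        return self.n_sites == 0

    def iter_records(self) -> Iterable[Tuple[str, int, str, int]]:
        for (chrom, strand) in sorted(self.entries):
            pos, cnt = self.entries[(chrom, strand)]
            for p, c in zip(pos.tolist(), cnt.tolist()):
                yield chrom, p, strand, c

    @classmethod
    def from_records(
        cls, records: Iterable[Tuple[str, int, str, int]]
    ) -> "CtssTrack":
        acc: Dict[Tuple[str, str], Dict[int, int]] = {}
        for chrom, pos, strand, count in records:
            if strand not in ("+", "-"):
                raise ValueError(f"CTSS strand must be + or -, got {strand!r}")
            if count < 0:
                raise ValueError("CTSS counts must be non-negative")
            if count == 0:
                continue
            acc.setdefault((chrom, strand), {})
            acc[(chrom, strand)][pos] = acc[(chrom, strand)].get(pos, 0) + count
        entries = {}
        for key, d in acc.items():
            pos = np.array(sorted(d), dtype=np.int64)
            cnt = np.array([d[p] for p in pos.tolist()], dtype=np.int64)
            entries[key] = (pos, cnt)
        return cls(entries)


@dataclass
class PeakSet:
    """Named collection of unstranded intervals from one ChIP experiment."""

    name: str
    intervals: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


class SignalTrack:
    """Per-base float signal over a genome; uncovered bases read as 0.0."""

    def __init__(self, arrays: Optional[Mapping[str, np.ndarray]] = None) -> None:
        self._arrays: Dict[str, np.ndarray] = {}
        if arrays:
            for chrom, arr in arrays.items():
                a = np.asarray(arr, dtype=float)
                if not np.all(np.isfinite(a)):
                    raise ValueError(f"non-finite signal values on {chrom}")
                self._arrays[chrom] = a

    @property
    def chroms(self) -> List[str]:
        return sorted(self._arrays)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); exactly end-start values."""
        if end <= start:
            raise ValueError("end must exceed start")
        out = np.zeros(end - start, dtype=float)
        arr = self._arrays.get(chrom)
        if arr is None:
            return out
        lo = max(start, 0)
        hi = min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def values_over(self, interval: GenomicInterval) -> np.ndarray:
        return self.values(interval.chrom, interval.start, interval.end)

    def scaled(self, k: float) -> "SignalTrack":
        return SignalTrack({c: a * k for c, a in self._arrays.items()})


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated transcript; tss_position is strand-aware."""

    gene_id: str
    transcript_id: str
    span: GenomicInterval
    cds_key: str = ""

    @property
    def tss_position(self) -> int:
        if self.span.strand == "-":
            return self.span.end - 1
        return self.span.start


# ---------------------------------------------------------------------------
# CTSS


def read_ctss(
    path: str | Path, genome_index: Optional[Mapping[str, int]] = None
) -> CtssTrack:
    """Read a 4-column CTSS TSV (chrom, 0-based pos, strand, count).

    ``genome_index`` maps chromosome name to length; when given, positions are
    bounds-checked against it.
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise CtssParseError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(parts)}"
                )
            chrom, pos_s, strand, count_s = parts
            try:
                pos = int(pos_s)
                count = int(count_s)
            except ValueError as exc:
                raise CtssParseError(
                    f"{path}: line {lineno}: non-integer position or count"
                ) from exc
            if pos < 0 or count < 0:
                raise CtssParseError(
                    f"{path}: line {lineno}: negative position or count"
                )
            if strand not in ("+", "-"):
                raise CtssParseError(
                    f"{path}: line {lineno}: strand must be + or -, got {strand!r}"
                )
            if genome_index is not None:
                if chrom not in genome_index:
                    warnings.warn(
                        f"{path}: line {lineno}: unknown chromosome {chrom!r}"
                    )
                elif pos >= genome_index[chrom]:
                    raise CtssParseError(
                        f"{path}: line {lineno}: position {pos} beyond "
                        f"{chrom} length {genome_index[chrom]}"
                    )
            records.append((chrom, pos, strand, count))
    return CtssTrack.from_records(records)


def write_ctss(track: CtssTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, strand, count in track.iter_records():
            fh.write(f"{chrom}\t{pos}\t{strand}\t{count}\n")


# ---------------------------------------------------------------------------
# Peaks (BED3 / BED6 / narrowPeak)


def read_peaks(path: str | Path, name: Optional[str] = None) -> PeakSet:
    """Read BED3/BED6/narrowPeak; only coordinates are used (strand '.')."""
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            intervals.append(GenomicInterval(chrom, start, end, "."))
    return PeakSet(name=name or Path(path).stem, intervals=intervals)


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Signal (fixed-step wiggle, bedGraph)


def read_signal(
    path: str | Path, chrom_sizes: Optional[Mapping[str, int]] = None
) -> SignalTrack:
    """Read a fixed-step wiggle or bedGraph file into a SignalTrack.

    Dialect is sniffed: any ``fixedStep`` header means wiggle, otherwise the
    file is treated as 4-column bedGraph. Wiggle starts are 1-based and are
    converted; bedGraph records are 0-based half-open. Overlapping bedGraph
    records are an error (the signal would be ambiguous); unsorted records are
    accepted with a warning.
    """
    text = Path(path).read_text().splitlines()
    is_wiggle = any(ln.startswith("fixedStep") for ln in text)
    segments: List[Tuple[str, int, int, float]] = []  # chrom, start0, end0, value
    if is_wiggle:
        chrom = None
        pos = 0
        step = 1
        span = 1
        for raw in text:
            line = raw.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # 1-based -> 0-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                continue
            if chrom is None:
                raise ValueError(f"{path}: data before fixedStep header")
            value = float(line)
            segments.append((chrom, pos, pos + span, value))
            pos += step
    else:
        for lineno, raw in enumerate(text, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 bedGraph fields"
                )
            segments.append(
                (parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
            )
        if segments != sorted(segments, key=lambda s: (s[0], s[1])):
            warnings.warn(f"{path}: unsorted bedGraph; re-sorting")
            segments.sort(key=lambda s: (s[0], s[1]))
        prev: Dict[str, int] = {}
        for chrom, start, end, _ in segments:
            if start < prev.get(chrom, 0):
                raise ValueError(
                    f"{path}: overlapping bedGraph records on {chrom} at {start}"
                )
            prev[chrom] = end

    lengths: Dict[str, int] = dict(chrom_sizes or {})
    for chrom, _, end, _ in segments:
        lengths[chrom] = max(lengths.get(chrom, 0), end)
    arrays = {c: np.zeros(n, dtype=float) for c, n in lengths.items()}
    for chrom, start, end, value in segments:
        arrays[chrom][start:end] = value
    return SignalTrack(arrays)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a SignalTrack as bedGraph, run-length compressing equal values."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            arr = track.values(chrom, 0, len(track._arrays[chrom]))
            if len(arr) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(arr)]])
            for s, e in zip(starts.tolist(), ends.tolist()):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Transcripts (genePred-like TSV)

_TRANSCRIPT_COLS = [
    "gene_id",
    "transcript_id",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsKey",
]


def read_transcripts(path: str | Path) -> List[TranscriptModel]:
    """Read a genePred-like TSV: gene_id, transcript_id, chrom, strand,
    txStart, txEnd, cdsKey (cdsKey empty for non-coding)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TRANSCRIPT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing transcript columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TranscriptModel(
                gene_id=row.gene_id,
                transcript_id=row.transcript_id,
                span=GenomicInterval(
                    row.chrom, int(row.txStart), int(row.txEnd), row.strand
                ),
                cds_key=row.cdsKey,
            )
        )
    return out


def write_transcripts(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": t.gene_id,
            "transcript_id": t.transcript_id,
            "chrom": t.span.chrom,
            "strand": t.span.strand,
            "txStart": t.span.start,
            "txEnd": t.span.end,
            "cdsKey": t.cds_key,
        }
        for t in transcripts
    ]
    pd.DataFrame(rows, columns=_TRANSCRIPT_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TSS record tables


def write_tss_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a TSS record table as TSV with header; round-trips losslessly."""
    records.to_csv(path, sep="\t", index=False)


def read_tss_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
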