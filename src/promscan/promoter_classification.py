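"""Classify TSSs by proximity to histone-mark and TF ChIP peaks, and assign
them to annotated genes.

A TSS falls in class BOTH when some H3K4me3 peak lies within ``window`` bp of
the TSS anchor *and* that peak overlaps (shares at least one bp with) some
SOX10 peak; H3K4ME3_ONLY when an H3K4me3 peak is within the window but no such
overlapping pair exists; SOX10_ONLY when only a SOX10 peak is within the
window; NEITHER otherwise. Distances are measured from the cluster anchor (the
modal base): 0 if the anchor lies inside the peak, else the bp gap to the
nearer edge. The residual case — both marks nearby but never as an overlapping
pair — is labelled H3K4ME3_ONLY and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, PeakSet, TranscriptModel
from .tss_clustering import TssCluster

__all__ = [
    "CLASS_LABELS",
    "TssRecord",
    "ClassSummary",
    "classify_tss",
    "assign_genes",
    "summarize_classes",
    "records_to_frame",
]

CLASS_LABELS = ("BOTH", "H3K4ME3_ONLY", "SOX10_ONLY", "NEITHER")


@dataclass
class TssRecord:
    """A classified TSS with optional gene assignment and expression summary."""

    cluster: TssCluster
    class_label: str
    h3k4me3_distance: Optional[int] = None  # nearest peak, bp from anchor
    sox10_distance: Optional[int] = None
    gene_id: Optional[str] = None
    gene_distance: Optional[int] = None
    sample_counts: Dict[str, int] = field(default_factory=dict)
    rpm: Optional[float] = None
    rpm_density: Optional[float] = None

    @property
    def tss_id(self) -> str:
        return self.cluster.tss_id

    @property
    def anchor(self) -> int:
        return self.cluster.anchor

    @property
    def strand(self) -> str:
        return self.cluster.interval.strand


@dataclass
class ClassSummary:
    """Per-class TSS counts and gene-mapping rates."""

    table: pd.DataFrame  # rows: class labels + Total
    n_residual_both_no_overlap: int = 0


def _merge_covered(peaks: PeakSet) -> List[GenomicInterval]:
    """Union of covered bases: overlapping/abutting peaks become one
    interval, so classification depends only on coverage, not on how a
    peak caller happened to split it."""
    merged: List[GenomicInterval] = []
    for iv in peaks.intervals:  # already sorted by (chrom, start)
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start <= merged[-1].end
        ):
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chrom, merged[-1].start, iv.end, "."
                )
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end, "."))
    return merged


def _peak_tree(intervals: Sequence[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _peaks_within(
    trees: Mapping[str, IntervalTree], chrom: str, anchor: int, window: int
) -> List[GenomicInterval]:
    tree = trees.get(chrom)
    if tree is None:
        return []
    # anchor inside peak -> distance 0; else gap to nearer edge <= window.
    # A peak [s, e) is within `window` of the anchor iff s <= anchor + window
    # and e > anchor - window (gap = s - anchor or anchor - e + 1).
    hits = tree.overlap(anchor - window, anchor + window + 1)
    return [h.data for h in hits]


def classify_tss(
    clusters: Sequence[TssCluster],
    h3k4me3: PeakSet,
    sox10: PeakSet,
    window: int = 1000,
) -> List[TssRecord]:
    """Assign each cluster one of the four peak-association classes."""
    if window <= 0:
        raise ValueError("window must be positive")
    h3_merged = _merge_covered(h3k4me3)
    so_merged = _merge_covered(sox10)
    h3_trees = _peak_tree(h3_merged)
    so_trees = _peak_tree(so_merged)

    so_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in so_merged:
        so_by_chrom.setdefault(iv.chrom, []).append(iv)
    so_starts = {
        c: np.array([iv.start for iv in ivs]) for c, ivs in so_by_chrom.items()
    }
    so_ends = {c: np.array([iv.end for iv in ivs]) for c, ivs in so_by_chrom.items()}

    def h3_overlaps_sox10(peak: GenomicInterval) -> bool:
        starts = so_starts.get(peak.chrom)
        if starts is None:
            return False
        ends = so_ends[peak.chrom]
        return bool(np.any((starts < peak.end) & (ends > peak.start)))

    records: List[TssRecord] = []
    for cl in clusters:
        chrom, anchor = cl.interval.chrom, cl.anchor
        h3_near = _peaks_within(h3_trees, chrom, anchor, window)
        so_near = _peaks_within(so_trees, chrom, anchor, window)
        h3_dist = (
            min(iv.distance_to_point(anchor) for iv in h3_near) if h3_near else None
        )
        so_dist = (
            min(iv.distance_to_point(anchor) for iv in so_near) if so_near else None
        )
        if any(h3_overlaps_sox10(p) for p in h3_near):
            label = "BOTH"
        elif h3_near:
            label = "H3K4ME3_ONLY"
        elif so_near:
            label = "SOX10_ONLY"
        else:
            label = "NEITHER"
        records.append(
            TssRecord(
                cluster=cl,
                class_label=label,
                h3k4me3_distance=h3_dist,
                sox10_distance=so_dist,
            )
        )
    return records


def assign_genes(
    records: Sequence[TssRecord],
    transcripts: Sequence[TranscriptModel],
    window: int = 1000,
    fallback_map: Optional[Mapping[Tuple[str, int], Tuple[str, int]]] = None,
) -> List[TssRecord]:
    """Assign each TSS to the nearest same-strand gene within ``window`` bp.

    The gene span is the union of the gene's transcript spans, extended by
    ``window`` on both sides; a TSS is assigned when its anchor falls inside
    that extended span on the matching strand. Ties (equal distance) break by
    smaller span, then lexicographic gene_id. TSSs left unassigned are retried
    after translating the anchor through ``fallback_map``, a coordinate
    orthology table mapping (chrom, pos) -> (chrom', pos') (standing in for a
    cross-genome liftOver step).
    """
    # gene span = union of transcript spans, per strand
    spans: Dict[Tuple[str, str, str], Tuple[int, int]] = {}
    for t in transcripts:
        key = (t.gene_id, t.span.chrom, t.span.strand)
        cur = spans.get(key)
        if cur is None:
            spans[key] = (t.span.start, t.span.end)
        else:
            spans[key] = (min(cur[0], t.span.start), max(cur[1], t.span.end))

    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for (gene_id, chrom, strand), (s, e) in sorted(spans.items()):
        trees.setdefault((chrom, strand), IntervalTree()).addi(
            max(0, s - window), e + window, (gene_id, s, e)
        )

    def lookup(chrom: str, strand: str, anchor: int):
        tree = trees.get((chrom, strand))
        if tree is None:
            return None
        hits = tree.at(anchor)
        if not hits:
            return None
        candidates = []
        for h in hits:
            gene_id, s, e = h.data
            dist = 0 if s <= anchor < e else min(abs(anchor - s), abs(anchor - (e - 1)))
            candidates.append((dist, e - s, gene_id))
        candidates.sort()
        dist, _, gene_id = candidates[0]
        return gene_id, dist

    out: List[TssRecord] = []
    for rec in records:
        chrom = rec.cluster.interval.chrom
        hit = lookup(chrom, rec.strand, rec.anchor)
        if hit is None and fallback_map is not None:
            mapped = fallback_map.get((chrom, rec.anchor))
            if mapped is not None:
                mchrom, mpos = mapped
                if any(mchrom == c for (c, _s) in trees):
                    hit = lookup(mchrom, rec.strand, mpos)
                else:
                    warnings.warn(
                        f"fallback map target chromosome {mchrom!r} unknown; "
                        f"skipping {rec.tss_id}"
                    )
        if hit is None:
            out.append(replace(rec, gene_id=None, gene_distance=None))
        else:
            out.append(replace(rec, gene_id=hit[0], gene_distance=hit[1]))
    return out


def summarize_classes(records: Sequence[TssRecord]) -> ClassSummary:
    """Per-class TSS counts, gene-mapping rates (2 decimals) and unique genes."""
    from .report_stats import round_half_up

    rows = []
    for label in CLASS_LABELS:
        recs = [r for r in records if r.class_label == label]
        n = len(recs)
        mapped = [r for r in recs if r.gene_id is not None]
        pct = round_half_up(100.0 * len(mapped) / n, 2) if n else 0.0
        frac = (
            round_half_up(100.0 * n / len(records), 1) if records else 0.0
        )
        rows.append(
            {
                "class": label,
                "n_tss": n,
                "n_within_1kb_of_gene": len(mapped),
                "percent_within_1kb": pct,
                "n_unique_genes": len({r.gene_id for r in mapped}),
                "percent_of_total": frac,
            }
        )
    n_all = len(records)
    mapped_all = [r for r in records if r.gene_id is not None]
    rows.append(
        {
            "class": "Total",
            "n_tss": n_all,
            "n_within_1kb_of_gene": len(mapped_all),
            "percent_within_1kb": (
                round_half_up(100.0 * len(mapped_all) / n_all, 2) if n_all else 0.0
            ),
            "n_unique_genes": len({r.gene_id for r in mapped_all}),
            "percent_of_total": 100.0 if n_all else 0.0,
        }
    )
    residual = sum(
        1
        for r in records
        if r.class_label == "H3K4ME3_ONLY" and r.sox10_distance is not None
    )
    return ClassSummary(table=pd.DataFrame(rows), n_residual_both_no_overlap=residual)


def records_to_frame(records: Sequence[TssRecord]) -> pd.DataFrame:
    """Flatten TssRecords to a DataFrame for TSV output."""
    rows = []
    for r in records:
        iv = r.cluster.interval
        row = {
            "tss_id": r.tss_id,
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "strand": iv.strand,
            "anchor": r.anchor,
            "total_count": r.cluster.total_count,
            "n_sites": r.cluster.n_sites,
            "min_density": r.cluster.min_density,
            "max_density": r.cluster.max_density,
            "class_label": r.class_label,
            "h3k4me3_distance": r.h3k4me3_distance,
            "sox10_distance": r.sox10_distance,
            "gene_id": r.gene_id,
            "gene_distance": r.gene_distance,
            "rpm": r.rpm,
            "rpm_density": r.rpm_density,
        }
        for sample, c in r.sample_counts.items():
            row[f"count_{sample}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


def attach_expression(
    records: Sequence[TssRecord],
    counts: np.ndarray,
    sample_names: Sequence[str],
    library_sizes: Sequence[int],
) -> List[TssRecord]:
    """Attach per-sample counts plus mean RPM and RPM per 100 bp."""
    counts = np.asarray(counts)
    lib = np.asarray(library_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive for RPM")
    out = []
    for i, rec in enumerate(records):
        per_sample = dict(zip(sample_names, counts[i].tolist()))
        rpm = float(np.mean(counts[i] / lib * 1e6))
        out.append(
            replace(
                rec,
                sample_counts=per_sample,
                rpm=rpm,
                rpm_density=rpm * 100.0 / rec.cluster.length,
            )
        )
    return out
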