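"""Aggregate per-base signal around TSS anchors, class comparisons by a
label-permutation test on the area under the mean profile, and GC-stratified
profiles.

Windows are strand-oriented: positive offsets are downstream of the TSS in
the direction of transcription, so minus-strand windows are reversed. Bases
outside the chromosome contribute 0 signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io_formats import SignalTrack
from .promoter_classification import TssRecord

__all__ = [
    "MetageneProfile",
    "metagene_profile",
    "compare_profiles_auc",
    "gc_binned_profiles",
    "window_gc_fraction",
]


@dataclass
class MetageneProfile:
    """Mean per-offset signal over a set of anchored windows."""

    label: str
    offsets: np.ndarray  # -window .. window-1, transcription-oriented
    mean_signal: np.ndarray
    n_regions: int

    @property
    def auc(self) -> float:
        """Area under the profile, rectangle rule at 1-bp bins."""
        return float(self.mean_signal.sum())


def _window_matrix(
    records: Sequence[TssRecord], signal: SignalTrack, window: int
) -> np.ndarray:
    """Per-record strand-oriented signal windows, shape (n, 2*window)."""
    rows = np.empty((len(records), 2 * window), dtype=float)
    for i, rec in enumerate(records):
        chrom = rec.cluster.interval.chrom
        a = rec.anchor
        v = signal.values(chrom, a - window, a + window)
        if rec.strand == "-":
            v = v[::-1]
        rows[i] = v
    return rows


def metagene_profile(
    records_by_class: Mapping[str, Sequence[TssRecord]],
    signal: SignalTrack,
    window: int = 1000,
) -> Dict[str, MetageneProfile]:
    """One mean profile per class; empty classes are omitted with a warning."""
    offsets = np.arange(-window, window)
    out: Dict[str, MetageneProfile] = {}
    for label, records in records_by_class.items():
        if len(records) == 0:
            warnings.warn(f"class {label!r} has no records; omitted")
            continue
        mat = _window_matrix(records, signal, window)
        out[label] = MetageneProfile(
            label=label,
            offsets=offsets,
            mean_signal=mat.mean(axis=0),
            n_regions=len(records),
        )
    return out


def compare_profiles_auc(
    records_a: Sequence[TssRecord],
    records_b: Sequence[TssRecord],
    signal: SignalTrack,
    window: int = 1000,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the AUC difference between two classes.

    The statistic is |AUC(mean profile A) - AUC(mean profile B)|; since the
    AUC of a mean profile is the mean of per-region window sums, the null is
    built by permuting region labels over the pooled per-region sums.
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if len(records_a) < 2 or len(records_b) < 2:
        raise ValueError("both classes need >= 2 records")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value")
    sums_a = _window_matrix(records_a, signal, window).sum(axis=1)
    sums_b = _window_matrix(records_b, signal, window).sum(axis=1)
    observed = abs(sums_a.mean() - sums_b.mean())
    # canonical pooled order + smaller-group-first assignment make the
    # p-value exactly invariant to exchanging the roles of A and B
    pooled = np.sort(np.concatenate([sums_a, sums_b]))
    n_small = min(len(sums_a), len(sums_b))
    n_large = len(pooled) - n_small
    total = pooled.sum()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        head = perm[:n_small].sum()
        stat = abs(head / n_small - (total - head) / n_large)
        if stat >= observed - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def window_gc_fraction(
    records: Sequence[TssRecord], genome: Mapping[str, str], window: int = 1000
) -> np.ndarray:
    """GC fraction of each record's +/- window sequence (strand-agnostic;
    GC content is reverse-complement invariant). N and other ambiguity codes
    count as non-GC. Windows extending past a chromosome end are truncated."""
    out = np.empty(len(records))
    for i, rec in enumerate(records):
        chrom = rec.cluster.interval.chrom
        seq = str(genome[chrom])
        a = rec.anchor
        sub = seq[max(0, a - window) : min(len(seq), a + window)].upper()
        if len(sub) < 2 * window:
            warnings.warn(f"{rec.tss_id}: window truncated at chromosome end")
        out[i] = (sub.count("G") + sub.count("C")) / max(1, len(sub))
    return out


def gc_binned_profiles(
    records_by_class: Mapping[str, Sequence[TssRecord]],
    signal: SignalTrack,
    genome: Mapping[str, str],
    window: int = 1000,
    n_bins: int = 5,
) -> Dict[Tuple[str, int], MetageneProfile]:
    """Metagene profiles per (class, GC-quantile bin).

    Quantile boundaries come from the pooled GC distribution across all
    classes; ties at a boundary fall in the lower bin.
    """
    all_records = [r for recs in records_by_class.values() for r in recs]
    if not all_records:
        return {}
    gc_all = window_gc_fraction(all_records, genome, window)
    edges = np.quantile(gc_all, np.linspace(0, 1, n_bins + 1)[1:-1])

    def bin_of(gc: float) -> int:
        # ties to the lower bin: first edge with gc <= edge
        for b, e in enumerate(edges):
            if gc <= e:
                return b
        return n_bins - 1

    out: Dict[Tuple[str, int], MetageneProfile] = {}
    for label, records in records_by_class.items():
        if not records:
            continue
        gc = window_gc_fraction(records, genome, window)
        for b in range(n_bins):
            sub = [r for r, g in zip(records, gc) if bin_of(g) == b]
            if not sub:
                continue
            mat = _window_matrix(sub, signal, window)
            out[(label, b)] = MetageneProfile(
                label=f"{label}/gc_bin{b}",
                offsets=np.arange(-window, window),
                mean_signal=mat.mean(axis=0),
                n_regions=len(sub),
            )
    return out
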