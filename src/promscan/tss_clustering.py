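"""Density-based clustering of per-base 5' end counts into TSS intervals.

The clustering follows the parametric maximal-scoring-segment idea: a segment
of sites scores ``S_d = (sum of counts) - d * (bp length)`` for a density
parameter ``d``. For each ``d > 0`` the maximal-scoring segments of a
chromosome/strand form a disjoint set, and as ``d`` varies they form a nested
family. Each reported cluster carries the density window
``(min_density, max_density)`` over which it is the maximal segment: at
densities just above ``max_density`` it breaks at its weakest prefix or
suffix, and below ``min_density`` it is absorbed into its parent. Outermost
clusters carry ``min_density = 0.0`` (they are optimal for every sufficiently
small positive density).

The recursion is top-down: starting from all sites on one chromosome/strand,
find the weakest prefix/suffix boundary (the smallest density at which some
prefix or suffix of the segment would score non-positively), record the
segment, and split there. bp length of a segment spanning sites at positions
``p_i..p_j`` is ``p_j + 1 - p_i``, so a single site has length 1 and a finite
maximal density equal to its count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .io_formats import CtssTrack, GenomicInterval

__all__ = ["TssCluster", "cluster_ctss", "filter_clusters", "pool_tracks"]


@dataclass(frozen=True)
class TssCluster:
    """A contiguous stranded TSS interval with counts and density bounds."""

    interval: GenomicInterval
    total_count: int
    anchor: int
    min_density: float
    max_density: float
    n_sites: int

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.anchor < self.interval.end):
            raise ValueError("anchor must lie within the cluster interval")
        if self.max_density < self.min_density:
            raise ValueError("max_density must be >= min_density")

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def stability(self) -> float:
        """max/min density ratio; infinite for outermost clusters."""
        if self.min_density <= 0.0:
            return float("inf")
        return self.max_density / self.min_density

    @property
    def tss_id(self) -> str:
        s = self.interval
        return f"{s.chrom}:{s.start}-{s.end}{s.strand}"


def _anchor(pos: np.ndarray, cnt: np.ndarray, strand: str) -> int:
    """5'-most base (w.r.t. strand) among those with the maximal count."""
    top = np.flatnonzero(cnt == cnt.max())
    idx = top[0] if strand == "+" else top[-1]
    return int(pos[idx])


def _segment_tree(
    pos: np.ndarray, cnt: np.ndarray
) -> List[Tuple[int, int, float, float]]:
    """Enumerate (lo, hi, min_density, max_density) for every segment that is
    maximal-scoring at some density, over sites pos[lo:hi]."""
    out: List[Tuple[int, int, float, float]] = []
    csum = np.concatenate([[0], np.cumsum(cnt)])

    # iterative DFS; synthetic promoters can hold many sites per segment
    stack: List[Tuple[int, int, float]] = [(0, len(pos), 0.0)]
    while stack:
        lo, hi, min_d = stack.pop()
        n = hi - lo
        if n == 0:
            continue
        if n == 1:
            max_d = float(cnt[lo])  # score c - d*1 > 0 iff d < c
            if max_d > min_d:
                out.append((lo, hi, min_d, max_d))
            continue
        # break densities at every cut k (between sites k-1 and k):
        #   prefix sites lo..k-1 occupy [p_lo, p_k) at the worst cut point
        #   suffix sites k..hi-1 occupy [p_{k-1}+1, p_{hi-1}+1) at the worst cut
        k = np.arange(lo + 1, hi)
        pre = (csum[k] - csum[lo]) / (pos[k] - pos[lo])
        suf = (csum[hi] - csum[k]) / (pos[hi - 1] - pos[k - 1])
        both = np.minimum(pre, suf)
        j = int(np.argmin(both))
        max_d = float(both[j])
        cut = lo + 1 + j
        if max_d > min_d:
            out.append((lo, hi, min_d, max_d))
        new_min = max(min_d, max_d)
        stack.append((lo, cut, new_min))
        stack.append((cut, hi, new_min))
    return out


def cluster_ctss(track: CtssTrack, min_count: int = 1) -> List[TssCluster]:
    """Cluster a CTSS track into the full nested family of TSS clusters.

    Each chromosome/strand is clustered independently; opposite-strand sites
    never co-cluster. Returns clusters sorted by (chrom, strand, start, -length)
    so parents precede children.
    """
    clusters: List[TssCluster] = []
    for (chrom, strand), (pos, cnt) in sorted(track.entries.items()):
        keep = cnt >= min_count
        p, c = pos[keep], cnt[keep]
        if len(p) == 0:
            continue
        for lo, hi, min_d, max_d in _segment_tree(p, c):
            seg_pos, seg_cnt = p[lo:hi], c[lo:hi]
            clusters.append(
                TssCluster(
                    interval=GenomicInterval(
                        chrom, int(seg_pos[0]), int(seg_pos[-1]) + 1, strand
                    ),
                    total_count=int(seg_cnt.sum()),
                    anchor=_anchor(seg_pos, seg_cnt, strand),
                    min_density=min_d,
                    max_density=max_d,
                    n_sites=hi - lo,
                )
            )
    clusters.sort(
        key=lambda cl: (
            cl.interval.chrom,
            cl.interval.strand,
            cl.interval.start,
            -cl.length,
        )
    )
    return clusters


def filter_clusters(
    clusters: Sequence[TssCluster],
    max_length: int = 200,
    min_total: int = 10,
    min_stability: float = 2.0,
) -> List[TssCluster]:
    """Filter the nested cluster family down to one TSS per promoter.

    Keeps clusters with bp length <= max_length, total_count >= min_total and
    density stability (max/min) >= min_stability, then resolves nesting by
    keeping only the outermost surviving cluster of each nested run.
    """
    if max_length < 0 or min_total < 0 or min_stability < 0:
        raise ValueError("filter thresholds must be >= 0")
    survivors = [
        cl
        for cl in clusters
        if cl.length <= max_length
        and cl.total_count >= min_total
        and cl.stability >= min_stability
    ]
    survivors.sort(
        key=lambda cl: (
            cl.interval.chrom,
            cl.interval.strand,
            cl.interval.start,
            -cl.length,
        )
    )
    kept: List[TssCluster] = []
    last: Dict[Tuple[str, str], TssCluster] = {}
    for cl in survivors:
        key = (cl.interval.chrom, cl.interval.strand)
        prev = last.get(key)
        if (
            prev is not None
            and cl.interval.start >= prev.interval.start
            and cl.interval.end <= prev.interval.end
        ):
            continue  # nested inside an already kept cluster
        kept.append(cl)
        last[key] = cl
    return kept


def pool_tracks(tracks: Sequence[CtssTrack]) -> CtssTrack:
    """Sum CTSS counts across samples to define one TSS coordinate system."""
    records = []
    for t in tracks:
        records.extend(t.iter_records())
    return CtssTrack.from_records(records)


def count_in_clusters(
    clusters: Sequence[TssCluster], tracks: Sequence[CtssTrack]
) -> np.ndarray:
    """Re-tally per-sample counts within cluster intervals.

    Returns an array of shape (n_clusters, n_samples).
    """
    out = np.zeros((len(clusters), len(tracks)), dtype=np.int64)
    for j, track in enumerate(tracks):
        for i, cl in enumerate(clusters):
            key = (cl.interval.chrom, cl.interval.strand)
            if key not in track.entries:
                continue
            pos, cnt = track.entries[key]
            lo = np.searchsorted(pos, cl.interval.start, side="left")
            hi = np.searchsorted(pos, cl.interval.end, side="left")
            out[i, j] = cnt[lo:hi].sum()
    return out
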