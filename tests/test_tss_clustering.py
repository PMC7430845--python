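import numpy as np
import pytest

from promscan.io_formats import CtssTrack, GenomicInterval
from promscan.tss_clustering import (
    TssCluster,
    cluster_ctss,
    count_in_clusters,
    filter_clusters,
    pool_tracks,
)


def brute_force_maximal_segments(pos, cnt, d):
    """Independent enumeration of maximal-scoring segments at density d.

    A site-delimited segment scores sum(counts) - d * bp_length. It is
    locally maximal when the whole segment and every prefix/suffix at every
    cut score positively; the maximal segments are the locally maximal ones
    not contained in a larger locally maximal one.
    """
    n = len(pos)
    candidates = []
    for i in range(n):
        for j in range(i, n):
            length = pos[j] + 1 - pos[i]
            if cnt[i : j + 1].sum() - d * length <= 0:
                continue
            ok = True
            for k in range(i + 1, j + 1):
                prefix = cnt[i:k].sum() - d * (pos[k] - pos[i])
                suffix = cnt[k : j + 1].sum() - d * (pos[j] - pos[k - 1])
                if prefix <= 0 or suffix <= 0:
                    ok = False
                    break
            if ok:
                candidates.append((int(pos[i]), int(pos[j]) + 1))
    return {
        c
        for c in candidates
        if not any(o != c and o[0] <= c[0] and c[1] <= o[1] for o in candidates)
    }


def track_from_arrays(pos, cnt, strand="+", chrom="chr1"):
    return CtssTrack.from_records(
        [(chrom, int(p), strand, int(c)) for p, c in zip(pos, cnt)]
    )


class TestClusterCtss:
    def test_single_site(self, single_site_track):
        clusters = cluster_ctss(single_site_track)
        assert len(clusters) == 1
        cl = clusters[0]
        assert (cl.interval.start, cl.interval.end) == (100, 101)
        assert cl.total_count == 5
        assert cl.anchor == 100
        assert cl.max_density == 5.0

    def test_empty_track(self):
        assert cluster_ctss(CtssTrack()) == []

    def test_strands_cluster_independently(self):
        track = CtssTrack.from_records(
            [("chr1", 100, "+", 5), ("chr1", 101, "-", 5)]
        )
        clusters = cluster_ctss(track)
        assert len(clusters) == 2
        assert {c.interval.strand for c in clusters} == {"+", "-"}

    def test_oracle_equivalence_random_instances(self):
        """The nested family equals brute-force enumeration across densities."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(1, 16))
            pos = np.sort(rng.choice(300, size=n, replace=False)).astype(int)
            cnt = rng.integers(1, 20, size=n).astype(int)
            clusters = cluster_ctss(track_from_arrays(pos, cnt))
            bounds = sorted(
                {c.min_density for c in clusters} | {c.max_density for c in clusters}
            )
            probes = list(np.linspace(0.01, cnt.max(), 25))
            probes += [(c.min_density + c.max_density) / 2 for c in clusters]
            for d in probes:
                if any(abs(d - b) < 1e-9 for b in bounds):
                    continue  # boundary densities are ambiguous by definition
                impl = {
                    (c.interval.start, c.interval.end)
                    for c in clusters
                    if c.min_density < d < c.max_density
                }
                assert impl == brute_force_maximal_segments(pos, cnt, d)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(500, size=12, replace=False))
        cnt = rng.integers(1, 30, size=12)
        base = cluster_ctss(track_from_arrays(pos, cnt))
        scaled = cluster_ctss(track_from_arrays(pos, cnt * 3))
        assert len(base) == len(scaled)
        for a, b in zip(base, scaled):
            assert a.interval == b.interval
            assert b.min_density == pytest.approx(3 * a.min_density)
            assert b.max_density == pytest.approx(3 * a.max_density)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(500, size=10, replace=False))
        cnt = rng.integers(1, 30, size=10)
        base = cluster_ctss(track_from_arrays(pos, cnt))
        shifted = cluster_ctss(track_from_arrays(pos + 1234, cnt))
        for a, b in zip(base, shifted):
            assert b.interval.start == a.interval.start + 1234
            assert b.interval.end == a.interval.end + 1234
            assert b.min_density == pytest.approx(a.min_density)
            assert b.max_density == pytest.approx(a.max_density)

    def test_anchor_is_five_prime_most_modal_base(self):
        pos = np.array([100, 105, 110])
        cnt = np.array([7, 7, 3])
        plus = cluster_ctss(track_from_arrays(pos, cnt, "+"))
        minus = cluster_ctss(track_from_arrays(pos, cnt, "-"))
        outer_plus = max(plus, key=lambda c: c.length)
        outer_minus = max(minus, key=lambda c: c.length)
        assert outer_plus.anchor == 100
        assert outer_minus.anchor == 105


def _mk(start, end, total, min_d, max_d, n_sites=3, strand="+"):
    return TssCluster(
        interval=GenomicInterval("chr1", start, end, strand),
        total_count=total,
        anchor=start,
        min_density=min_d,
        max_density=max_d,
        n_sites=n_sites,
    )


class TestFilterClusters:
    def test_length_threshold(self):
        assert filter_clusters([_mk(0, 250, 100, 1, 10)], max_length=200) == []

    def test_total_threshold(self):
        assert filter_clusters([_mk(0, 50, 9, 1, 10)], min_total=10) == []

    def test_stability_threshold(self):
        assert filter_clusters([_mk(0, 50, 100, 10, 19)], min_stability=2) == []
        kept = filter_clusters([_mk(0, 50, 100, 10, 20)], min_stability=2)
        assert len(kept) == 1

    def test_root_cluster_is_infinitely_stable(self):
        kept = filter_clusters([_mk(0, 50, 100, 0.0, 5.0)], min_stability=2)
        assert len(kept) == 1

    def test_nested_pair_keeps_outer(self):
        outer = _mk(0, 100, 100, 1, 10)
        inner = _mk(20, 40, 60, 2, 30)
        kept = filter_clusters([inner, outer], min_total=1, min_stability=2)
        assert kept == [outer]

    def test_nested_pair_inner_survives_when_outer_fails(self):
        outer = _mk(0, 100, 100, 8, 10)  # stability 1.25: removed
        inner = _mk(20, 40, 60, 2, 30)
        kept = filter_clusters([inner, outer], min_total=1, min_stability=2)
        assert kept == [inner]


class TestPoolingAndRecounting:
    def test_pooled_counts_sum_samples(self):
        t1 = CtssTrack.from_records([("chr1", 10, "+", 2)])
        t2 = CtssTrack.from_records([("chr1", 10, "+", 3), ("chr1", 12, "+", 1)])
        pooled = pool_tracks([t1, t2])
        pos, cnt = pooled.entries[("chr1", "+")]
        assert pos.tolist() == [10, 12]
        assert cnt.tolist() == [5, 1]

    def test_per_sample_retally_within_clusters(self):
        t1 = CtssTrack.from_records([("chr1", 10, "+", 2), ("chr1", 50, "+", 9)])
        t2 = CtssTrack.from_records([("chr1", 11, "+", 3)])
        clusters = [_mk(10, 12, 5, 0, 5, n_sites=2)]
        counts = count_in_clusters(clusters, [t1, t2])
        assert counts.tolist() == [[2, 3]]
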