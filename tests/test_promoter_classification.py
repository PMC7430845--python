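import numpy as np
import pytest

from promscan.io_formats import GenomicInterval, PeakSet, TranscriptModel
from promscan.promoter_classification import (
    assign_genes,
    attach_expression,
    classify_tss,
    records_to_frame,
    summarize_classes,
)
from promscan.synthetic_data import match_records_to_truth
from promscan.tss_clustering import TssCluster, cluster_ctss, filter_clusters, pool_tracks


def mk_cluster(anchor, strand="+", chrom="chr1", total=20):
    return TssCluster(
        interval=GenomicInterval(chrom, anchor, anchor + 1, strand),
        total_count=total,
        anchor=anchor,
        min_density=0.0,
        max_density=float(total),
        n_sites=1,
    )


def peakset(name, *spans):
    return PeakSet(name, [GenomicInterval("chr1", s, e) for s, e in spans])


class TestClassifyTss:
    def test_both_requires_overlapping_peak_pair(self):
        h3 = peakset("H3K4me3", (1500, 2600))
        so = peakset("SOX10", (2400, 2800))
        (rec,) = classify_tss([mk_cluster(1000)], h3, so)
        assert rec.class_label == "BOTH"

    def test_h3_only_when_sox10_does_not_overlap(self):
        h3 = peakset("H3K4me3", (1500, 2600))
        so = peakset("SOX10", (5000, 5400))  # not overlapping, not within 1 kb
        (rec,) = classify_tss([mk_cluster(1000)], h3, so)
        assert rec.class_label == "H3K4ME3_ONLY"

    def test_residual_both_near_but_disjoint_is_h3_only(self):
        # both marks within 1 kb of the anchor but the peaks never overlap
        h3 = peakset("H3K4me3", (1200, 1400))
        so = peakset("SOX10", (400, 600))
        (rec,) = classify_tss([mk_cluster(1000)], h3, so)
        assert rec.class_label == "H3K4ME3_ONLY"
        assert rec.sox10_distance is not None

    def test_sox10_only_and_neither(self):
        h3 = peakset("H3K4me3")
        so = peakset("SOX10", (1800, 2200))
        (rec,) = classify_tss([mk_cluster(1000)], h3, so)
        assert rec.class_label == "SOX10_ONLY"
        (rec2,) = classify_tss([mk_cluster(1000)], peakset("a"), peakset("b"))
        assert rec2.class_label == "NEITHER"

    def test_window_boundary_is_inclusive(self):
        # peak starts exactly window bp downstream of the anchor
        h3 = peakset("H3K4me3", (2000, 2100))
        (rec,) = classify_tss([mk_cluster(1000)], h3, peakset("s"), window=1000)
        assert rec.class_label == "H3K4ME3_ONLY"
        assert rec.h3k4me3_distance == 1000
        h3_far = peakset("H3K4me3", (2001, 2100))
        (rec2,) = classify_tss([mk_cluster(1000)], h3_far, peakset("s"), window=1000)
        assert rec2.class_label == "NEITHER"

    def test_invariant_to_peak_order_and_abutting_split(self):
        anchorses = [mk_cluster(a) for a in (500, 1000, 2500, 4000)]
        h3_whole = peakset("H3K4me3", (1500, 2600))
        h3_split = peakset("H3K4me3", (2000, 2600), (1500, 2000))
        so = peakset("SOX10", (2400, 2800))
        labels_whole = [r.class_label for r in classify_tss(anchorses, h3_whole, so)]
        labels_split = [r.class_label for r in classify_tss(anchorses, h3_split, so)]
        assert labels_whole == labels_split

    def test_label_rederivable_from_stored_distances(self):
        h3 = peakset("H3K4me3", (1500, 2600))
        so = peakset("SOX10", (2400, 2800), (9000, 9100))
        records = classify_tss(
            [mk_cluster(a) for a in (1000, 5500, 8500, 20_000)], h3, so
        )
        for rec in records:
            if rec.class_label in ("BOTH", "H3K4ME3_ONLY"):
                assert rec.h3k4me3_distance is not None
                assert rec.h3k4me3_distance <= 1000
            elif rec.class_label == "SOX10_ONLY":
                assert rec.h3k4me3_distance is None
                assert rec.sox10_distance <= 1000
            else:
                assert rec.h3k4me3_distance is None
                assert rec.sox10_distance is None

    def test_synthetic_study_labels_recovered_exactly(self, study):
        objects, truth = study["objects"], study["truth"]
        tracks = [t for model in objects["tracks"].values() for t in model]
        clusters = filter_clusters(cluster_ctss(pool_tracks(tracks)))
        records = classify_tss(clusters, objects["h3k4me3"], objects["sox10"])
        matched = match_records_to_truth(records, truth)
        assert len(matched) == len(records)
        assert (matched["recovered_class"] == matched["class_label"]).all()


def tx(gene, start, end, strand, chrom="chr1", tid=None, cds=""):
    return TranscriptModel(
        gene_id=gene,
        transcript_id=tid or f"{gene}.t1",
        span=GenomicInterval(chrom, start, end, strand),
        cds_key=cds,
    )


class TestAssignGenes:
    def test_within_extended_span_same_strand(self):
        recs = classify_tss([mk_cluster(500)], peakset("a"), peakset("b"))
        out = assign_genes(recs, [tx("g1", 1000, 3000, "+")], window=1000)
        assert out[0].gene_id == "g1"

    def test_opposite_strand_unassigned(self):
        recs = classify_tss([mk_cluster(500, strand="-")], peakset("a"), peakset("b"))
        out = assign_genes(recs, [tx("g1", 1000, 3000, "+")], window=1000)
        assert out[0].gene_id is None

    def test_tie_break_deterministic_under_input_order(self):
        # two genes equidistant from the anchor, same span length
        genes = [
            tx("gB", 2000, 3000, "+"),
            tx("gA", 2000, 3000, "+", tid="gA.t1"),
        ]
        recs = classify_tss([mk_cluster(1500)], peakset("a"), peakset("b"))
        first = assign_genes(recs, genes, window=1000)[0].gene_id
        second = assign_genes(recs, list(reversed(genes)), window=1000)[0].gene_id
        assert first == second == "gA"

    def test_nearest_gene_wins(self):
        genes = [tx("near", 2000, 2500, "+"), tx("far", 2300, 2800, "+")]
        recs = classify_tss([mk_cluster(1500)], peakset("a"), peakset("b"))
        out = assign_genes(recs, genes, window=1000)
        assert out[0].gene_id == "near"

    def test_gene_span_is_union_of_transcripts(self):
        genes = [
            tx("g1", 5000, 6000, "+", tid="t1"),
            tx("g1", 2000, 2500, "+", tid="t2"),
        ]
        recs = classify_tss([mk_cluster(3000)], peakset("a"), peakset("b"))
        out = assign_genes(recs, genes, window=100)
        assert out[0].gene_id == "g1"  # inside the union span
        assert out[0].gene_distance == 0

    def test_fallback_map_rescues_unassigned(self):
        genes = [tx("gm", 100, 400, "+", chrom="chrM")]
        recs = classify_tss([mk_cluster(50_000)], peakset("a"), peakset("b"))
        fallback = {("chr1", 50_000): ("chrM", 200)}
        out = assign_genes(recs, genes, window=100, fallback_map=fallback)
        assert out[0].gene_id == "gm"


class TestSummaries:
    def test_zero_mapped_is_zero_percent(self):
        recs = classify_tss(
            [mk_cluster(i * 5000) for i in range(1, 11)], peakset("a"), peakset("b")
        )
        summary = summarize_classes(recs)
        total_row = summary.table[summary.table["class"] == "Total"].iloc[0]
        assert total_row["n_tss"] == 10
        assert total_row["percent_within_1kb"] == 0.0

    def test_class_fractions_sum_to_100(self, study):
        objects = study["objects"]
        tracks = [t for model in objects["tracks"].values() for t in model]
        clusters = filter_clusters(cluster_ctss(pool_tracks(tracks)))
        records = classify_tss(clusters, objects["h3k4me3"], objects["sox10"])
        records = assign_genes(records, objects["transcripts"])
        table = summarize_classes(records).table
        per_class = table[table["class"] != "Total"]
        assert per_class["n_tss"].sum() == len(records)
        assert per_class["percent_of_total"].sum() == pytest.approx(100.0, abs=0.4)

    def test_rpm_and_density_definitions(self):
        recs = classify_tss([mk_cluster(100, total=50)], peakset("a"), peakset("b"))
        out = attach_expression(recs, np.array([[50]]), ["s1"], [1_000_000])
        assert out[0].rpm == pytest.approx(50.0)
        assert out[0].rpm_density == pytest.approx(50.0 * 100 / 1)
        frame = records_to_frame(out)
        assert frame.loc[0, "count_s1"] == 50
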