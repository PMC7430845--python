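#!/usr/bin/env python
"""Cluster the pooled CTSS of all samples into TSSs, classify each TSS by
its proximity to H3K4me3 and SOX10 peaks (BOTH / H3K4ME3_ONLY / SOX10_ONLY /
NEITHER), assign TSSs to genes on the same strand within 1 kb, and tabulate
per-class gene-mapping rates and the per-class expression ECDF.

Reads results/study/; writes tss_records.tsv, class_summary.tsv and
ecdf_rpm.tsv under results/."""

from pathlib import Path

from promscan.io_formats import (
    read_ctss,
    read_peaks,
    read_transcripts,
    write_tss_table,
)
from promscan.promoter_classification import (
    assign_genes,
    attach_expression,
    classify_tss,
    records_to_frame,
    summarize_classes,
)
from promscan.report_stats import ecdf_table
from promscan.tss_clustering import (
    cluster_ctss,
    count_in_clusters,
    filter_clusters,
    pool_tracks,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = RESULTS / "study"
    ctss_paths = sorted(study.glob("ctss_*.tsv"))
    sample_names = [p.stem.replace("ctss_", "") for p in ctss_paths]
    tracks = [read_ctss(p) for p in ctss_paths]

    pooled = pool_tracks(tracks)
    clusters = filter_clusters(cluster_ctss(pooled))
    print(f"{pooled.n_sites:,} CTSS positions -> {len(clusters)} TSS clusters")

    h3 = read_peaks(study / "h3k4me3_peaks.bed", "H3K4me3")
    so = read_peaks(study / "sox10_peaks.bed", "SOX10")
    records = classify_tss(clusters, h3, so, window=1000)
    records = assign_genes(records, read_transcripts(study / "transcripts.tsv"))
    counts = count_in_clusters(clusters, tracks)
    records = attach_expression(
        records, counts, sample_names, [max(1, t.library_size) for t in tracks]
    )

    write_tss_table(records_to_frame(records), RESULTS / "tss_records.tsv")
    summary = summarize_classes(records)
    summary.table.to_csv(RESULTS / "class_summary.tsv", sep="\t", index=False)
    print("\nper-class gene-mapping summary:")
    print(summary.table.to_string(index=False))
    if summary.n_residual_both_no_overlap:
        print(
            f"\nnote: {summary.n_residual_both_no_overlap} TSSs had both marks "
            "within 1 kb without a peak-on-peak overlap (labelled H3K4ME3_ONLY)"
        )

    by_class = {}
    for r in records:
        by_class.setdefault(r.class_label, []).append(r.rpm)
    ecdf_table(by_class).to_csv(RESULTS / "ecdf_rpm.tsv", sep="\t", index=False)
    print("\nwrote tss_records.tsv, class_summary.tsv, ecdf_rpm.tsv")


if __name__ == "__main__":
    main()
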