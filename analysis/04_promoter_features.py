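#!/usr/bin/env python
"""Characterize promoter classes by sequence and signal features, contrasting
knockout-dependent (DOWN) against unchanged TSSs as in the upstream study:
aggregate ChIP signal around TSS anchors (with a permutation AUC test),
binding-motif counts per peak (one mismatch allowed), per-motif conservation,
CpG islands around anchors, and strand-oriented GC profiles.

Reads results/study/, results/tss_records.tsv and results/de_sox10_loss.tsv;
writes metagene.tsv, motifs_per_peak.tsv, motif_conservation.tsv,
cpg_fraction.tsv, gc_profile.tsv and feature_contrasts.tsv under results/."""

from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from promscan.io_formats import GenomicInterval, read_peaks, read_signal
from promscan.metagene import compare_profiles_auc, metagene_profile
from promscan.promoter_classification import TssRecord
from promscan.report_stats import mann_whitney_u
from promscan.sequence_features import (
    MotifSpec,
    cpg_fraction_by_offset,
    cpg_islands,
    gc_profile,
    motif_conservation,
    motifs_per_peak,
    scan_motifs,
)
from promscan.tss_clustering import TssCluster

RESULTS = Path(__file__).resolve().parent.parent / "results"
WINDOW = 1000


def load_records():
    frame = pd.read_csv(RESULTS / "tss_records.tsv", sep="\t")
    status = (
        pd.read_csv(RESULTS / "de_sox10_loss.tsv", sep="\t")
        .set_index("tss_id")["status"]
    )
    records = []
    for row in frame.itertuples(index=False):
        cluster = TssCluster(
            interval=GenomicInterval(row.chrom, row.start, row.end, row.strand),
            total_count=row.total_count,
            anchor=row.anchor,
            min_density=row.min_density,
            max_density=row.max_density,
            n_sites=row.n_sites,
        )
        records.append(TssRecord(cluster=cluster, class_label=row.class_label))
    return frame, records, status


def main() -> None:
    study = RESULTS / "study"
    frame, records, status = load_records()
    by_status = {}
    for rec in records:
        by_status.setdefault(status.get(rec.tss_id, "NA"), []).append(rec)

    # metagene: aggregate ChIP signal per status class + permutation AUC test
    signal = read_signal(study / "sox10_signal.bedgraph")
    profiles = metagene_profile(by_status, signal, window=WINDOW)
    rows = [
        {"status": label, "offset": o, "mean_signal": v}
        for label, prof in profiles.items()
        for o, v in zip(prof.offsets.tolist(), prof.mean_signal.tolist())
    ]
    pd.DataFrame(rows).to_csv(RESULTS / "metagene.tsv", sep="\t", index=False)
    p_auc = compare_profiles_auc(
        by_status["DOWN"], by_status["UNCHANGED"], signal,
        window=WINDOW, n_perm=10_000, seed=1,
    )
    print(f"metagene AUC permutation p (DOWN vs UNCHANGED): {p_auc:.2e}")

    genome = {name: str(rec[:]) for name, rec in Fasta(str(study / "genome.fa")).items()}
    cons = read_signal(study / "conservation.bedgraph")
    so = read_peaks(study / "sox10_peaks.bed", "SOX10")
    spec = MotifSpec("monomer", "WWCAAWG", max_mismatch=1)

    # status of the TSS nearest each peak / hit
    anchors = frame[["tss_id", "chrom", "anchor"]]

    def status_near(chrom, pos):
        sub = anchors[anchors["chrom"] == chrom]
        d = (sub["anchor"] - pos).abs()
        if len(d) == 0 or d.min() > 1500:
            return "NA"
        return status.get(sub.loc[d.idxmin(), "tss_id"], "NA")

    n_motifs = motifs_per_peak(so, genome, spec)
    peak_status = [
        status_near(iv.chrom, (iv.start + iv.end) // 2) for iv in so.intervals
    ]
    pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in so.intervals],
            "start": [iv.start for iv in so.intervals],
            "end": [iv.end for iv in so.intervals],
            "status": peak_status,
            "n_motifs": n_motifs,
        }
    ).to_csv(RESULTS / "motifs_per_peak.tsv", sep="\t", index=False)

    regions = [
        (iv.chrom, iv.start, genome[iv.chrom][iv.start : iv.end])
        for iv in so.intervals
    ]
    hits = scan_motifs(regions, spec)
    scores = motif_conservation(hits, cons)
    hit_status = [status_near(h.interval.chrom, h.interval.start) for h in hits]
    pd.DataFrame(
        {
            "chrom": [h.interval.chrom for h in hits],
            "start": [h.interval.start for h in hits],
            "n_mismatches": [h.n_mismatches for h in hits],
            "status": hit_status,
            "mean_conservation": scores,
        }
    ).to_csv(RESULTS / "motif_conservation.tsv", sep="\t", index=False)

    # CpG islands over each anchor window
    islands = []
    anchor_island = {}
    for rec in records:
        seq = genome[rec.cluster.interval.chrom]
        lo = max(0, rec.anchor - WINDOW)
        isl = cpg_islands(
            seq[lo : rec.anchor + WINDOW], chrom=rec.cluster.interval.chrom,
            origin=lo,
        )
        islands.extend(isl)
        anchor_island[rec.tss_id] = any(
            i.interval.start <= rec.anchor < i.interval.end for i in isl
        )
    cpg_fraction_by_offset(by_status, islands, window=WINDOW).to_csv(
        RESULTS / "cpg_fraction.tsv", sep="\t", index=False
    )
    gc_profile(by_status, genome, window=WINDOW).to_csv(
        RESULTS / "gc_profile.tsv", sep="\t", index=False
    )

    # dependent-vs-unchanged contrasts
    def split(values, labels):
        groups = {"DOWN": [], "UNCHANGED": []}
        for v, s in zip(values, labels):
            if s in groups:
                groups[s].append(v)
        return groups["DOWN"], groups["UNCHANGED"]

    contrasts = []
    down, unch = split(n_motifs.tolist(), peak_status)
    _, p = mann_whitney_u(down, unch)
    contrasts.append(("motifs_per_peak", np.mean(down), np.mean(unch), p))
    down, unch = split(scores.tolist(), hit_status)
    _, p = mann_whitney_u(down, unch)
    contrasts.append(("motif_conservation", np.mean(down), np.mean(unch), p))
    island_flags = [int(anchor_island[r.tss_id]) for r in records]
    island_status = [status.get(r.tss_id, "NA") for r in records]
    down, unch = split(island_flags, island_status)
    _, p = mann_whitney_u(down, unch)
    contrasts.append(("anchor_in_cpg_island", np.mean(down), np.mean(unch), p))
    table = pd.DataFrame(
        contrasts, columns=["feature", "mean_down", "mean_unchanged", "mw_p"]
    )
    table.to_csv(RESULTS / "feature_contrasts.tsv", sep="\t", index=False)
    print("\ndependent (DOWN) vs unchanged feature contrasts:")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
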