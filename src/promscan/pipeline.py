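"""End-to-end orchestration: cluster -> classify -> differential expression
-> metagene -> sequence features -> tissue specificity -> report.

A single :class:`RunConfig` (YAML-loadable) names every input and parameter;
``run_all`` executes the stages in order, writes per-stage TSVs under the
output directory, and records a manifest with input checksums, parameters
and per-stage row counts. Identical config + inputs + seed give identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from .differential_expression import run_de
from .metagene import compare_profiles_auc, metagene_profile
from .promoter_classification import (
    assign_genes,
    attach_expression,
    classify_tss,
    records_to_frame,
    summarize_classes,
)
from .report_stats import ecdf_table
from .sequence_features import (
    MotifSpec,
    cpg_fraction_by_offset,
    cpg_islands,
    gc_profile,
    motif_conservation,
    motifs_per_peak,
    scan_motifs,
)
from .tissue_specificity import tau_table
from .tss_clustering import cluster_ctss, count_in_clusters, filter_clusters, pool_tracks

__all__ = ["RunConfig", "run_all", "analyze_study_objects"]


@dataclass
class RunConfig:
    """Paths and parameters for a full run."""

    # inputs: sample name -> CTSS path, and sample name -> group label
    ctss: Dict[str, str] = field(default_factory=dict)
    groups: Dict[str, str] = field(default_factory=dict)
    # contrasts: name -> [group_a, group_b]
    contrasts: Dict[str, List[str]] = field(default_factory=dict)
    h3k4me3_peaks: str = ""
    sox10_peaks: str = ""
    genome_fasta: str = ""
    chip_signal: str = ""
    conservation: str = ""
    transcripts: str = ""
    tissue_counts: str = ""  # optional TSV: rows keyed by region id
    tissue_map: str = ""  # optional TSV: row_id, chrom, pos, strand
    outdir: str = "promscan_out"
    # parameters
    window: int = 1000
    max_length: int = 200
    min_total: int = 10
    min_stability: float = 2.0
    alpha: float = 0.05
    min_cpm: float = 1.0
    min_samples: int = 2
    motif_consensus: str = "WWCAAWG"
    motif_max_mismatch: int = 1
    dimer_spacer_min: int = 3
    dimer_spacer_max: int = 6
    n_perm: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate(self) -> None:
        required = [self.h3k4me3_peaks, self.sox10_peaks]
        for p in list(self.ctss.values()) + [p for p in required if p]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for opt in (
            self.genome_fasta,
            self.chip_signal,
            self.conservation,
            self.transcripts,
            self.tissue_counts,
            self.tissue_map,
        ):
            if opt and not Path(opt).exists():
                raise FileNotFoundError(opt)
        if not self.ctss:
            raise ValueError("at least one CTSS input is required")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _read_fasta(path: str | Path) -> Dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def run_all(config: RunConfig) -> Dict[str, object]:
    """Run every stage; returns the manifest dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "inputs": {},
        "parameters": {
            k: v
            for k, v in config.__dict__.items()
            if (not isinstance(v, dict) or k in ("contrasts",))
            and k != "outdir"
        },
        "stages": {},
    }
    for name, path in list(config.ctss.items()) + [
        ("h3k4me3_peaks", config.h3k4me3_peaks),
        ("sox10_peaks", config.sox10_peaks),
    ]:
        manifest["inputs"][name] = _sha256(path)

    # stage 1: clustering on pooled CTSS ------------------------------------
    sample_names = sorted(config.ctss)
    tracks = [iof.read_ctss(config.ctss[s]) for s in sample_names]
    pooled = pool_tracks(tracks)
    clusters = filter_clusters(
        cluster_ctss(pooled),
        max_length=config.max_length,
        min_total=config.min_total,
        min_stability=config.min_stability,
    )
    manifest["stages"]["clusters"] = len(clusters)

    # stage 2: classification + gene assignment -----------------------------
    h3 = iof.read_peaks(config.h3k4me3_peaks, "H3K4me3")
    so = iof.read_peaks(config.sox10_peaks, "SOX10")
    records = classify_tss(clusters, h3, so, window=config.window)
    if config.transcripts:
        transcripts = iof.read_transcripts(config.transcripts)
        records = assign_genes(records, transcripts, window=config.window)
    counts = count_in_clusters(clusters, tracks)
    lib_sizes = [max(1, t.library_size) for t in tracks]
    records = attach_expression(records, counts, sample_names, lib_sizes)
    frame = records_to_frame(records)
    iof.write_tss_table(frame, outdir / "tss_records.tsv")
    summary = summarize_classes(records)
    summary.table.to_csv(outdir / "class_summary.tsv", sep="\t", index=False)
    manifest["stages"]["classified"] = len(records)

    # expression ECDF per class (mean RPM across samples)
    by_class: Dict[str, list] = {}
    for r in records:
        by_class.setdefault(r.class_label, []).append(r.rpm)
    ecdf_table(by_class).to_csv(outdir / "ecdf_rpm.tsv", sep="\t", index=False)

    # stage 3: differential expression per contrast --------------------------
    group_vec = [config.groups.get(s, s) for s in sample_names]
    tss_ids = [r.tss_id for r in records]
    de_tables: Dict[str, pd.DataFrame] = {}
    for cname, (ga, gb) in config.contrasts.items():
        # group_a columns first so log2FC is log2(group_b / group_a)
        cols = [i for i, g in enumerate(group_vec) if g == ga]
        cols += [i for i, g in enumerate(group_vec) if g == gb]
        sub = counts[:, cols]
        sub_groups = [group_vec[i] for i in cols]
        de = run_de(
            sub,
            sub_groups,
            row_ids=tss_ids,
            alpha=config.alpha,
            min_cpm=config.min_cpm,
            min_samples=config.min_samples,
        )
        de.to_csv(outdir / f"de_{cname}.tsv", sep="\t", index=False)
        de_tables[cname] = de
        manifest["stages"][f"de_{cname}"] = len(de)

    # stage 4: metagene -------------------------------------------------------
    if config.chip_signal:
        signal = iof.read_signal(config.chip_signal)
        recs_by_class = {}
        for r in records:
            recs_by_class.setdefault(r.class_label, []).append(r)
        profiles = metagene_profile(recs_by_class, signal, window=config.window)
        rows = []
        for label, prof in profiles.items():
            for off, v in zip(prof.offsets.tolist(), prof.mean_signal.tolist()):
                rows.append({"class": label, "offset": off, "mean_signal": v})
        pd.DataFrame(rows).to_csv(outdir / "metagene.tsv", sep="\t", index=False)
        if "BOTH" in recs_by_class and "H3K4ME3_ONLY" in recs_by_class:
            p = compare_profiles_auc(
                recs_by_class["BOTH"],
                recs_by_class["H3K4ME3_ONLY"],
                signal,
                window=config.window,
                n_perm=config.n_perm,
                seed=config.seed,
            )
            manifest["stages"]["metagene_auc_p_both_vs_h3only"] = p

    # stage 5: sequence features ---------------------------------------------
    if config.genome_fasta:
        genome = _read_fasta(config.genome_fasta)
        mono = MotifSpec(
            name="monomer",
            iupac=config.motif_consensus,
            max_mismatch=config.motif_max_mismatch,
        )
        counts_per_peak = motifs_per_peak(so, genome, mono)
        pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in so.intervals],
                "start": [iv.start for iv in so.intervals],
                "end": [iv.end for iv in so.intervals],
                "n_motifs": counts_per_peak,
            }
        ).to_csv(outdir / "motifs_per_peak.tsv", sep="\t", index=False)
        if config.conservation:
            cons = iof.read_signal(config.conservation)
            regions = [
                (iv.chrom, iv.start, genome[iv.chrom][iv.start : iv.end])
                for iv in so.intervals
            ]
            hits = scan_motifs(regions, mono)
            scores = motif_conservation(hits, cons)
            pd.DataFrame(
                {
                    "chrom": [h.interval.chrom for h in hits],
                    "start": [h.interval.start for h in hits],
                    "end": [h.interval.end for h in hits],
                    "strand": [h.strand for h in hits],
                    "n_mismatches": [h.n_mismatches for h in hits],
                    "mean_conservation": scores,
                }
            ).to_csv(outdir / "motif_conservation.tsv", sep="\t", index=False)
            manifest["stages"]["motif_hits"] = len(hits)

        # CpG islands over each TSS window
        islands = []
        for r in records:
            chrom = r.cluster.interval.chrom
            seq = genome[chrom]
            lo = max(0, r.anchor - config.window)
            hi = min(len(seq), r.anchor + config.window)
            islands.extend(
                cpg_islands(seq[lo:hi], chrom=chrom, origin=lo)
            )
        recs_by_class = {}
        for r in records:
            recs_by_class.setdefault(r.class_label, []).append(r)
        cpg_fraction_by_offset(recs_by_class, islands, window=config.window).to_csv(
            outdir / "cpg_fraction.tsv", sep="\t", index=False
        )
        gc_profile(recs_by_class, genome, window=config.window).to_csv(
            outdir / "gc_profile.tsv", sep="\t", index=False
        )
        manifest["stages"]["cpg_islands"] = len(islands)

    # stage 6: tissue specificity --------------------------------------------
    if config.tissue_counts:
        tissue = pd.read_csv(config.tissue_counts, sep="\t", index_col=0)
        tau = tau_table(tissue)
        tau.to_csv(outdir / "tau.tsv", sep="\t")
        manifest["stages"]["tau_scored"] = int(tau["tau"].notna().sum())

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def analyze_study_objects(
    objects: Dict[str, object],
    motif_spec: Optional[MotifSpec] = None,
    window: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> Dict[str, object]:
    """In-memory composition of the full analysis over a simulated study.

    Runs clustering on the pooled CTSS of every sample, classification
    against the two peak sets, both differential-expression contrasts
    (differentiation: control vs cAMP; knockout: parental vs knockout), and
    the promoter feature stages (per-peak motif counts, per-hit motif
    conservation, CpG islands over TSS windows, Tau scores). Returns the
    intermediate products keyed by stage, with every per-TSS table indexed by
    ``tss_id``.
    """
    if motif_spec is None:
        motif_spec = MotifSpec(name="monomer", iupac="WWCAAWG", max_mismatch=1)

    tracks_by_model: Dict[str, list] = objects["tracks"]
    sample_names: Dict[str, list] = objects["sample_names"]
    all_tracks = [t for model in tracks_by_model.values() for t in model]
    pooled = pool_tracks(all_tracks)
    clusters = filter_clusters(cluster_ctss(pooled))
    records = classify_tss(
        clusters, objects["h3k4me3"], objects["sox10"], window=window
    )

    out: Dict[str, object] = {"clusters": clusters, "records": records}

    # differential expression per model contrast
    contrast_samples = {
        "camp": ("primary", "control", "camp"),
        "sox10_loss": ("s16", "parental", "dsox10"),
    }
    tss_ids = [r.tss_id for r in records]
    for cname, (model, ga, gb) in contrast_samples.items():
        names = sample_names[model]
        tracks = tracks_by_model[model]
        order = [i for i, n in enumerate(names) if f"_{ga}_" in f"_{n}_"]
        order += [i for i, n in enumerate(names) if f"_{gb}_" in f"_{n}_"]
        counts = count_in_clusters(clusters, [tracks[i] for i in order])
        groups = [ga if f"_{ga}_" in f"_{names[i]}_" else gb for i in order]
        out[f"de_{cname}"] = run_de(
            counts, groups, row_ids=tss_ids, alpha=alpha
        ).set_index("tss_id")

    # feature stages
    genome = objects["genome"]
    so: iof.PeakSet = objects["sox10"]
    out["motifs_per_peak"] = motifs_per_peak(so, genome, motif_spec)
    regions = [
        (iv.chrom, iv.start, genome[iv.chrom][iv.start : iv.end])
        for iv in so.intervals
    ]
    hits = scan_motifs(regions, motif_spec)
    out["motif_hits"] = hits
    out["motif_conservation"] = motif_conservation(hits, objects["conservation"])

    islands = []
    anchor_island: Dict[str, bool] = {}
    for r in records:
        seq = genome[r.cluster.interval.chrom]
        lo = max(0, r.anchor - window)
        hi = min(len(seq), r.anchor + window)
        isl = cpg_islands(
            seq[lo:hi], chrom=r.cluster.interval.chrom, origin=lo
        )
        islands.extend(isl)
        anchor_island[r.tss_id] = any(
            i.interval.start <= r.anchor < i.interval.end for i in isl
        )
    out["cpg_islands"] = islands
    out["anchor_has_island"] = anchor_island

    tau = tau_table(objects["tissue_counts"])
    out["tau"] = tau
    return out
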