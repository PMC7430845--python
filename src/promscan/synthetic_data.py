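"""Generate a fully specified miniature promoter study with known ground
truth for every downstream stage.

The generator emulates the structure of a TSS-centric promoter experiment:

* a random genome (FASTA) with promoters placed well apart on both strands,
* stranded CTSS tracks per sample for four cellular models (adult nerve,
  control / differentiated primary cells, parental / factor-knockout line),
  with per-promoter 5' end counts drawn multinomially over a triangular
  61-bp window peaking at the true TSS,
* H3K4me3 (1,000 bp) and SOX10 (400 bp) peak intervals planted per promoter
  class so the 1-kb proximity rule and the peak-on-peak overlap rule are
  exercised separately,
* a SOX10 ChIP signal track with a Gaussian bump over each bound promoter,
  elevated at factor-dependent promoters,
* concrete binding-site realizations of an IUPAC consensus planted inside
  SOX10 peaks (more at dependent promoters), a per-base conservation track
  elevated over planted motifs, and CpG-island sequence planted
  preferentially at promoters that are *not* factor-dependent,
* an 11-tissue expression matrix in which dependent TSSs are one-tissue
  dominant and the rest are largely ubiquitous,
* a transcript annotation with one gene per promoter.

Everything is deterministic for a fixed seed; per-component generators are
derived from the master seed at fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    CtssTrack,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    TranscriptModel,
    write_bedgraph,
    write_ctss,
    write_peaks,
    write_transcripts,
)
from .sequence_features import IUPAC, reverse_complement

__all__ = ["SimConfig", "GroundTruth", "simulate_study", "simulate_counts",
           "simulate_transcript_annotation", "match_records_to_truth", "TISSUES"]

TISSUES = [
    "cortex", "spinal_cord", "skin", "lung", "heart", "colon",
    "thymus", "stomach", "liver", "ovary", "testis",
]
SOX10_POSITIVE_TISSUES = ["spinal_cord", "skin", "cortex"]

MODELS = {  # model -> (group label per replicate)
    "nerve": ["nerve"] * 2,
    "primary": ["control"] * 3 + ["camp"] * 3,
    "s16": ["parental"] * 2 + ["dsox10"] * 4,
}


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic promoter experiment."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    gc_background: float = 0.45
    # promoters per class
    n_both: int = 50
    n_h3k4me3_only: int = 50
    n_sox10_only: int = 50
    n_neither: int = 50
    min_spacing: int = 3_000
    # CTSS shape
    ctss_halfwidth: int = 30  # triangular window = 2*halfwidth + 1 bp
    # per-class mean nerve expression (counts per replicate)
    nerve_mean: Dict[str, float] = field(
        default_factory=lambda: {
            "BOTH": 300.0, "H3K4ME3_ONLY": 200.0,
            "SOX10_ONLY": 100.0, "NEITHER": 30.0,
        }
    )
    # negative-binomial counts
    base_mean: float = 100.0
    dispersion: float = 0.1
    lfc: float = 2.0  # planted |log2 fold change|
    # status fractions within the BOTH class (knockout contrast)
    frac_dependent: float = 0.4
    frac_upregulated: float = 0.1
    frac_not_expressed: float = 0.1
    # differentiation-contrast fractions
    frac_camp_up_dependent: float = 0.5
    frac_camp_down_dependent: float = 0.1
    frac_camp_up_other: float = 0.115
    frac_camp_down_other: float = 0.099
    # peaks
    h3k4me3_width: int = 1_000
    sox10_width: int = 400
    peak_jitter: int = 200
    # motifs
    motif_consensus: str = "WWCAAWG"
    motif_mean_dependent: float = 4.0
    motif_mean_other: float = 1.0
    # fraction of background CpG dinucleotides deaminated (C->T), emulating
    # the genome-wide CpG depletion of vertebrate genomes outside islands
    cpg_depletion: float = 0.8
    # conservation
    conservation_baseline: float = 0.2
    conservation_elevation_dependent: float = 0.8
    conservation_elevation_other: float = 0.4
    # ChIP signal bump amplitude (RPM) per status
    signal_amplitude: Dict[str, float] = field(
        default_factory=lambda: {
            "DOWN": 3.0, "UP": 1.0, "UNCHANGED": 1.0, "NOT_EXPRESSED": 1.0,
            "H3K4ME3_ONLY": 0.3, "SOX10_ONLY": 1.0, "NEITHER": 0.0,
        }
    )
    signal_sd: float = 150.0  # bp spread of the bump
    # CpG islands: exact fraction of promoters planted with an island, by
    # dependence status. The depletion at dependent promoters is sharper than
    # the genome-scale observation it mimics because a 50-promoter class is
    # far too small to resolve a 2x difference in a binary trait.
    cpg_frac_dependent: float = 0.2
    cpg_frac_other: float = 0.9
    cpg_island_length: int = 300
    # tissue specificity
    tissue_mean: float = 100.0
    restricted_fold: float = 20.0
    frac_restricted_other: float = 0.2

    def n_promoters(self) -> Dict[str, int]:
        return {
            "BOTH": self.n_both,
            "H3K4ME3_ONLY": self.n_h3k4me3_only,
            "SOX10_ONLY": self.n_sox10_only,
            "NEITHER": self.n_neither,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class GroundTruth:
    """Planted truth for every emitted promoter, motif and expression row."""

    promoters: pd.DataFrame  # one row per promoter
    motifs: pd.DataFrame  # one row per planted motif occurrence

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.promoters.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        self.motifs.to_csv(outdir / "planted_motifs.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, outdir: str | Path) -> "GroundTruth":
        outdir = Path(outdir)
        return cls(
            promoters=pd.read_csv(outdir / "ground_truth.tsv", sep="\t"),
            motifs=pd.read_csv(outdir / "planted_motifs.tsv", sep="\t"),
        )


def match_records_to_truth(
    records: Sequence,  # TssRecord
    truth: GroundTruth,
    max_distance: int = 500,
) -> pd.DataFrame:
    """Join recovered TSS records to planted promoters by anchor proximity.

    Each record is matched to the nearest same-chromosome, same-strand
    promoter within ``max_distance`` bp of its anchor; unmatched records are
    dropped. Returns the ground-truth rows augmented with the record's
    tss_id, recovered class label and anchor.
    """
    prom = truth.promoters
    rows = []
    for rec in records:
        iv = rec.cluster.interval
        sub = prom[(prom["chrom"] == iv.chrom) & (prom["strand"] == iv.strand)]
        if len(sub) == 0:
            continue
        dist = (sub["tss_pos"] - rec.anchor).abs()
        j = dist.idxmin()
        if dist[j] > max_distance:
            continue
        row = prom.loc[j].to_dict()
        row.update(
            {
                "tss_id": rec.tss_id,
                "recovered_class": rec.class_label,
                "recovered_anchor": rec.anchor,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# standalone count simulator


def simulate_counts(
    n_tss: int,
    n_per_group: int,
    mean: float,
    dispersion: float,
    lfc_vector: Optional[np.ndarray] = None,
    seed: int = 0,
) -> Tuple[np.ndarray, List[str]]:
    """Negative-binomial count matrix for a two-group design.

    Row i has group means ``mean * 2^(-lfc_i/2)`` (group A) and
    ``mean * 2^(+lfc_i/2)`` (group B) at the given dispersion, so the planted
    between-group log2 ratio is exactly ``lfc_i``. Returns (counts, groups)
    with counts of shape (n_tss, 2 * n_per_group).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0 (use ~1e-8 for Poisson-like)")
    lfc = np.zeros(n_tss) if lfc_vector is None else np.asarray(lfc_vector, float)
    if len(lfc) != n_tss:
        raise ValueError("lfc_vector length must equal n_tss")
    rng = np.random.default_rng(seed)
    mu_a = mean * 2.0 ** (-lfc / 2.0)
    mu_b = mean * 2.0 ** (+lfc / 2.0)
    size = 1.0 / dispersion

    def draw(mu: np.ndarray) -> np.ndarray:
        p = size / (size + mu)
        return rng.negative_binomial(
            size, p[:, None], size=(n_tss, n_per_group)
        )

    counts = np.hstack([draw(mu_a), draw(mu_b)])
    groups = ["A"] * n_per_group + ["B"] * n_per_group
    return counts, groups


def simulate_transcript_annotation(
    n_genes: int,
    multi_tss_fraction: float = 0.3,
    multi_cds_fraction: float = 0.15,
    seed: int = 0,
) -> List[TranscriptModel]:
    """Random transcript annotation with a planted fraction of multi-TSS and
    multi-CDS genes, for exercising isoform-diversity counting."""
    rng = np.random.default_rng(seed)
    out: List[TranscriptModel] = []
    pos = 1_000
    for g in range(n_genes):
        gene = f"gene{g:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        multi_tss = rng.random() < multi_tss_fraction
        multi_cds = rng.random() < multi_cds_fraction
        starts = [pos]
        if multi_tss:
            starts.append(pos + int(rng.integers(500, 2_000)))
        for k, s in enumerate(starts):
            cds = f"{gene}_cds{(k if multi_cds else 0)}"
            out.append(
                TranscriptModel(
                    gene_id=gene,
                    transcript_id=f"{gene}.t{k}",
                    span=GenomicInterval("chrSim", s, s + 5_000, strand),
                    cds_key=cds,
                )
            )
        pos += 20_000
    return out


# ---------------------------------------------------------------------------
# full study


def _place_promoters(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic grid placement with jitter; errors if infeasible."""
    counts = cfg.n_promoters()
    total = sum(counts.values())
    if total == 0:
        return pd.DataFrame(
            columns=["promoter_id", "chrom", "tss_pos", "strand", "class_label"]
        )
    per_chrom = int(np.ceil(total / cfg.n_chroms))
    margin = 5_000
    usable = cfg.chrom_length - 2 * margin
    if per_chrom > 0:
        spacing = usable // per_chrom
        if spacing < cfg.min_spacing:
            raise ValueError(
                f"cannot place {per_chrom} promoters per chromosome of "
                f"{cfg.chrom_length} bp with spacing >= {cfg.min_spacing}"
            )
    labels = [lab for lab, n in counts.items() for _ in range(n)]
    rng.shuffle(labels)
    rows = []
    i = 0
    for lab in labels:
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        jitter = int(rng.integers(-cfg.min_spacing // 10, cfg.min_spacing // 10 + 1))
        tss = margin + slot * spacing + spacing // 2 + jitter
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(
            {
                "promoter_id": f"p{i:04d}",
                "chrom": chrom,
                "tss_pos": int(tss),
                "strand": strand,
                "class_label": lab,
            }
        )
        i += 1
    return pd.DataFrame(rows)


def _assign_statuses(
    prom: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Knockout- and differentiation-contrast statuses plus feature truth."""
    prom = prom.copy()
    n = len(prom)
    status = np.array(["UNCHANGED"] * n, dtype=object)
    both_idx = prom.index[prom["class_label"] == "BOTH"].to_numpy()
    shuffled = rng.permutation(both_idx)
    n_dep = int(round(cfg.frac_dependent * len(both_idx)))
    n_up = int(round(cfg.frac_upregulated * len(both_idx)))
    n_ne = int(round(cfg.frac_not_expressed * len(both_idx)))
    status[shuffled[:n_dep]] = "DOWN"
    status[shuffled[n_dep : n_dep + n_up]] = "UP"
    status[shuffled[n_dep + n_up : n_dep + n_up + n_ne]] = "NOT_EXPRESSED"
    prom["sox10_status"] = status

    camp = np.array(["UNCHANGED"] * n, dtype=object)
    for i in range(n):
        if prom["class_label"].iloc[i] != "BOTH":
            continue  # differentiation effects are planted on candidates only
        r = rng.random()
        if status[i] == "DOWN":
            if r < cfg.frac_camp_up_dependent:
                camp[i] = "UP"
            elif r < cfg.frac_camp_up_dependent + cfg.frac_camp_down_dependent:
                camp[i] = "DOWN"
        else:
            if r < cfg.frac_camp_up_other:
                camp[i] = "UP"
            elif r < cfg.frac_camp_up_other + cfg.frac_camp_down_other:
                camp[i] = "DOWN"
    prom["camp_status"] = camp

    dep = prom["sox10_status"] == "DOWN"
    has_sox_peak = prom["class_label"].isin(["BOTH", "SOX10_ONLY"])
    prom["n_planted_motifs"] = np.where(
        has_sox_peak,
        rng.poisson(
            np.where(dep, cfg.motif_mean_dependent, cfg.motif_mean_other)
        ),
        0,
    )
    def exact_subset(mask: np.ndarray, fraction: float) -> np.ndarray:
        """Flag exactly round(fraction * n) members of the masked stratum."""
        idx = np.flatnonzero(mask)
        k = int(round(fraction * len(idx)))
        chosen = rng.permutation(idx)[:k]
        out = np.zeros(len(mask), dtype=bool)
        out[chosen] = True
        return out

    dep_arr = dep.to_numpy()
    prom["has_cpg_island"] = exact_subset(
        dep_arr, cfg.cpg_frac_dependent
    ) | exact_subset(~dep_arr, cfg.cpg_frac_other)
    restricted = dep_arr | exact_subset(~dep_arr, cfg.frac_restricted_other)
    prom["tissue_class"] = np.where(restricted, "restricted", "ubiquitous")
    prom["dominant_tissue"] = [
        SOX10_POSITIVE_TISSUES[int(rng.integers(len(SOX10_POSITIVE_TISSUES)))]
        if r
        else ""
        for r in restricted
    ]
    return prom


def _instantiate_consensus(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        IUPAC[ch][int(rng.integers(len(IUPAC[ch])))] for ch in consensus.upper()
    )


def simulate_study(
    config: SimConfig, outdir: str | Path
) -> Tuple[Dict[str, object], GroundTruth]:
    """Generate the full miniature study under ``outdir``.

    Returns (objects, ground_truth) where ``objects`` holds the in-memory
    products (genome dict, CTSS tracks per model/sample, peak sets, signal
    and conservation tracks, tissue count matrix, transcripts) and every
    product is also written to disk in the dialects the I/O layer reads.
    Raises before writing anything if promoter placement is infeasible.
    """
    cfg = config
    outdir = Path(outdir)

    rng_place = np.random.default_rng(cfg.seed + 1)
    rng_genome = np.random.default_rng(cfg.seed + 2)
    rng_feat = np.random.default_rng(cfg.seed + 3)
    rng_expr = np.random.default_rng(cfg.seed + 4)
    rng_tissue = np.random.default_rng(cfg.seed + 5)

    prom = _place_promoters(cfg, rng_place)
    prom = _assign_statuses(prom, cfg, rng_place) if len(prom) else prom.assign(
        sox10_status=[], camp_status=[], n_planted_motifs=[],
        has_cpg_island=[], tissue_class=[], dominant_tissue=[],
    )
    outdir.mkdir(parents=True, exist_ok=True)

    # genome -----------------------------------------------------------------
    p_gc = cfg.gc_background
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    genome: Dict[str, np.ndarray] = {}
    for c in range(cfg.n_chroms):
        arr = rng_genome.choice(
            np.frombuffer(b"ACGT", dtype="S1"), size=cfg.chrom_length, p=probs
        ).copy()
        # vertebrate-style background CpG depletion: deaminate most CG
        # dinucleotides so islands stand out only where planted
        cg = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
        hit = cg[rng_genome.random(len(cg)) < cfg.cpg_depletion]
        arr[hit] = np.frombuffer(b"T", dtype="S1")[0]
        genome[f"chr{c + 1}"] = arr

    # peaks, motifs, islands, signal, conservation ---------------------------
    h3_peaks: List[GenomicInterval] = []
    so_peaks: List[GenomicInterval] = []
    motif_rows: List[dict] = []
    signal = {c: np.zeros(cfg.chrom_length) for c in genome}
    cons = {c: np.full(cfg.chrom_length, cfg.conservation_baseline) for c in genome}

    for row in prom.itertuples(index=False):
        chrom, tss, lab = row.chrom, row.tss_pos, row.class_label
        status = row.sox10_status
        h3_center = tss + int(rng_feat.integers(-cfg.peak_jitter, cfg.peak_jitter + 1))
        so_center = h3_center + int(
            rng_feat.integers(-cfg.peak_jitter, cfg.peak_jitter + 1)
        )

        # CpG island sequence centred on the TSS; planted before motifs so a
        # planted motif is never overwritten and stays findable at 0 mismatches
        island_span: Optional[Tuple[int, int]] = None
        if row.has_cpg_island:
            half = cfg.cpg_island_length // 2
            lo = tss - half
            island = np.frombuffer(
                b"CG" * (cfg.cpg_island_length // 2), dtype="S1"
            ).copy()
            # sprinkle in some AT so the island is not a pure repeat
            n_noise = cfg.cpg_island_length // 10
            pos_noise = rng_feat.choice(cfg.cpg_island_length, n_noise, replace=False)
            island[pos_noise] = np.frombuffer(b"A", dtype="S1")[0]
            genome[chrom][lo : lo + cfg.cpg_island_length] = island
            island_span = (lo, lo + cfg.cpg_island_length)

        if lab in ("BOTH", "H3K4ME3_ONLY"):
            h3_peaks.append(
                GenomicInterval(
                    chrom,
                    h3_center - cfg.h3k4me3_width // 2,
                    h3_center + cfg.h3k4me3_width // 2,
                )
            )
        if lab in ("BOTH", "SOX10_ONLY"):
            so_lo = so_center - cfg.sox10_width // 2
            so_hi = so_center + cfg.sox10_width // 2
            so_peaks.append(GenomicInterval(chrom, so_lo, so_hi))

            # plant motifs at non-overlapping offsets inside the SOX10 peak
            m = len(cfg.motif_consensus)
            n_mot = int(row.n_planted_motifs)
            offsets: List[int] = []
            tries = 0
            while len(offsets) < n_mot and tries < 200:
                tries += 1
                off = int(rng_feat.integers(0, cfg.sox10_width - m))
                if any(abs(off - o) < m for o in offsets):
                    continue
                if island_span is not None:
                    g0 = so_lo + off
                    if g0 < island_span[1] and g0 + m > island_span[0]:
                        continue  # keep planted island sequence intact
                offsets.append(off)
            elev = (
                cfg.conservation_elevation_dependent
                if status == "DOWN"
                else cfg.conservation_elevation_other
            )
            for off in sorted(offsets):
                realization = _instantiate_consensus(cfg.motif_consensus, rng_feat)
                strand = "+" if rng_feat.random() < 0.5 else "-"
                planted = (
                    realization if strand == "+" else reverse_complement(realization)
                )
                start = so_lo + off
                genome[chrom][start : start + m] = np.frombuffer(
                    planted.encode(), dtype="S1"
                )
                cons[chrom][start : start + m] = cfg.conservation_baseline + elev
                motif_rows.append(
                    {
                        "promoter_id": row.promoter_id,
                        "chrom": chrom,
                        "start": start,
                        "end": start + m,
                        "strand": strand,
                        "sequence": realization,
                    }
                )

        # ChIP signal bump
        amp = cfg.signal_amplitude.get(
            status if lab == "BOTH" else lab, 0.0
        )
        if amp > 0:
            lo = max(0, tss - 1_000)
            hi = min(cfg.chrom_length, tss + 1_000)
            x = np.arange(lo, hi)
            signal[chrom][lo:hi] += amp * np.exp(
                -0.5 * ((x - tss) / cfg.signal_sd) ** 2
            )

    # planted counts may fall short of the Poisson draw when a peak is
    # crowded by an island; record what was actually planted
    if len(prom):
        planted = (
            pd.DataFrame(motif_rows)["promoter_id"].value_counts()
            if motif_rows
            else pd.Series(dtype=int)
        )
        prom["n_planted_motifs"] = (
            prom["promoter_id"].map(planted).fillna(0).astype(int)
        )

    # CTSS tracks ------------------------------------------------------------
    hw = cfg.ctss_halfwidth
    tri = (hw + 1.0) - np.abs(np.arange(-hw, hw + 1))
    tri /= tri.sum()
    offsets_tri = np.arange(-hw, hw + 1)

    def promoter_mean(row, group: str) -> float:
        lab, status, camp = row.class_label, row.sox10_status, row.camp_status
        if group == "nerve":
            return cfg.nerve_mean[lab]
        if lab != "BOTH":
            # non-candidate promoters: expressed at base level in culture
            base = cfg.nerve_mean[lab]
            return base
        if group in ("parental", "dsox10"):
            if status == "NOT_EXPRESSED":
                return 0.0
            mu = cfg.base_mean
            if group == "dsox10":
                if status == "DOWN":
                    mu *= 2.0 ** (-cfg.lfc)
                elif status == "UP":
                    mu *= 2.0 ** (cfg.lfc)
            return mu
        if group in ("control", "camp"):
            mu = cfg.base_mean
            if group == "camp":
                if camp == "UP":
                    mu *= 2.0 ** (cfg.lfc)
                elif camp == "DOWN":
                    mu *= 2.0 ** (-cfg.lfc)
            return mu
        raise ValueError(group)

    size = 1.0 / cfg.dispersion
    tracks: Dict[str, List[CtssTrack]] = {}
    sample_names: Dict[str, List[str]] = {}
    for model, groups in MODELS.items():
        tracks[model] = []
        sample_names[model] = []
        for ridx, group in enumerate(groups):
            records = []
            for row in prom.itertuples(index=False):
                mu = promoter_mean(row, group)
                if mu <= 0:
                    continue
                p = size / (size + mu)
                total = int(rng_expr.negative_binomial(size, p))
                if total == 0:
                    continue
                alloc = rng_expr.multinomial(total, tri)
                pos = row.tss_pos + offsets_tri
                for pp, cc in zip(pos.tolist(), alloc.tolist()):
                    if cc > 0:
                        records.append((row.chrom, pp, row.strand, int(cc)))
            tracks[model].append(CtssTrack.from_records(records))
            sample_names[model].append(f"{model}_{group}_{ridx}")

    # tissue expression matrix ------------------------------------------------
    tissue_counts = np.zeros((len(prom), len(TISSUES)), dtype=np.int64)
    for i, row in enumerate(prom.itertuples(index=False)):
        mu = np.full(len(TISSUES), cfg.tissue_mean)
        if row.tissue_class == "restricted":
            mu[:] = cfg.tissue_mean / cfg.restricted_fold
            mu[TISSUES.index(row.dominant_tissue)] = cfg.tissue_mean
        p = size / (size + mu)
        tissue_counts[i] = rng_tissue.negative_binomial(size, p)
    tissue_df = pd.DataFrame(
        tissue_counts, index=prom["promoter_id"], columns=TISSUES
    )

    # transcripts: one gene per promoter, span 2 kb downstream ---------------
    transcripts = []
    for row in prom.itertuples(index=False):
        if row.strand == "+":
            span = GenomicInterval(row.chrom, row.tss_pos, row.tss_pos + 2_000, "+")
        else:
            span = GenomicInterval(row.chrom, row.tss_pos - 1_999, row.tss_pos + 1, "-")
        transcripts.append(
            TranscriptModel(
                gene_id=f"gene_{row.promoter_id}",
                transcript_id=f"tx_{row.promoter_id}",
                span=span,
                cds_key=f"cds_{row.promoter_id}",
            )
        )

    # write everything --------------------------------------------------------
    with open(outdir / "genome.fa", "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom].tobytes().decode()
            for k in range(0, len(seq), 80):
                fh.write(seq[k : k + 80] + "\n")

    h3 = PeakSet("H3K4me3", h3_peaks)
    so = PeakSet("SOX10", so_peaks)
    write_peaks(h3, outdir / "h3k4me3_peaks.bed")
    write_peaks(so, outdir / "sox10_peaks.bed")

    signal_track = SignalTrack(signal)
    cons_track = SignalTrack(cons)
    write_bedgraph(signal_track, outdir / "sox10_signal.bedgraph")
    write_bedgraph(cons_track, outdir / "conservation.bedgraph")

    for model in MODELS:
        for name, track in zip(sample_names[model], tracks[model]):
            write_ctss(track, outdir / f"ctss_{name}.tsv")

    write_transcripts(transcripts, outdir / "transcripts.tsv")
    tissue_df.to_csv(outdir / "tissue_counts.tsv", sep="\t")
    cfg.to_yaml(outdir / "sim_config.yaml")

    motifs_df = pd.DataFrame(
        motif_rows,
        columns=["promoter_id", "chrom", "start", "end", "strand", "sequence"],
    )
    truth = GroundTruth(promoters=prom, motifs=motifs_df)
    truth.save(outdir)

    genome_str = {c: genome[c].tobytes().decode() for c in genome}
    objects = {
        "genome": genome_str,
        "tracks": tracks,
        "sample_names": sample_names,
        "h3k4me3": h3,
        "sox10": so,
        "signal": signal_track,
        "conservation": cons_track,
        "tissue_counts": tissue_df,
        "transcripts": transcripts,
    }
    return objects, truth
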