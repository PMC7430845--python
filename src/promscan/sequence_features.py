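"""Sequence-level promoter features: IUPAC motif scanning with mismatch
tolerance (monomeric and dimeric sites), per-motif conservation averages,
CpG-island detection, and GC profiling around TSSs.

The default monomeric consensus shipped here (``WWCAAWG``, one mismatch
allowed) is a family-level HMG-box half-site placeholder; real analyses
should supply the consensus appropriate to the factor under study. Dimeric
sites are two half-sites on opposite strands (inverted orientation) separated
by a short spacer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io_formats import GenomicInterval, PeakSet, SignalTrack

__all__ = [
    "MotifSpec",
    "MotifHit",
    "CpgIsland",
    "DEFAULT_MONOMER",
    "DEFAULT_DIMER",
    "scan_motifs",
    "motifs_per_peak",
    "motif_conservation",
    "cpg_islands",
    "cpg_fraction_by_offset",
    "gc_profile",
    "reverse_complement",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Bases to bit codes; anything not ACGT (incl. N) encodes as 0 and can
    never satisfy an IUPAC class, i.e. genome Ns count as mismatches."""
    arr = np.zeros(len(seq), dtype=np.uint8)
    s = seq.upper()
    for base, bit in _BASE_BIT.items():
        arr[np.frombuffer(s.encode(), dtype=np.uint8) == ord(base)] = bit
    return arr


def _iupac_masks(consensus: str) -> np.ndarray:
    masks = np.zeros(len(consensus), dtype=np.uint8)
    for i, ch in enumerate(consensus.upper()):
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in {consensus!r}")
        masks[i] = sum(_BASE_BIT[b] for b in IUPAC[ch])
    return masks


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC consensus with a mismatch budget; optionally dimeric."""

    name: str
    iupac: str
    max_mismatch: int = 0
    dimer: bool = False
    spacer_min: int = 0
    spacer_max: int = 0

    def __post_init__(self) -> None:
        _iupac_masks(self.iupac)  # validates characters
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.dimer and self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min must be <= spacer_max")


DEFAULT_MONOMER = MotifSpec(name="sox_monomer", iupac="WWCAAWG", max_mismatch=1)
DEFAULT_DIMER = MotifSpec(
    name="sox_dimer",
    iupac="WWCAAWG",
    max_mismatch=1,
    dimer=True,
    spacer_min=3,
    spacer_max=6,
)


@dataclass(frozen=True)
class MotifHit:
    """A motif match; for dimers both half-sites and the spacer length."""

    interval: GenomicInterval
    strand: str
    n_mismatches: int
    motif: str
    half_sites: Optional[Tuple[GenomicInterval, GenomicInterval]] = None
    spacer: Optional[int] = None


def _scan_one_strand(
    bits: np.ndarray, masks: np.ndarray, max_mismatch: int
) -> List[Tuple[int, int]]:
    """(offset, n_mismatches) for matches of the mask on the encoded strand."""
    m = len(masks)
    n_win = len(bits) - m + 1
    if n_win <= 0:
        return []
    mm = np.zeros(n_win, dtype=np.int32)
    for j in range(m):
        mm += (bits[j : j + n_win] & masks[j]) == 0
    idx = np.flatnonzero(mm <= max_mismatch)
    return [(int(i), int(mm[i])) for i in idx]


def _monomer_hits(
    sequence: str, spec: MotifSpec, chrom: str, origin: int
) -> List[MotifHit]:
    bits = _encode(sequence)
    m = len(spec.iupac)
    hits: List[MotifHit] = []
    fwd = _iupac_masks(spec.iupac)
    rev = _iupac_masks(reverse_complement(spec.iupac))
    for strand, masks in (("+", fwd), ("-", rev)):
        for off, mm in _scan_one_strand(bits, masks, spec.max_mismatch):
            hits.append(
                MotifHit(
                    interval=GenomicInterval(chrom, origin + off, origin + off + m, strand),
                    strand=strand,
                    n_mismatches=mm,
                    motif=spec.name,
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def _pair_dimers(
    monomers: List[MotifHit], spec: MotifSpec, chrom: str
) -> List[MotifHit]:
    """Greedy left-to-right pairing of opposite-strand half-sites.

    Each half-site joins at most one dimer; a pair of half-site intervals is
    reported once even when a palindromic consensus yields coincident hits on
    both strands.
    """
    used = [False] * len(monomers)
    seen: set = set()
    dimers: List[MotifHit] = []
    for i, left in enumerate(monomers):
        if used[i]:
            continue
        for j in range(i + 1, len(monomers)):
            right = monomers[j]
            if used[j] or right.strand == left.strand:
                continue
            spacer = right.interval.start - left.interval.end
            if spacer < spec.spacer_min:
                continue
            if spacer > spec.spacer_max:
                break  # monomers sorted by start; no closer partner follows
            key = (left.interval.start, right.interval.start)
            if key in seen:
                continue
            seen.add(key)
            used[i] = used[j] = True
            dimers.append(
                MotifHit(
                    interval=GenomicInterval(
                        chrom, left.interval.start, right.interval.end, "."
                    ),
                    strand=".",
                    n_mismatches=left.n_mismatches + right.n_mismatches,
                    motif=spec.name,
                    half_sites=(left.interval, right.interval),
                    spacer=spacer,
                )
            )
            break
    return dimers


def scan_motifs(
    sequence_regions: Sequence[Tuple[str, int, str]], spec: MotifSpec
) -> List[MotifHit]:
    """Scan regions for a motif spec.

    ``sequence_regions`` is a list of (chrom, origin, sequence): the sequence
    of a region whose first base sits at genome position ``origin``. Monomeric
    specs report every position/strand within the mismatch budget; dimeric
    specs report paired opposite-strand half-sites with an in-bounds spacer.
    """
    out: List[MotifHit] = []
    for chrom, origin, seq in sequence_regions:
        monomers = _monomer_hits(seq, spec, chrom, origin)
        if spec.dimer:
            out.extend(_pair_dimers(monomers, spec, chrom))
        else:
            out.extend(monomers)
    return out


def motifs_per_peak(
    peaks: PeakSet, genome: Mapping[str, str], spec: MotifSpec
) -> np.ndarray:
    """Number of motif hits falling fully inside each peak (in peak order)."""
    counts = np.zeros(len(peaks.intervals), dtype=np.int64)
    for i, iv in enumerate(peaks.intervals):
        seq = str(genome[iv.chrom])[iv.start : iv.end]
        hits = scan_motifs([(iv.chrom, iv.start, seq)], spec)
        counts[i] = sum(
            1
            for h in hits
            if h.interval.start >= iv.start and h.interval.end <= iv.end
        )
    return counts


def motif_conservation(hits: Sequence[MotifHit], cons: SignalTrack) -> np.ndarray:
    """Mean per-base conservation per hit; for dimers the two half-sites only
    (the spacer is excluded). Bases without coverage contribute 0."""
    out = np.empty(len(hits))
    for i, h in enumerate(hits):
        if h.half_sites is not None:
            vals = np.concatenate(
                [cons.values_over(h.half_sites[0]), cons.values_over(h.half_sites[1])]
            )
        else:
            vals = cons.values_over(h.interval)
        out[i] = float(vals.mean())
    return out


# ---------------------------------------------------------------------------
# CpG islands


@dataclass(frozen=True)
class CpgIsland:
    interval: GenomicInterval
    gc_fraction: float
    obs_exp_ratio: float


def _island_stats(seq: str) -> Tuple[float, float]:
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cg = seq.count("CG")
    gc = (n_c + n_g) / len(seq)
    oe = (n_cg * len(seq)) / (n_c * n_g) if n_c * n_g > 0 else 0.0
    return gc, oe


def cpg_islands(
    region_sequence: str,
    window: int = 100,
    min_length: int = 200,
    gc_threshold: float = 0.5,
    oe_threshold: float = 0.6,
    chrom: str = "region",
    origin: int = 0,
) -> List[CpgIsland]:
    """Sliding-window CpG island detection.

    Every ``window``-bp window (step 1) is scored for GC fraction and for the
    CpG observed/expected ratio ``(#CG * window) / (#C * #G)`` (0 when a
    window has no C or no G). Windows passing both thresholds are merged by
    span union, and merged runs of at least ``min_length`` bp are reported
    with the statistics of the merged sequence. Coordinates are offset by
    ``origin`` on chromosome ``chrom``.
    """
    seq = region_sequence.upper()
    n = len(seq)
    if n < window:
        raise ValueError(f"sequence shorter ({n}) than window ({window})")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int32)
    is_g = (arr == ord("G")).astype(np.int32)
    is_cg = np.zeros(n, dtype=np.int32)
    if n > 1:
        is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))

    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    starts = np.arange(n - window + 1)
    c = cum_c[starts + window] - cum_c[starts]
    g = cum_g[starts + window] - cum_g[starts]
    # CG dinucleotides fully inside the window (start positions within it)
    cg = cum_cg[starts + window - 1] - cum_cg[starts]
    gc_frac = (c + g) / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(c * g > 0, cg * window / np.maximum(c * g, 1), 0.0)
    passing = (gc_frac >= gc_threshold) & (oe >= oe_threshold)

    islands: List[CpgIsland] = []
    idx = np.flatnonzero(passing)
    if len(idx) == 0:
        return islands
    # merge overlapping/adjacent window spans [i, i+window)
    run_start = int(idx[0])
    run_end = int(idx[0]) + window
    for i in idx[1:].tolist():
        if i <= run_end:  # window at i overlaps/abuts the current run
            run_end = i + window
        else:
            if run_end - run_start >= min_length:
                gc_i, oe_i = _island_stats(seq[run_start:run_end])
                islands.append(
                    CpgIsland(
                        GenomicInterval(chrom, origin + run_start, origin + run_end),
                        gc_i,
                        oe_i,
                    )
                )
            run_start, run_end = i, i + window
    if run_end - run_start >= min_length:
        gc_i, oe_i = _island_stats(seq[run_start:run_end])
        islands.append(
            CpgIsland(
                GenomicInterval(chrom, origin + run_start, origin + run_end),
                gc_i,
                oe_i,
            )
        )
    return islands


def cpg_fraction_by_offset(
    records_by_class: Mapping[str, Sequence["TssRecord"]],
    islands: Sequence[CpgIsland],
    window: int = 1000,
    bin_size: int = 100,
) -> "pd.DataFrame":
    """Fraction of TSSs whose window carries island sequence, per offset bin.

    Offsets are strand-oriented; an island contributes to a bin when at least
    one island base overlaps the bin's genomic span. Also reports, per class,
    the fraction of TSSs with an island covering the anchor itself
    (``anchor_fraction``).
    """
    import pandas as pd

    from .promoter_classification import TssRecord  # noqa: F401 (typing)

    by_chrom: Dict[str, List[CpgIsland]] = {}
    for isl in islands:
        by_chrom.setdefault(isl.interval.chrom, []).append(isl)

    n_bins = 2 * window // bin_size
    rows = []
    for label, records in records_by_class.items():
        if not records:
            continue
        hitmat = np.zeros((len(records), n_bins), dtype=bool)
        anchor_hit = np.zeros(len(records), dtype=bool)
        for i, rec in enumerate(records):
            chrom = rec.cluster.interval.chrom
            a = rec.anchor
            for isl in by_chrom.get(chrom, []):
                s, e = isl.interval.start, isl.interval.end
                if e <= a - window or s >= a + window:
                    continue
                if s <= a < e:
                    anchor_hit[i] = True
                # genomic offsets overlapped by the island, clipped to window
                lo = max(s, a - window) - a
                hi = min(e, a + window) - a
                if rec.strand == "-":
                    lo, hi = -hi, -lo
                b_lo = (lo + window) // bin_size
                b_hi = (hi - 1 + window) // bin_size
                hitmat[i, b_lo : b_hi + 1] = True
        frac = hitmat.mean(axis=0)
        for b in range(n_bins):
            rows.append(
                {
                    "class": label,
                    "offset_start": b * bin_size - window,
                    "offset_end": (b + 1) * bin_size - window,
                    "fraction_with_island": float(frac[b]),
                    "anchor_fraction": float(anchor_hit.mean()),
                    "n_regions": len(records),
                }
            )
    return pd.DataFrame(rows)


def gc_profile(
    records_by_class: Mapping[str, Sequence["TssRecord"]],
    genome: Mapping[str, str],
    window: int = 1000,
    bin_size: int = 10,
) -> "pd.DataFrame":
    """Strand-oriented mean GC fraction per offset bin per class."""
    import pandas as pd

    n_bins = 2 * window // bin_size
    rows = []
    for label, records in records_by_class.items():
        if not records:
            continue
        acc = np.zeros((len(records), n_bins))
        for i, rec in enumerate(records):
            chrom = rec.cluster.interval.chrom
            seq = str(genome[chrom]).upper()
            a = rec.anchor
            sub = seq[max(0, a - window) : a + window]
            # pad windows truncated at chromosome edges so offsets stay aligned
            pad_left = window - (a - max(0, a - window))
            full = "N" * pad_left + sub
            full = full + "N" * (2 * window - len(full))
            if rec.strand == "-":
                full = full[::-1]
            arr = np.frombuffer(full.encode(), dtype=np.uint8)
            gc = ((arr == ord("G")) | (arr == ord("C"))).astype(float)
            acc[i] = gc.reshape(n_bins, bin_size).mean(axis=1)
        mean_gc = acc.mean(axis=0)
        for b in range(n_bins):
            rows.append(
                {
                    "class": label,
                    "offset_start": b * bin_size - window,
                    "offset_end": (b + 1) * bin_size - window,
                    "mean_gc": float(mean_gc[b]),
                    "n_regions": len(records),
                }
            )
    return pd.DataFrame(rows)
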