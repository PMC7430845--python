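import numpy as np
import pytest

from promscan.io_formats import GenomicInterval, PeakSet, SignalTrack
from promscan.sequence_features import (
    DEFAULT_MONOMER,
    IUPAC,
    MotifHit,
    MotifSpec,
    cpg_islands,
    gc_profile,
    motif_conservation,
    motifs_per_peak,
    reverse_complement,
    scan_motifs,
)

from conftest import make_record


def brute_force_scan(sequence, consensus, max_mismatch):
    """Position-by-position rescan, fully independent of the vector path."""
    hits = set()
    seq = sequence.upper()
    for strand, motif in (("+", consensus), ("-", reverse_complement(consensus))):
        m = len(motif)
        for i in range(len(seq) - m + 1):
            mm = sum(
                1
                for a, b in zip(seq[i : i + m], motif)
                if a not in IUPAC.get(b, "")
            )
            if mm <= max_mismatch:
                hits.add((i, strand, mm))
    return hits


class TestScanMotifs:
    def test_exact_planted_site_found_once(self):
        seq = "T" * 50 + "AACAATG" + "T" * 50
        spec = MotifSpec("m", "AACAATG", 0)
        hits = scan_motifs([("chr1", 100, seq)], spec)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert plus[0].interval.start == 150
        assert plus[0].n_mismatches == 0

    def test_two_substitutions_exceed_budget(self):
        seq = "G" * 30 + "AACGGTG" + "G" * 30  # AACAATG with 2 substitutions
        spec = MotifSpec("m", "AACAATG", 1)
        hits = scan_motifs([("chr1", 0, seq)], spec)
        assert all(h.interval.start != 30 for h in hits)

    def test_all_n_region_yields_no_hits(self):
        hits = scan_motifs([("chr1", 0, "N" * 200)], DEFAULT_MONOMER)
        assert hits == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_rescanner(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        spec = MotifSpec("m", "WWCAAWG", 1)
        hits = scan_motifs([("chr1", 0, seq)], spec)
        got = {(h.interval.start, h.strand, h.n_mismatches) for h in hits}
        assert got == brute_force_scan(seq, spec.iupac, spec.max_mismatch)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), 1500))
        spec = MotifSpec("m", "WWCAAWG", 1)
        fwd = scan_motifs([("chr1", 0, seq)], spec)
        rev = scan_motifs([("chr1", 0, reverse_complement(seq))], spec)
        L, m = len(seq), len(spec.iupac)
        flip = {"+": "-", "-": "+"}
        mirrored = {
            (L - h.interval.end, flip[h.strand], h.n_mismatches) for h in fwd
        }
        got = {(h.interval.start, h.strand, h.n_mismatches) for h in rev}
        assert got == mirrored

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            MotifSpec("bad", "ACGX", 0)


class TestDimericSites:
    def test_inverted_pair_with_in_bounds_spacer(self):
        mono = "AACAATG"
        spacer = "GGGG"  # 4 bp, within [3, 6]
        seq = "T" * 20 + mono + spacer + reverse_complement(mono) + "T" * 20
        spec = MotifSpec("d", mono, 0, dimer=True, spacer_min=3, spacer_max=6)
        hits = scan_motifs([("chr1", 0, seq)], spec)
        assert len(hits) == 1
        h = hits[0]
        assert h.spacer == 4
        assert h.half_sites[0].end + 4 == h.half_sites[1].start
        assert {h.half_sites[0].strand, h.half_sites[1].strand} == {"+", "-"}

    def test_out_of_bounds_spacer_rejected(self):
        mono = "AACAATG"
        seq = "T" * 20 + mono + "G" * 10 + reverse_complement(mono) + "T" * 20
        spec = MotifSpec("d", mono, 0, dimer=True, spacer_min=3, spacer_max=6)
        assert scan_motifs([("chr1", 0, seq)], spec) == []

    def test_half_site_used_at_most_once(self):
        mono = "AACAATG"
        rc = reverse_complement(mono)
        seq = "T" * 10 + mono + "GGGG" + rc + "GGGG" + rc + "T" * 10
        spec = MotifSpec("d", mono, 0, dimer=True, spacer_min=3, spacer_max=6)
        hits = scan_motifs([("chr1", 0, seq)], spec)
        assert len(hits) == 1  # middle half-site pairs once, not twice


class TestMotifsPerPeak:
    def test_no_motifs_in_hostile_sequence(self):
        genome = {"chr1": "G" * 1000}
        peaks = PeakSet("p", [GenomicInterval("chr1", 100, 500)])
        spec = MotifSpec("m", "AAAAAAA", 0)
        assert motifs_per_peak(peaks, genome, spec).tolist() == [0]

    def test_three_planted_sites_counted(self):
        mono = "AACAATG"
        block = "G" * 30
        seq = "G" * 100 + mono + block + mono + block + mono + "G" * 100
        genome = {"chr1": seq}
        peaks = PeakSet("p", [GenomicInterval("chr1", 50, len(seq) - 50)])
        spec = MotifSpec("m", mono, 0)
        assert motifs_per_peak(peaks, genome, spec).tolist() == [3]


class TestMotifConservation:
    def test_constant_track_returns_constant(self):
        cons = SignalTrack({"chr1": np.full(100, 0.8)})
        hit = MotifHit(GenomicInterval("chr1", 10, 17, "+"), "+", 0, "m")
        assert motif_conservation([hit], cons)[0] == pytest.approx(0.8)

    def test_half_one_half_zero_averages_half(self):
        arr = np.zeros(100)
        arr[10:13] = 1.0
        cons = SignalTrack({"chr1": arr})
        hit = MotifHit(GenomicInterval("chr1", 10, 16, "+"), "+", 0, "m")
        assert motif_conservation([hit], cons)[0] == pytest.approx(0.5)

    def test_dimer_average_excludes_spacer(self):
        arr = np.zeros(100)
        arr[10:17] = 1.0  # left half-site fully conserved
        arr[17:21] = 9.0  # spacer: high values that must not contribute
        cons = SignalTrack({"chr1": arr})
        left = GenomicInterval("chr1", 10, 17, "+")
        right = GenomicInterval("chr1", 21, 28, "-")
        hit = MotifHit(
            GenomicInterval("chr1", 10, 28, "."), ".", 0, "d",
            half_sites=(left, right), spacer=4,
        )
        assert motif_conservation([hit], cons)[0] == pytest.approx(0.5)

    def test_linear_in_track_scale(self):
        rng = np.random.default_rng(3)
        cons = SignalTrack({"chr1": rng.random(500)})
        hits = [
            MotifHit(GenomicInterval("chr1", s, s + 7, "+"), "+", 0, "m")
            for s in (5, 50, 200)
        ]
        base = motif_conservation(hits, cons)
        scaled = motif_conservation(hits, cons.scaled(3.0))
        assert np.allclose(scaled, 3.0 * base)


class TestCpgIslands:
    def test_at_repeat_has_no_islands(self):
        assert cpg_islands("AT" * 500) == []

    def test_cg_repeat_is_one_island_with_expected_stats(self):
        islands = cpg_islands("CG" * 200)
        assert len(islands) == 1
        isl = islands[0]
        assert isl.interval.start == 0
        assert isl.interval.end == 400
        assert isl.gc_fraction == pytest.approx(1.0)
        assert isl.obs_exp_ratio == pytest.approx(2.0, rel=0.01)

    def test_short_island_rejected_by_min_length(self):
        # 60 bp CG core at [400, 460): windows starting in [350, 410] carry
        # >= 50 core bases and pass; their union spans [350, 510), 160 bp
        seq = "AT" * 200 + "CG" * 30 + "AT" * 200
        assert cpg_islands(seq, min_length=200) == []
        islands = cpg_islands(seq, min_length=150)
        assert len(islands) == 1
        assert len(islands[0].interval) == 160

    def test_flanking_padding_shifts_island_cores(self):
        # island-negative padding relocates the island; the core is preserved
        # and boundary windows can extend it by less than one window width
        core = "CG" * 150
        pad = "AT" * 300
        plain = cpg_islands(core)
        padded = cpg_islands(pad + core + pad)
        assert len(plain) == len(padded) == 1
        shift = len(pad)
        assert padded[0].interval.start <= plain[0].interval.start + shift
        assert padded[0].interval.end >= plain[0].interval.end + shift
        assert plain[0].interval.start + shift - padded[0].interval.start < 100
        assert padded[0].interval.end - (plain[0].interval.end + shift) < 100

    def test_sequence_shorter_than_window_is_error(self):
        with pytest.raises(ValueError, match="shorter"):
            cpg_islands("ACGT", window=100)


class TestGcProfile:
    def test_uniform_genome_flat_at_half(self):
        genome = {"chr1": "ACGT" * 2500}
        recs = [make_record("chr1", 3000 + i * 100) for i in range(5)]
        out = gc_profile({"x": recs}, genome, window=500, bin_size=10)
        assert np.allclose(out["mean_gc"], 0.5)

    def test_single_record_profile_equals_its_own_gc(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        genome = {"chr1": seq}
        rec = make_record("chr1", 5000)
        out = gc_profile({"x": [rec]}, genome, window=100, bin_size=10)
        first_bin = seq[4900:4910]
        expected = sum(c in "GC" for c in first_bin) / 10
        assert out.iloc[0]["mean_gc"] == pytest.approx(expected)

    def test_classes_with_different_gc_separate(self):
        rng = np.random.default_rng(12)
        low = "".join(rng.choice(list("ACGT"), 50_000, p=[0.3, 0.2, 0.2, 0.3]))
        high = "".join(rng.choice(list("ACGT"), 50_000, p=[0.2, 0.3, 0.3, 0.2]))
        genome = {"lo": low, "hi": high}
        recs_lo = [make_record("lo", 2000 + 2100 * i) for i in range(20)]
        recs_hi = [make_record("hi", 2000 + 2100 * i) for i in range(20)]
        out = gc_profile({"lo": recs_lo, "hi": recs_hi}, genome, window=1000)
        mean_lo = out[out["class"] == "lo"]["mean_gc"].mean()
        mean_hi = out[out["class"] == "hi"]["mean_gc"].mean()
        assert mean_hi - mean_lo == pytest.approx(0.2, abs=0.03)
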