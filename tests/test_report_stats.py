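import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from promscan.io_formats import GenomicInterval, TranscriptModel
from promscan.report_stats import (
    crosstab_percentages,
    ecdf_table,
    isoform_diversity,
    mann_whitney_u,
    round_half_up,
    zscore_matrix,
)
from promscan.synthetic_data import simulate_transcript_annotation


class TestRoundHalfUp:
    @pytest.mark.parametrize(
        "value,decimals,expected",
        [(0.125, 2, 0.13), (0.135, 2, 0.14), (12.55, 1, 12.6), (94.085, 2, 94.09)],
    )
    def test_half_rounds_away_from_zero(self, value, decimals, expected):
        assert round_half_up(value, decimals) == expected


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3])[1] == 1.0
        assert mann_whitney_u([5, 5], [5, 5, 5])[1] == 1.0

    def test_most_extreme_small_split(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2.0 / 6.0)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        assert mann_whitney_u(a, b)[1] < 1e-10

    def test_exact_mode_agrees_with_full_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 6))
            pooled = rng.integers(0, 6, n_a + n_b).astype(float)  # ties likely
            a, b = pooled[:n_a], pooled[n_a:]
            _, p = mann_whitney_u(a, b)
            # independent enumeration using scipy's U statistic per labelling
            ranks = stats.rankdata(pooled)
            mean_u = n_a * n_b / 2
            obs = abs(ranks[:n_a].sum() - n_a * (n_a + 1) / 2 - mean_u)
            count = total = 0
            for combo in itertools.combinations(range(n_a + n_b), n_a):
                u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
                total += 1
                count += abs(u - mean_u) >= obs - 1e-9
            assert p == pytest.approx(count / total)

    def test_tie_free_exact_matches_scipy(self):
        rng = np.random.default_rng(2)
        a = rng.permutation(100)[:5].astype(float)
        b = (rng.permutation(100)[:6] + 200).astype(float)
        _, p = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestEcdf:
    def test_single_value_steps_to_one(self):
        out = ecdf_table({"x": [1, 1, 1]}, log10_transform=False)
        assert out["cumulative_fraction"].tolist() == [1 / 3, 2 / 3, 1.0]
        assert (out["value"] == 1.0).all()

    def test_quarter_steps(self):
        out = ecdf_table({"x": [1, 2, 3, 4]}, log10_transform=False)
        assert out["cumulative_fraction"].tolist() == [0.25, 0.5, 0.75, 1.0]

    def test_zeros_excluded_and_counted_under_log(self):
        out = ecdf_table({"x": [0.0, 0.0, 10.0, 100.0]})
        assert len(out) == 2
        assert (out["n_zero_excluded"] == 2).all()
        assert out["value"].tolist() == [1.0, 2.0]

    def test_ends_at_one_for_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            vals = rng.random(int(rng.integers(1, 50))) * 100
            out = ecdf_table({"c": vals}, log10_transform=False)
            assert out["cumulative_fraction"].iloc[-1] == 1.0
            assert out["cumulative_fraction"].is_monotonic_increasing

    def test_empty_class_omitted(self):
        out = ecdf_table({"empty": [], "full": [1.0]}, log10_transform=False)
        assert set(out["class"]) == {"full"}


class TestZscores:
    def test_closed_form_row(self):
        out = zscore_matrix(np.array([[1.0, 2.0, 3.0]]), row_ids=["r"])
        vals = out[[0, 1, 2]].to_numpy()[0]
        assert vals == pytest.approx([-1.224744871, 0.0, 1.224744871])

    def test_constant_row_is_flagged_zeros(self):
        out = zscore_matrix(np.array([[5.0, 5.0, 5.0]]))
        assert out[[0, 1, 2]].to_numpy().tolist() == [[0.0, 0.0, 0.0]]
        assert out["constant"].iloc[0]

    def test_unscaling_recovers_input(self):
        rng = np.random.default_rng(4)
        x = rng.random((20, 6)) * 50
        z = zscore_matrix(x)[[*range(6)]].to_numpy()
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        assert np.allclose(z * sd + mean, x)


class TestCrosstabPercentages:
    def test_printed_fraction_reproduced(self):
        out = crosstab_percentages({"both": (4993, 39_706)}, decimals=1)
        assert out["percent"].iloc[0] == 12.6

    def test_two_decimal_mapping_rate(self):
        out = crosstab_percentages({"m": (4698, 4993)}, decimals=2)
        assert out["percent"].iloc[0] == 94.09

    def test_zero_numerator(self):
        out = crosstab_percentages({"none": (0, 10)})
        assert out["percent"].iloc[0] == 0.0

    def test_numerator_above_denominator_rejected(self):
        with pytest.raises(ValueError):
            crosstab_percentages({"bad": (11, 10)})

    def test_partition_percentages_sum_to_about_100(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = int(rng.integers(2, 8))
            sizes = rng.integers(1, 1000, k)
            total = int(sizes.sum())
            table = crosstab_percentages(
                {f"c{i}": (int(n), total) for i, n in enumerate(sizes)}, decimals=1
            )
            assert table["percent"].sum() == pytest.approx(100.0, abs=0.1 * k)


def tmodel(gene, tss, strand="+", cds="", tid=None):
    if strand == "+":
        span = GenomicInterval("chr1", tss, tss + 1000, "+")
    else:
        span = GenomicInterval("chr1", tss - 999, tss + 1, "-")
    return TranscriptModel(gene, tid or f"{gene}.{tss}.{cds}", span, cds)


class TestIsoformDiversity:
    def test_same_tss_different_cds(self):
        ts = [tmodel("g", 100, cds="c1"), tmodel("g", 100, cds="c2", tid="x")]
        (d,) = isoform_diversity(ts)
        assert not d.multi_tss
        assert d.multi_cds
        assert d.n_distinct_cds == 2

    def test_duplicate_tss_counted_once(self):
        ts = [tmodel("g", 100), tmodel("g", 100, tid="b"), tmodel("g", 5000)]
        (d,) = isoform_diversity(ts)
        assert d.n_distinct_tss == 2

    def test_merge_distance_collapses_nearby_starts(self):
        ts = [tmodel("g", 100), tmodel("g", 130, tid="b"), tmodel("g", 5000)]
        assert isoform_diversity(ts, tss_merge_distance=0)[0].n_distinct_tss == 3
        assert isoform_diversity(ts, tss_merge_distance=50)[0].n_distinct_tss == 2

    def test_noncoding_transcripts_ignored_for_cds(self):
        ts = [tmodel("g", 100, cds=""), tmodel("g", 900, cds="c1", tid="b")]
        (d,) = isoform_diversity(ts)
        assert d.n_distinct_cds == 1
        assert not d.multi_cds

    def test_planted_multi_tss_fraction_recovered(self):
        n = 400
        ts = simulate_transcript_annotation(n, multi_tss_fraction=0.3, seed=6)
        out = isoform_diversity(ts)
        frac = sum(d.multi_tss for d in out) / n
        assert frac == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / n))
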