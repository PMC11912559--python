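import numpy as np
import pandas as pd
import pytest

from tandemkit.catalog import StrLocus
from tandemkit.comparative import (
    CohortStats,
    distribution_overlap,
    find_common_loci,
    msi_locus_filter,
    msi_summary,
    relative_allele_size,
    relative_allele_sizes,
    score_locus,
)
from tandemkit.genotyping import AlleleHistogram


def _table(locus_ids):
    return pd.DataFrame({"locus_id": locus_ids})


class TestFindCommonLoci:
    def test_intersection(self):
        assert find_common_loci(_table(["L1", "L2", "L3"]), _table(["L2", "L3", "L4"])) == ["L2", "L3"]

    def test_disjoint(self):
        assert find_common_loci(_table(["L1"]), _table(["L2"])) == []

    def test_identical(self):
        assert find_common_loci(_table(["L1", "L2"]), _table(["L1", "L2"])) == ["L1", "L2"]


class TestScoreLocus:
    def test_identical_histograms_score_zero(self):
        h = AlleleHistogram({10: 4, 9: 1})
        assert score_locus(h, h).score == 0.0

    def test_score_is_distance_times_normal_prominence(self):
        hn = AlleleHistogram({10: 30})
        ht = AlleleHistogram({8: 30})
        cmp_ = score_locus(hn, ht)
        assert cmp_.distance == pytest.approx(2.0)
        assert cmp_.prominence_n == pytest.approx(30.0)
        assert cmp_.score == pytest.approx(60.0)

    def test_asymmetric_in_prominence(self):
        hn = AlleleHistogram({10: 30})
        ht = AlleleHistogram({8: 5})
        assert score_locus(hn, ht).score != score_locus(ht, hn).score


class TestRelativeAlleleSize:
    @pytest.mark.parametrize(
        "counts,ref,expected",
        [({10: 1}, 10, 0.0), ({9: 1}, 10, -1.0), ({9: 1, 10: 1}, 10, -0.5)],
    )
    def test_examples(self, counts, ref, expected):
        assert relative_allele_size(AlleleHistogram(counts), ref) == pytest.approx(expected)

    def test_linear_under_mixing(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c1 = {int(a): int(c) for a, c in zip(rng.integers(5, 15, 3), rng.integers(1, 20, 3))}
            c2 = {int(a): int(c) for a, c in zip(rng.integers(5, 15, 3), rng.integers(1, 20, 3))}
            w = float(rng.random())
            mixed = {}
            for a, c in c1.items():
                mixed[a] = mixed.get(a, 0) + w * c / sum(c1.values())
            for a, c in c2.items():
                mixed[a] = mixed.get(a, 0) + (1 - w) * c / sum(c2.values())
            r1 = relative_allele_size(AlleleHistogram(c1), 10)
            r2 = relative_allele_size(AlleleHistogram(c2), 10)
            rm = relative_allele_size(AlleleHistogram(mixed), 10)
            assert rm == pytest.approx(w * r1 + (1 - w) * r2)


def _locus(lid, count=12, left="TCTAGCTAGCTC", right="TCGATCGATCGA", unit="A"):
    return StrLocus(
        locus_id=lid,
        chrom="c",
        start=1000,
        end=1000 + count * len(unit),
        unit=unit,
        ref_repeat_count=count,
        left_flank=left,
        right_flank=right,
        flank_window=12,
    )


def _locus_table(rows):
    return pd.DataFrame(
        rows,
        columns=["locus_id", "coverage_used", "peak_prominence"],
    )


class TestMsiLocusFilter:
    """Each selection rule removes exactly its constructed offender."""

    def _catalog(self):
        return [
            _locus("ok"),
            _locus("gadj", right="GTCATCGATCGA"),
            _locus("lowcov"),
            _locus("short", count=9),
            _locus("long", count=15),
            _locus("notA", unit="C"),
            _locus("cohort"),
        ]

    def _sample(self):
        return _locus_table(
            [
                ("ok", 35, 30.0),
                ("gadj", 35, 30.0),
                ("lowcov", 29, 30.0),
                ("short", 35, 30.0),
                ("long", 35, 30.0),
                ("notA", 35, 30.0),
                ("cohort", 35, 30.0),
            ]
        )

    def test_each_rule_removes_its_offender(self):
        cohort = [
            _table(["ok", "gadj", "lowcov", "short", "long", "notA"]),
            _table(["ok", "gadj", "lowcov", "short", "long", "notA"]),
            _table(["ok", "gadj", "lowcov", "short", "long", "notA", "cohort"]),
            _table(["cohort"]),
        ]
        kept = msi_locus_filter(
            self._sample(),
            self._catalog(),
            cohort=cohort,
            min_coverage=30,
            min_samples_covered=3,
            exclude_g_adjacent=True,
            prominence_band=False,
        )
        # guanine-adjacent, under-covered, out-of-range, non-A, and
        # cohort-undersupported loci all gone; only "ok" survives
        assert kept == ["ok"]

    def test_g_adjacent_left_side_also_excluded(self):
        catalog = [_locus("lg", left="TCTAGCTAGCTG")]
        kept = msi_locus_filter(
            _locus_table([("lg", 35, 30.0)]), catalog, prominence_band=False
        )
        assert kept == []

    def test_prominence_band_removes_mid_prominence_locus(self):
        # prominences 10, 20, 30: mu=20, sigma=sqrt(200/3)~8.16,
        # band [15.92, 24.08] contains exactly the 20
        catalog = [_locus(l) for l in ("p10", "p20", "p30")]
        table = _locus_table([("p10", 35, 10.0), ("p20", 35, 20.0), ("p30", 35, 30.0)])
        kept = msi_locus_filter(table, catalog, prominence_band=True)
        assert kept == ["p10", "p30"]
        inverted = msi_locus_filter(table, catalog, prominence_band=True, invert_band=True)
        assert inverted == ["p20"]


class TestCohortStats:
    def test_mean_and_sd(self):
        stats = CohortStats.from_prominences([10.0, 20.0, 30.0])
        assert stats.mu == pytest.approx(20.0)
        assert stats.sigma == pytest.approx(np.sqrt(200 / 3))


def _allele_table(per_locus_alleles):
    rows = []
    for lid, alleles in per_locus_alleles.items():
        for i, a in enumerate(alleles):
            rows.append((lid, f"{lid}r{i}", "forward", a, 0, a, "A"))
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "read_id",
            "strand",
            "corrected_allele",
            "edit_distance",
            "observed_length_nt",
            "sequenced_unit",
        ],
    )


class TestMsiSummary:
    def _setup(self, shift=0):
        catalog = [_locus(f"L{i}", count=12) for i in range(4)]
        alleles = {f"L{i}": [12 + shift] * 32 for i in range(4)}
        locus_table = _locus_table([(f"L{i}", 32, 32.0) for i in range(4)])
        return catalog, _allele_table(alleles), locus_table

    def test_stable_sample_mean_zero(self):
        catalog, at, lt = self._setup(0)
        per_locus, per_sample, overlap = msi_summary(
            {"mss": (at, lt)}, catalog, prominence_band=False, exclude_g_adjacent=False
        )
        assert per_sample["mean"].iloc[0] == pytest.approx(0.0)

    def test_unstable_sample_mean_minus_one(self):
        catalog, at, lt = self._setup(-1)
        _, per_sample, _ = msi_summary(
            {"msi": (at, lt)}, catalog, prominence_band=False, exclude_g_adjacent=False
        )
        assert per_sample["mean"].iloc[0] == pytest.approx(-1.0)

    def test_identical_samples_overlap_one(self):
        catalog, at, lt = self._setup(0)
        _, _, overlap = msi_summary(
            {"a": (at, lt), "b": (at.copy(), lt.copy())},
            catalog,
            prominence_band=False,
            exclude_g_adjacent=False,
        )
        assert overlap.loc["a", "b"] == pytest.approx(1.0)

    def test_no_surviving_loci_signals(self):
        catalog, at, lt = self._setup(0)
        with pytest.raises(ValueError):
            msi_summary(
                {"s": (at, lt)}, catalog, min_coverage=1000, prominence_band=False
            )


class TestDistributionOverlap:
    def test_disjoint_distributions(self):
        assert distribution_overlap([0.0] * 10, [-2.0] * 10) == pytest.approx(0.0)

    def test_partial_overlap(self):
        a = [0.0] * 5 + [-1.0] * 5
        b = [0.0] * 10
        assert distribution_overlap(a, b) == pytest.approx(0.5)
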