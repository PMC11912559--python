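import random

import pytest
from hypothesis import given, settings, strategies as st

from tandemkit.catalog import (
    DEFAULT_MIN_LENGTHS,
    StrLocus,
    build_catalog,
    catalog_from_frame,
    catalog_to_frame,
    count_kmers,
    effective_kmer_count,
    filter_catalog,
    find_perfect_repeats,
    kmer_diversity,
    select_low_complexity_subset,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


def _is_primitive(unit):
    return all(
        not (len(unit) % p == 0 and unit == unit[: p] * (len(unit) // p))
        for p in range(1, len(unit))
    )


def exhaustive_repeats(seq, p, min_len):
    """Independent oracle: test every start for a maximal perfect run of
    period p, then resolve overlaps greedily left-to-right."""
    runs = []
    n = len(seq)
    for a in range(n - 2 * p + 1):
        unit = seq[a : a + p]
        if not set(unit) <= set("ACGT") or not _is_primitive(unit):
            continue
        count = 1
        while seq[a + count * p : a + (count + 1) * p] == unit:
            count += 1
        if count < 2 or count * p < min_len:
            continue
        # maximal: not left-extendable by periodicity
        if a > 0 and seq[a - 1] == seq[a - 1 + p] and seq[a - 1] in "ACGT":
            continue
        runs.append((a, a + count * p, unit, count))
    kept, last_end = [], 0
    for run in sorted(runs):
        if run[0] >= last_end:
            kept.append(run)
            last_end = run[1]
    return kept


class TestFindPerfectRepeats:
    @pytest.mark.parametrize(
        "seq,unit_size,min_len,expected",
        [
            ("CC" + "A" * 10 + "GG", 1, 10, [(2, 12, "A", 10)]),
            ("G" + "AT" * 7 + "C", 2, 12, [(1, 15, "AT", 7)]),
            ("A" * 9, 1, 10, []),
            ("", 1, 10, []),
            ("A" * 5 + "N" + "A" * 5, 1, 10, []),  # non-ACGT splits the run
        ],
    )
    def test_examples(self, seq, unit_size, min_len, expected):
        loci = find_perfect_repeats(seq, unit_size, min_len)
        got = [(l.start, l.end, l.unit, l.ref_repeat_count) for l in loci]
        assert got == expected

    def test_nonprimitive_unit_not_reported(self):
        # A*12 must not appear as an "AA" dinucleotide repeat
        assert find_perfect_repeats("C" + "A" * 12 + "C", 2, 4) == []

    @pytest.mark.parametrize("unit_size", [1, 2, 3])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle(self, unit_size, seed):
        rng = random.Random(seed)
        # biased alphabet so that repeats actually occur
        seq = "".join(rng.choice("AACGT") for _ in range(2000))
        min_len = DEFAULT_MIN_LENGTHS[unit_size]
        got = [
            (l.start, l.end, l.unit, l.ref_repeat_count)
            for l in find_perfect_repeats(seq, unit_size, min_len)
        ]
        assert got == exhaustive_repeats(seq, unit_size, min_len)

    @given(seq=dna)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_loci_never_overlap_and_roundtrip(self, seq):
        loci = find_perfect_repeats(seq, 2, 6)
        prev_end = 0
        for l in loci:
            assert l.start >= prev_end
            assert seq[l.start : l.end] == l.unit * l.ref_repeat_count
            prev_end = l.end


class TestKmers:
    def test_worked_dinucleotide_counts(self):
        assert count_kmers("ATCGC", 2) == {"AT": 1, "TC": 1, "CG": 1, "GC": 1}

    @pytest.mark.parametrize(
        "seq,k,expected",
        [("AAAA", 2, {"AA": 3}), ("ACGT", 4, {"ACGT": 1}), ("AC", 3, {})],
    )
    def test_counts(self, seq, k, expected):
        assert count_kmers(seq, k) == expected

    @pytest.mark.parametrize(
        "seq,k,expected",
        [("ATCGC", 2, 1.0), ("AAAAA", 2, 0.25), ("AAAT", 2, 0.6)],
    )
    def test_diversity_values(self, seq, k, expected):
        assert kmer_diversity(seq, k) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "seq,k,expected",
        [("AAAAA", 2, 1.0), ("ATCGC", 2, 4.0), ("AAAT", 2, 1.8)],
    )
    def test_effective_count_values(self, seq, k, expected):
        assert effective_kmer_count(seq, k) == pytest.approx(expected)

    def test_short_sequence_signals(self):
        with pytest.raises(ValueError):
            kmer_diversity("A", 2)

    @given(seq=st.text(alphabet="ACGT", min_size=2, max_size=60))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_diversity_bounds_and_hill_relation(self, seq):
        k = 2
        n_windows = len(seq) - k + 1
        div = kmer_diversity(seq, k)
        eff = effective_kmer_count(seq, k)
        assert 1 / n_windows - 1e-12 <= div <= 1 + 1e-12
        assert 1 - 1e-12 <= eff <= n_windows + 1e-12
        assert eff == pytest.approx(n_windows * div)
        assert sum(count_kmers(seq, k).values()) == n_windows


def _locus(locus_id, left, right, unit="A", count=12, truncated=False):
    return StrLocus(
        locus_id=locus_id,
        chrom="c",
        start=100,
        end=100 + count * len(unit),
        unit=unit,
        ref_repeat_count=count,
        left_flank=left,
        right_flank=right,
        flank_window=len(left),
        truncated_flank=truncated,
    )


class TestFilterCatalog:
    def test_one_strand_coverage_suffices(self):
        locus = _locus("ok", "ATCGCTGCATCG", "CGATGCAGCGAT")
        kept = filter_catalog(
            [locus], coverage_by_strand={"ok": (25, 0)}, min_strand_coverage=20
        )
        assert [l.locus_id for l in kept] == ["ok"]

    def test_homopolymer_flank_removed(self):
        locus = _locus("lc", "AAAAAAAAAAAA", "CGATGCAGCGAT")
        assert filter_catalog([locus]) == []

    def test_low_coverage_both_strands_removed(self):
        locus = _locus("low", "ATCGCTGCATCG", "CGATGCAGCGAT")
        kept = filter_catalog(
            [locus], coverage_by_strand={"low": (10, 10)}, min_strand_coverage=20
        )
        assert kept == []

    def test_missing_coverage_is_zero(self):
        locus = _locus("gone", "ATCGCTGCATCG", "CGATGCAGCGAT")
        assert filter_catalog([locus], coverage_by_strand={}) == []

    def test_truncated_flanks_skip_complexity(self):
        locus = _locus("edge", "AAAA", "CGAT", truncated=True)
        assert [l.locus_id for l in filter_catalog([locus])] == ["edge"]


class TestLowComplexitySubset:
    def test_worked_examples(self):
        locus_a = _locus("A", "AAAAAAAAAAAC", "GCAATCCATACT")
        locus_b = _locus("B", "TTTTTTTTCCCC", "GCAATCCATACT")
        selected = select_low_complexity_subset([locus_a, locus_b])
        assert [l.locus_id for l in selected] == ["A"]
        retained = select_low_complexity_subset([locus_a, locus_b], invert=True)
        assert [l.locus_id for l in retained] == ["B"]

    def test_flank_identical_to_tract_selected(self):
        locus = _locus("dup", "A" * 12, "GCAATCCATACT")
        assert select_low_complexity_subset([locus]) == [locus]


class TestBuildCatalog:
    def test_flanks_roundtrip_and_frame(self):
        seq = "GGATCGATCGAT" + "A" * 11 + "TCAGTCAGTCAG"
        catalog = build_catalog({"chr": seq}, unit_sizes=(1,), flank_window=12)
        assert len(catalog) == 1
        locus = catalog[0]
        assert (locus.start, locus.end) == (12, 23)
        assert locus.left_flank == "GGATCGATCGAT"
        assert locus.right_flank == "TCAGTCAGTCAG"
        frame = catalog_to_frame(catalog)
        rebuilt = catalog_from_frame(frame)
        assert rebuilt[0] == locus

    def test_contig_edge_truncation_flagged(self):
        seq = "A" * 10 + "TCAGTCAGTCAGT"
        locus = build_catalog({"c": seq}, unit_sizes=(1,), flank_window=12)[0]
        assert locus.truncated_flank and locus.left_flank == ""

    def test_simulated_reference_recovers_truth(self, zero_error_run):
        _, loci, truth, _, _ = zero_error_run
        from tandemkit.simulate import make_reference, SimulationConfig

        cfg = SimulationConfig(
            seed=11, n_loci=50, coverage=30, p_del=0.0, p_ins=0.0, p_sub=0.0
        )
        reference, _, _ = make_reference(cfg)
        catalog = build_catalog(reference, unit_sizes=(1,), flank_window=12)
        found = {(l.start, l.end): l.ref_repeat_count for l in catalog}
        for locus in loci:
            assert found.get((locus.start, locus.end)) == truth[locus.locus_id]
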