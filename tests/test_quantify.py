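"""Read QC, tag mapping, annotation filtering, miRNA assignment, TPM."""
import numpy as np
import pytest

from mirseed import quantify as qt
from mirseed.types import (
    AnnotationFeature,
    GenomicInterval,
    ReadRecord,
    SequenceRecord,
    revcomp,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
RNG = np.random.default_rng(8)


def _seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


def _read(seq, quals=None, rid="r"):
    return ReadRecord(rid, seq, quals if quals is not None else [40] * len(seq))


class TestQcFilter:
    def test_adapter_trimmed_before_length_check(self):
        insert = _seq(22)
        res = qt.qc_filter([_read(insert + ADAPTER)], ADAPTER)
        assert [r.sequence for r in res.clean] == [insert]
        assert res.n_removed == 0

    def test_adapter_with_two_mismatches_still_trimmed(self):
        insert = _seq(22)
        fuzzy = "AA" + ADAPTER[2:]
        res = qt.qc_filter([_read(insert + fuzzy)], ADAPTER)
        assert [r.sequence for r in res.clean] == [insert]

    def test_adapter_dimer_attributed_to_rule_1(self):
        res = qt.qc_filter([_read(ADAPTER + _seq(8))], ADAPTER)
        assert res.tally["adapter"] == 1 and not res.clean

    def test_short_insert_removed_by_rule_4(self):
        res = qt.qc_filter([_read(_seq(17) + ADAPTER)], ADAPTER)
        assert res.tally["too_short"] == 1

    def test_ten_percent_n_exactly_is_kept(self):
        insert = "N" * 2 + _seq(18)  # 2/20 = 10.0%, rule is strictly >10%
        res = qt.qc_filter([_read(insert + ADAPTER)], ADAPTER)
        assert len(res.clean) == 1

    def test_over_ten_percent_n_removed(self):
        insert = "N" * 3 + _seq(17)
        res = qt.qc_filter([_read(insert + ADAPTER)], ADAPTER)
        assert res.tally["high_n"] == 1

    def test_low_quality_majority_removed(self):
        insert = _seq(20)
        quals = [10] * 11 + [40] * 9 + [40] * len(ADAPTER)  # 11/20 = 55% below Q20
        res = qt.qc_filter([_read(insert + ADAPTER, quals)], ADAPTER)
        assert res.tally["low_quality"] == 1

    def test_half_low_quality_exactly_is_kept(self):
        insert = _seq(20)
        quals = [10] * 10 + [40] * 10 + [40] * len(ADAPTER)
        res = qt.qc_filter([_read(insert + ADAPTER, quals)], ADAPTER)
        assert len(res.clean) == 1

    def test_rule_order_attribution(self):
        # a read that is both high-N and short goes to the earlier rule (2)
        insert = "NNNN" + _seq(10)
        res = qt.qc_filter([_read(insert + ADAPTER)], ADAPTER)
        assert res.tally["high_n"] == 1 and res.tally["too_short"] == 0

    def test_tally_sums_to_removed(self):
        reads = [
            _read(_seq(22) + ADAPTER),
            _read(ADAPTER + _seq(8)),
            _read("N" * 5 + _seq(15) + ADAPTER),
            _read(_seq(10) + ADAPTER),
        ]
        res = qt.qc_filter(reads, ADAPTER)
        assert res.n_removed == len(reads) - len(res.clean) == 3

    def test_short_adapter_error(self):
        with pytest.raises(ValueError):
            qt.qc_filter([], "ACGTACG")

    def test_idempotent(self):
        rng = np.random.default_rng(13)
        reads = [_read(_seq(int(rng.integers(10, 28)), rng) + ADAPTER, rid=f"r{i}")
                 for i in range(300)]
        once = qt.qc_filter(reads, ADAPTER)
        twice = qt.qc_filter(once.clean, ADAPTER)
        assert [r.sequence for r in twice.clean] == [r.sequence for r in once.clean]
        assert twice.n_removed == 0


class TestCollapseAndMap:
    GENOME = [SequenceRecord("c1", _seq(3000))]

    def _tag_from_genome(self, start, length, strand="+"):
        s = self.GENOME[0].sequence[start : start + length]
        return s if strand == "+" else revcomp(s)

    def test_identical_reads_collapse(self):
        tag = self._tag_from_genome(100, 22)
        lib = qt.collapse_and_map("s1", [_read(tag), _read(tag)], self.GENOME)
        assert lib.unique_tags == {tag: 2}
        (tp,) = lib.mapped_tags
        assert tp.count == 2 and tp.placements[0] == GenomicInterval("c1", 101, 122, "+")

    def test_one_mismatch_tag_dropped(self):
        tag = list(self._tag_from_genome(100, 22))
        tag[10] = {"A": "C"}.get(tag[10], "A")
        lib = qt.collapse_and_map("s1", [_read("".join(tag))], self.GENOME)
        assert lib.mapped_tags == [] and len(lib.unique_tags) == 1

    def test_minus_strand_placement(self):
        tag = self._tag_from_genome(200, 20, "-")
        lib = qt.collapse_and_map("s1", [_read(tag)], self.GENOME)
        assert lib.mapped_tags[0].placements[0].strand == "-"

    def test_multi_mapping_tag_keeps_all_placements(self):
        seg = self.GENOME[0].sequence[100:122]
        genome = [SequenceRecord("c1", _seq(200) + seg + _seq(300) + seg + _seq(200))]
        lib = qt.collapse_and_map("s1", [_read(seg)], genome)
        assert len(lib.mapped_tags[0].placements) == 2


class TestClassifyAnnotation:
    FEATURES = [
        AnnotationFeature(GenomicInterval("c1", 100, 200, "+"), "rRNA"),
        AnnotationFeature(GenomicInterval("c1", 500, 600, "+"), "exon"),
        AnnotationFeature(GenomicInterval("c1", 300, 800, "+"), "gene"),
    ]

    def _tp(self, start, end):
        return qt.TagPlacements("A" * (end - start + 1), 1,
                                [GenomicInterval("c1", start, end, "+")])

    def test_rrna_overlap_discarded(self):
        assert qt.classify_annotation([self._tp(150, 170)], self.FEATURES) == []

    def test_one_nt_exon_overlap_discarded(self):
        assert qt.classify_annotation([self._tp(480, 500)], self.FEATURES) == []

    def test_intronic_and_intergenic_kept(self):
        kept = qt.classify_annotation([self._tp(650, 670), self._tp(900, 920)], self.FEATURES)
        assert len(kept) == 2  # gene overlap alone does not discard


class TestAssignment:
    def test_exact_tag_counted(self):
        mat = _seq(22)
        lib = qt.Library("s1", 100, {mat: 5}, [qt.TagPlacements(mat, 5, [])])
        (e,) = qt.assign_reads_to_mirnas([lib], [qt.MatureRecord("m-5p", mat, ["m"])])
        assert e.raw_counts == {"s1": 5}

    def test_three_nonseed_mismatches_unassigned(self):
        mat = _seq(22)
        tag = list(mat)
        for p in (8, 12, 16):
            tag[p] = {"A": "C"}.get(tag[p], "A")
        lib = qt.Library("s1", 100, {}, [qt.TagPlacements("".join(tag), 3, [])])
        assert qt.assign_reads_to_mirnas([lib], [qt.MatureRecord("m-5p", mat, ["m"])]) == []

    def test_single_seed_mismatch_unassigned(self):
        mat = _seq(22)
        tag = list(mat)
        tag[3] = {"A": "C"}.get(tag[3], "A")
        lib = qt.Library("s1", 100, {}, [qt.TagPlacements("".join(tag), 3, [])])
        assert qt.assign_reads_to_mirnas([lib], [qt.MatureRecord("m-5p", mat, ["m"])]) == []

    def test_three_prime_trimming_tolerance(self):
        mat = _seq(22)
        lib = qt.Library("s1", 100, {}, [qt.TagPlacements(mat[:20], 2, [])])
        (e,) = qt.assign_reads_to_mirnas([lib], [qt.MatureRecord("m-5p", mat, ["m"])])
        assert e.raw_counts["s1"] == 2
        lib2 = qt.Library("s1", 100, {}, [qt.TagPlacements(mat[:19], 2, [])])
        assert qt.assign_reads_to_mirnas([lib2], [qt.MatureRecord("m-5p", mat, ["m"])]) == []

    def test_shared_mature_name_merges_precursors(self):
        mat = _seq(22)
        lib = qt.Library("s1", 100, {}, [qt.TagPlacements(mat, 4, [])])
        (e,) = qt.assign_reads_to_mirnas(
            [lib],
            [qt.MatureRecord("m-5p", mat, ["mir-x-1"]), qt.MatureRecord("m-5p", mat, ["mir-x-2"])],
        )
        assert e.precursor_names == ["mir-x-1", "mir-x-2"]
        assert e.raw_counts["s1"] == 4  # counted once for the shared name

    def test_distinct_names_each_counted(self):
        mat = _seq(22)
        lib = qt.Library("s1", 100, {}, [qt.TagPlacements(mat, 4, [])])
        out = qt.assign_reads_to_mirnas(
            [lib],
            [qt.MatureRecord("a-5p", mat, ["a"]), qt.MatureRecord("b-5p", mat, ["b"])],
        )
        assert [e.raw_counts["s1"] for e in out] == [4, 4]


class TestCalling:
    def _expr(self, counts):
        raw = {f"s{i+1}": c for i, c in enumerate(counts)}
        return qt.MirnaExpression("m-5p", ["m"], raw)

    @pytest.mark.parametrize(
        "counts,kept",
        [([3, 3, 3, 2], True),     # total 11, 4 individuals
         ([10, 0, 0, 0], False),   # total 10, only 1 individual
         ([4, 3, 3, 0], True),     # total 10, 3 individuals (boundary)
         ([3, 3, 2, 1], False)],   # total 9 < 10
    )
    def test_support_thresholds(self, counts, kept):
        out = qt.call_known_mirnas([self._expr(counts)])
        assert (len(out) == 1) is kept

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError):
            qt.call_known_mirnas([self._expr([10, 10])])


class TestTpm:
    def test_formula(self):
        assert qt.tpm({"s": 50}, {"s": 10_000_000}) == {"s": 5.0}
        assert qt.tpm({"s": 0}, {"s": 100})["s"] == 0.0

    def test_mean_over_samples(self):
        e = qt.MirnaExpression("m", ["m"], {"a": 10, "b": 20})
        lib_a = qt.Library("a", 1_000_000, {})
        lib_b = qt.Library("b", 2_000_000, {})
        qt.add_tpm([e], [lib_a, lib_b])
        assert e.tpm == {"a": 10.0, "b": 10.0} and e.mean_tpm == 10.0

    def test_zero_clean_reads_error(self):
        with pytest.raises(ValueError):
            qt.tpm({"s": 5}, {"s": 0})

    def test_per_sample_tpm_sums_below_one_million(self):
        rng = np.random.default_rng(4)
        clean = 10_000
        counts = rng.integers(0, 200, size=50)
        exprs = [qt.MirnaExpression(f"m{i}", [f"m{i}"], {"s": int(c)}) for i, c in enumerate(counts)]
        lib = qt.Library("s", clean, {})
        qt.add_tpm(exprs, [lib])
        assert sum(e.tpm["s"] for e in exprs) <= 1e6
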