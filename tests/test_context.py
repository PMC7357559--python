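"""Context classes, mirror pairs, 10-kb clusters, ages, rank correlation."""
import itertools

import numpy as np
import pytest
from scipy import stats

from mirseed import context as ctx
from mirseed.types import AnnotationFeature, GenomicInterval


def _iv(chrom, start, end, strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestClassifyContext:
    ANNOT = [
        AnnotationFeature(_iv("c1", 1000, 5000), "gene", "G1"),
        AnnotationFeature(_iv("c1", 1000, 1400), "exon", "G1.e1"),
        AnnotationFeature(_iv("c1", 4500, 5000), "exon", "G1.e2"),
        AnnotationFeature(_iv("c1", 4800, 5000), "UTR"),
    ]

    @pytest.mark.parametrize(
        "locus,expected",
        [
            (_iv("c1", 2000, 2080), "intronic"),
            (_iv("c1", 1100, 1180), "exonic"),
            (_iv("c1", 4810, 4890), "UTR"),
            (_iv("c1", 1380, 1450), "splice_site_overlapping"),
            (_iv("c1", 8000, 8080), "intergenic"),
        ],
    )
    def test_context_classes(self, locus, expected):
        assert ctx.classify_context("m", locus, self.ANNOT).context == expected

    def test_every_locus_gets_exactly_one_class(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            start = int(rng.integers(1, 9000))
            locus = _iv("c1", start, start + 80)
            ann = ctx.classify_context("m", locus, self.ANNOT)
            assert ann.context in ctx.CONTEXT_CLASSES

    def test_host_gene_recorded_regardless_of_strand(self):
        ann = ctx.classify_context("m", _iv("c1", 2000, 2080, "-"), self.ANNOT)
        assert ann.host_gene == "G1"


class TestMirrorPairs:
    def test_overlapping_opposite_strands_pair(self):
        loci = [("a", _iv("c1", 100, 180, "+")), ("b", _iv("c1", 120, 200, "-"))]
        assert ctx.find_mirror_pairs(loci) == [("a", "b")]

    def test_same_strand_overlap_is_not_a_pair(self):
        loci = [("a", _iv("c1", 100, 180, "+")), ("b", _iv("c1", 120, 200, "+"))]
        assert ctx.find_mirror_pairs(loci) == []

    def test_adjacent_non_overlapping_not_a_pair(self):
        loci = [("a", _iv("c1", 100, 180, "+")), ("b", _iv("c1", 181, 260, "-"))]
        assert ctx.find_mirror_pairs(loci) == []

    def test_symmetric_under_input_order(self):
        loci = [("b", _iv("c1", 120, 200, "-")), ("a", _iv("c1", 100, 180, "+"))]
        assert ctx.find_mirror_pairs(loci) == [("a", "b")]


def _brute_force_clusters(loci, max_gap):
    """Transitive closure of the pairwise within-gap same-strand relation."""
    def linked(a, b):
        if a.chrom != b.chrom or a.strand != b.strand:
            return False
        gap = max(a.start, b.start) - min(a.end, b.end) - 1
        return gap <= max_gap

    names = [n for n, _ in loci]
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for (na, a), (nb, b) in itertools.combinations(loci, 2):
        if linked(a, b):
            parent[find(na)] = find(nb)
    groups = {}
    for n, iv in loci:
        groups.setdefault(find(n), []).append((n, iv))
    return sorted(
        sorted(n for n, _ in g) for g in groups.values() if len(g) >= 2
    )


class TestDetectClusters:
    def test_two_loci_within_gap_cluster(self):
        loci = [("a", _iv("c1", 1000, 1080)), ("b", _iv("c1", 11080, 11160))]
        (cl,) = ctx.detect_clusters(loci)  # gap = 9999
        assert cl.members == ["a", "b"] and cl.span == _iv("c1", 1000, 11160)

    def test_gap_exactly_10kb_clusters(self):
        loci = [("a", _iv("c1", 1000, 1080)), ("b", _iv("c1", 11081, 11160))]
        assert len(ctx.detect_clusters(loci)) == 1

    def test_gap_over_10kb_does_not(self):
        loci = [("a", _iv("c1", 1000, 1080)), ("b", _iv("c1", 11082, 11160))]
        assert ctx.detect_clusters(loci) == []

    def test_opposite_strands_never_cluster(self):
        loci = [("a", _iv("c1", 1000, 1080, "+")), ("b", _iv("c1", 2000, 2080, "-"))]
        assert ctx.detect_clusters(loci) == []

    def test_transitive_chaining(self):
        loci = [("a", _iv("c1", 1000, 1080)), ("b", _iv("c1", 9000, 9080)),
                ("c", _iv("c1", 17000, 17080))]
        (cl,) = ctx.detect_clusters(loci)
        assert cl.members == ["a", "b", "c"]

    def test_duplicate_names_error(self):
        loci = [("a", _iv("c1", 1000, 1080)), ("a", _iv("c1", 2000, 2080))]
        with pytest.raises(ValueError, match="a"):
            ctx.detect_clusters(loci)

    def test_equals_brute_force_transitive_closure(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(5, 120))
            loci = []
            for i in range(n):
                start = int(rng.integers(1, 300_000))
                loci.append((f"L{i}", _iv(rng.choice(["c1", "c2"]), start, start + 80,
                                          rng.choice(["+", "-"]))))
            got = sorted(sorted(c.members) for c in ctx.detect_clusters(loci))
            assert got == _brute_force_clusters(loci, 10_000)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        loci = [(f"L{i}", _iv("c1", int(rng.integers(1, 100_000)), int(rng.integers(1, 100_000)) + 100_100))
                for i in range(20)]
        loci = [(n, _iv("c1", iv.start, iv.start + 80)) for n, iv in loci]
        a = ctx.detect_clusters(loci)
        b = ctx.detect_clusters(list(reversed(loci)))
        assert [c.members for c in a] == [c.members for c in b]


class TestSeedClassAndFamilies:
    def _cluster(self, members):
        return ctx.Cluster(members, _iv("c1", 1, 10_000), "+")

    def test_identical_seeds_homo(self):
        seeds = {"a": "GTAAACA", "b": "GUAAACA"}  # U/T spellings compare equal
        assert ctx.classify_cluster_seed(self._cluster(["a", "b"]), seeds) == "homo"

    def test_distinct_seeds_hetero(self):
        seeds = {"a": "GTAAACA", "b": "ATAAACA"}
        assert ctx.classify_cluster_seed(self._cluster(["a", "b"]), seeds) == "hetero"

    def test_three_members_one_off_hetero(self):
        seeds = {"a": "GTAAACA", "b": "GTAAACA", "c": "GTAAACC"}
        assert ctx.classify_cluster_seed(self._cluster(["a", "b", "c"]), seeds) == "hetero"

    def test_member_without_seed_error(self):
        with pytest.raises(ValueError, match="b"):
            ctx.classify_cluster_seed(self._cluster(["a", "b"]), {"a": "GTAAACA"})

    def test_family_grouping_by_seed_identity(self):
        fams = ctx.group_families({"a": "GTAAACA", "b": "GUAAACA", "c": "CCCCCCC"})
        assert sorted(map(len, fams.values())) == [1, 2]


class TestAssignAge:
    @pytest.mark.parametrize(
        "species,expected",
        [
            (["hsa", "mmu", "dre"], "vertebrate"),
            (["hsa", "mmu"], "mammal"),
            (["hsa", "mml"], "primate"),
            (["mfa", "mml"], "cercopithecidae"),
        ],
    )
    def test_broadest_clade_wins(self, species, expected):
        assert ctx.assign_age(species) == expected

    def test_unknown_species_error_lists_label(self):
        with pytest.raises(ValueError, match="xyz"):
            ctx.assign_age(["hsa", "xyz"])

    def test_custom_clade_table(self):
        assert ctx.assign_age(["frog"], {"frog": "vertebrate"}) == "vertebrate"

    def test_ordinal_ranks(self):
        assert [ctx.age_rank(a) for a in ctx.AGE_CATEGORIES] == [1, 2, 3, 4]


class TestSpearman:
    def test_perfectly_monotone(self):
        ages = ["vertebrate", "mammal", "primate", "cercopithecidae"]
        rho, p = ctx.spearman_age_expression(ages, [100, 50, 10, 1])
        assert rho == pytest.approx(1.0)

    def test_monotone_with_ties_positive_and_significant(self):
        ages = ["vertebrate", "vertebrate", "mammal", "mammal", "primate",
                "primate", "cercopithecidae", "cercopithecidae"]
        tpm = [100, 90, 50, 40, 10, 8, 1, 0.5]
        rho, p = ctx.spearman_age_expression(ages, tpm)
        assert rho > 0.9 and p < 0.05

    def test_reversed_is_negative(self):
        ages = ["vertebrate", "mammal", "primate", "cercopithecidae"]
        rho, _ = ctx.spearman_age_expression(ages, [1, 10, 50, 100])
        assert rho == pytest.approx(-1.0)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            ctx.spearman_age_expression(["mammal"] * 3, [1, 2, 3])

    def test_matches_rank_pearson_oracle(self):
        """On <= 8 points: rho equals Pearson correlation of average ranks."""
        rng = np.random.default_rng(2)
        cats = list(ctx.AGE_CATEGORIES)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            ages = [cats[int(i)] for i in rng.integers(0, 4, size=n)]
            tpm = rng.gamma(1.0, 50.0, size=n)
            rho, _ = ctx.spearman_age_expression(ages, tpm)
            scores = [5 - ctx.age_rank(a) for a in ages]
            r_oracle = np.corrcoef(stats.rankdata(scores), stats.rankdata(tpm))[0, 1]
            if np.isnan(r_oracle):
                assert np.isnan(rho)
            else:
                assert rho == pytest.approx(r_oracle, abs=1e-12)
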