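import math

import numpy as np
import pytest

from bccluster.relation_classify import (
    ClassifyConfig,
    HitRecord,
    KarlinAltschul,
    classify_bcc,
    classify_pair,
    cluster_best_hits,
    evalue,
    local_align,
    merge_allelic,
    merge_redundant,
)

RNG = np.random.default_rng(42)
BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(rng.choice(BASES, size=n))


def with_substitutions(rng, seq, n_subs, margin=10):
    """Plant n interior substitutions (away from the ends)."""
    chars = list(seq)
    positions = rng.choice(
        np.arange(margin, len(seq) - margin), size=n_subs, replace=False
    )
    for p in positions:
        chars[p] = next(b for b in "ACGT" if b != chars[p])
    return "".join(chars)


class TestLocalAlign:
    def test_identical_sequences(self):
        s = random_seq(RNG, 100)
        aln = local_align(s, s)
        assert aln.aligned_cols == 100
        assert aln.identity_pct == 100.0
        assert aln.a_range == (0, 100) and aln.b_range == (0, 100)

    def test_interior_substitutions_identity(self):
        a = random_seq(RNG, 600)
        b = with_substitutions(RNG, a, 5)
        aln = local_align(a, b)
        assert aln.aligned_cols == 600
        assert aln.identities == 595
        assert aln.identity_pct == pytest.approx(100 * 595 / 600, abs=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_random_pairs_fail_duplicate_evalue_test(self):
        """Null distribution: unrelated 200-mers almost never reach E < 1e-5."""
        rng = np.random.default_rng(7)
        hits = 0
        trials = 300
        for _ in range(trials):
            aln = local_align(random_seq(rng, 200), random_seq(rng, 200))
            if aln.e_value < 1e-5:
                hits += 1
        assert hits / trials <= 0.01


class TestEvalue:
    def test_zero_score_formula(self):
        assert evalue(0.0, 1000, 1000) == pytest.approx(0.46 * 1000 * 1000)

    def test_matches_direct_formula(self):
        # independent evaluation of K m n exp(-lambda S)
        expected = 0.46 * 1000 * 1000 * math.exp(-1.28 * 20)
        assert evalue(20.0, 1000, 1000) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.5e-6, rel=0.05)

    def test_monotone_decreasing_in_score(self):
        values = [evalue(s, 500, 500) for s in range(0, 60, 5)]
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            KarlinAltschul(K=0.0, lam=1.28)
        with pytest.raises(ValueError):
            evalue(1.0, 0, 10)


class TestClassifyPair:
    def test_allelic_with_long_single_stranded_overhang(self):
        core = random_seq(RNG, 600)
        a = core
        b = with_substitutions(RNG, core, 5) + random_seq(RNG, 150)
        rel = classify_pair(a, b)
        assert rel.verdict == "allelic"
        assert rel.flank_b_right >= 140  # the permitted overhang

    def test_shared_block_is_duplicated(self):
        block = random_seq(RNG, 200)
        diverged = with_substitutions(RNG, block, 20)  # 90% identity
        a = random_seq(RNG, 300) + block + random_seq(RNG, 300)
        b = random_seq(RNG, 300) + diverged + random_seq(RNG, 300)
        rel = classify_pair(a, b)
        assert rel.verdict == "duplicated"
        assert rel.alignment.e_value < 1e-5

    def test_unrelated_sequences_are_alt_splice(self):
        rel = classify_pair(random_seq(RNG, 500), random_seq(RNG, 500))
        assert rel.verdict == "alt_splice"

    def test_double_stranded_mismatching_flank_blocks_allelic(self):
        """99% identity core but 12 dissimilar terminal bases on both sequences."""
        core = random_seq(RNG, 400)
        a = core + random_seq(RNG, 12)
        b = with_substitutions(RNG, core, 4) + random_seq(RNG, 12)
        rel = classify_pair(a, b)
        # both sequences have ~12 nt unaligned on the right: > 10 disqualifies
        if min(rel.flank_a_right, rel.flank_b_right) > 0 and max(
            rel.flank_a_right, rel.flank_b_right
        ) > 10:
            assert rel.verdict != "allelic"

    def test_reverse_complement_pair_is_allelic(self):
        comp = str.maketrans("ACGT", "TGCA")
        a = random_seq(RNG, 300)
        b = a.translate(comp)[::-1]
        rel = classify_pair(a, b)
        assert rel.verdict == "allelic"
        assert rel.alignment.strand == "reverse"

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        core = random_seq(rng, 300)
        a = core + random_seq(rng, 50)
        b = with_substitutions(rng, core, 3)
        assert classify_pair(a, b).verdict == classify_pair(b, a).verdict


class TestClassifyBcc:
    def test_three_dissimilar_contigs_alt_splicing(self):
        seqs = {f"c{i}": random_seq(RNG, 400) for i in range(3)}
        cls = classify_bcc(set(seqs), seqs)
        assert cls.verdict == "alternative_splicing"
        assert [sorted(g) for g in cls.merged_groups] == [["c0"], ["c1"], ["c2"]]

    def test_allelic_pair_within_splice_triangle(self):
        base = random_seq(RNG, 500)
        seqs = {
            "c0": base,
            "c1": with_substitutions(RNG, base, 4),  # 99.2% identical to c0
            "c2": random_seq(RNG, 500),
        }
        cls = classify_bcc(set(seqs), seqs)
        assert cls.verdict == "alternative_splicing"
        assert sorted(sorted(g) for g in cls.merged_groups) == [["c0", "c1"], ["c2"]]

    def test_all_allelic_triangle(self):
        base = random_seq(RNG, 500)
        seqs = {
            "c0": base,
            "c1": with_substitutions(RNG, base, 3),
            "c2": with_substitutions(RNG, base, 5),
        }
        cls = classify_bcc(set(seqs), seqs)
        assert cls.verdict == "allelic"
        assert cls.merged_groups == [{"c0", "c1", "c2"}]

    def test_missing_sequence_names_contig(self):
        with pytest.raises(KeyError, match="c1"):
            classify_bcc({"c0", "c1"}, {"c0": "ACGT"})


class TestMergeAllelic:
    def test_identical_sequences_unchanged(self):
        s = random_seq(RNG, 200)
        rel = classify_pair(s, s)
        assert merge_allelic(s, s, rel.alignment, 10, 10) == s

    def test_mismatch_resolved_by_coverage(self):
        a = random_seq(RNG, 200)
        b = with_substitutions(RNG, a, 1)
        rel = classify_pair(a, b)
        assert merge_allelic(a, b, rel.alignment, 30, 10) == a
        assert merge_allelic(a, b, rel.alignment, 10, 30) == b

    def test_overhang_extends_merged_sequence(self):
        a = random_seq(RNG, 300)
        b = a + random_seq(RNG, 100)
        rel = classify_pair(a, b)
        merged = merge_allelic(a, b, rel.alignment, 10, 10)
        assert merged == b  # alignment span + the 3' overhang

    def test_merge_is_classification_fixpoint(self):
        a = random_seq(RNG, 400)
        b = with_substitutions(RNG, a, 3) + random_seq(RNG, 60)
        rel = classify_pair(a, b)
        assert rel.verdict == "allelic"
        merged = merge_allelic(a, b, rel.alignment, 20, 10)
        assert classify_pair(merged, a).verdict == "allelic"
        assert classify_pair(merged, b).verdict == "allelic"

    def test_rejects_missing_alignment(self):
        with pytest.raises(ValueError):
            merge_allelic("ACGT", "ACGT", None, 1, 1)


class TestMergeRedundant:
    def test_substring_singleton_absorbed(self):
        contig = random_seq(RNG, 600)
        contigs = [("c1", contig)]
        singles = [("s1", contig[100:400])]
        _, remaining, report = merge_redundant(contigs, singles)
        assert remaining == []
        assert report["singletons_merged_into_contigs"] == 1

    def test_long_mismatching_end_blocks_merge(self):
        contig = random_seq(RNG, 600)
        singles = [("s1", contig[100:400] + random_seq(RNG, 12))]
        _, remaining, _ = merge_redundant([("c1", contig)], singles)
        assert [s[0] for s in remaining] == ["s1"]

    def test_identical_singletons_deduplicated(self):
        s = random_seq(RNG, 300)
        _, remaining, report = merge_redundant([], [("s1", s), ("s2", s)])
        assert [r[0] for r in remaining] == ["s1"]
        assert report["redundant_singletons_removed"] == 1

    def test_never_increases_and_idempotent(self):
        rng = np.random.default_rng(5)
        contigs = [("c1", random_seq(rng, 500))]
        singles = [
            ("s1", contigs[0][1][:300]),
            ("s2", random_seq(rng, 250)),
            ("s3", random_seq(rng, 250)),
        ]
        _, rem1, _ = merge_redundant(contigs, singles)
        assert len(rem1) <= len(singles)
        _, rem2, rep2 = merge_redundant(contigs, rem1)
        assert rem2 == rem1
        assert sum(rep2.values()) == 0


class TestClusterBestHits:
    def make_hits(self):
        return [
            HitRecord("q1", "h1a", "H1", 1e-20, 200.0),
            HitRecord("q2", "h1b", "H1", 1e-15, 150.0),
            HitRecord("q3", "h1c", "H1", 1e-10, 120.0),
            HitRecord("q3", "h2a", "H2", 1e-8, 90.0),
            HitRecord("q4", "h2b", "H2", 1e-4, 40.0),
        ]

    def test_shared_best_hit_forms_major_cluster(self):
        clusters = {c.group_id: c for c in cluster_best_hits(self.make_hits())}
        assert clusters["H1"].members == {"q1", "q2", "q3"}
        assert clusters["H1"].major

    def test_best_hit_assignment_prefers_lowest_evalue(self):
        clusters = {c.group_id: c for c in cluster_best_hits(self.make_hits())}
        # q3's best hit is H1, so the H2 cluster (holding q3 via a weaker
        # hit) is not major
        assert clusters["H2"].members == {"q3"}
        assert not clusters["H2"].major

    def test_weak_hit_unassigned_at_cutoff(self):
        clusters = cluster_best_hits(self.make_hits())
        assert not any("q4" in c.members for c in clusters)

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError):
            HitRecord("q", "s", "G", -1.0, 5.0)
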