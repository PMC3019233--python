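import math
from fractions import Fraction

import pytest

from bccluster.assembly_io import PairwiseAlignment
from bccluster.variant_pipeline import (
    FilterConfig,
    MsaMatrix,
    VariantCall,
    build_msa,
    call_variants,
    filter_variants,
    homopolymer_positions,
    remove_homopolymer_gaps,
    summarize_density,
    tabulate_changes,
    variant_probability,
    write_vcf,
)


def oracle_probability(k1, k2, ko=0, eps=0.01, pi=0.005):
    """Closed-form posterior computed with exact rational arithmetic."""
    e = Fraction(eps).limit_denominator(10**12)
    p = Fraction(pi).limit_denominator(10**12)
    l0 = (1 - e) ** k1 * (e / 3) ** (k2 + ko)
    beta = Fraction(
        math.factorial(k1) * math.factorial(k2), math.factorial(k1 + k2 + 1)
    )
    l1 = beta * (1 - e) ** (k1 + k2) * (e / 3) ** ko
    return float(p * l1 / (p * l1 + (1 - p) * l0))


def aln(columns, contig="c", read="r", anchor=1):
    return PairwiseAlignment(
        contig_id=contig, read_id=read, columns=columns, consensus_anchor=anchor
    )


class TestRemoveHomopolymerGaps:
    def test_gap_inside_long_run_removed(self):
        # read AAAA vs consensus AAA*A-style: consensus-side gap in an A run
        columns = [("A", "A"), ("A", "A"), ("A", "A"), ("*", "A"), ("C", "C")]
        cleaned, removed = remove_homopolymer_gaps(aln(columns))
        assert removed == [3]
        assert cleaned.columns == [("A", "A"), ("A", "A"), ("A", "A"), ("C", "C")]

    def test_gap_without_adjacent_run_kept(self):
        columns = [("C", "C"), ("*", "T"), ("G", "G")]
        cleaned, removed = remove_homopolymer_gaps(aln(columns))
        assert removed == []
        assert cleaned.columns == columns

    def test_run_of_two_below_threshold_kept(self):
        columns = [("A", "A"), ("*", "A"), ("C", "C")]
        cleaned, removed = remove_homopolymer_gaps(aln(columns), min_run=3)
        assert removed == []
        assert cleaned.columns == columns

    def test_read_side_gap_masked_not_deleted(self):
        # deletion in the read inside a TTT run: consensus coordinates must
        # be preserved, so the column is masked rather than dropped
        columns = [("T", "T"), ("T", "T"), ("T", "*"), ("G", "G")]
        cleaned, removed = remove_homopolymer_gaps(aln(columns))
        assert removed == [2]
        assert cleaned.columns[2] == ("T", ".")
        assert cleaned.consensus_fragment() == "TTTG"


class TestBuildMsa:
    def test_two_full_reads_coverage_two(self):
        cons = "ACGT" * 25
        alns = [
            aln([(c, c) for c in cons], read="r1"),
            aln([(c, c) for c in cons], read="r2"),
        ]
        msa = build_msa(alns, consensus=cons)
        assert len(msa.columns) == 100
        assert all(msa.coverage(k) == 2 for k in msa.columns)

    def test_insertion_column_keyed_by_rank(self):
        cons = "ACGTACGTACGT"
        cols = [(c, c) for c in cons[:10]]
        cols.insert(10, ("*", "T"))  # insertion after 0-based position 9
        msa = build_msa([aln(cols, read="r1")], consensus=cons)
        assert (9, 1) in msa.columns
        assert msa.columns[(9, 1)] == {"r1": "T"}

    def test_spanning_read_observes_gap_at_insertion(self):
        cons = "ACGTACGTACGT"
        with_ins = [(c, c) for c in cons]
        with_ins.insert(6, ("*", "A"))
        plain = [(c, c) for c in cons]
        msa = build_msa([aln(with_ins, read="ri"), aln(plain, read="rp")],
                        consensus=cons)
        assert msa.columns[(5, 1)] == {"ri": "A", "rp": "-"}

    def test_empty_input(self):
        msa = build_msa([])
        assert msa.columns == {}

    def test_mixed_contigs_rejected(self):
        with pytest.raises(ValueError):
            build_msa([aln([("A", "A")], contig="c1"),
                       aln([("A", "A")], contig="c2")])


class TestCallVariants:
    @staticmethod
    def column_msa(bases, consensus="A" * 1 + "CGT"):
        msa = MsaMatrix(contig_id="c", consensus="ACGTACGT")
        msa.columns[(1, 0)] = {f"r{i}": b for i, b in enumerate(bases)}
        return msa

    def test_monomorphic_column_no_call(self):
        assert call_variants(self.column_msa(["C"] * 10)) == []

    @pytest.mark.parametrize("k1,k2", [(10, 10), (19, 1), (16, 4), (30, 2)])
    def test_probability_matches_exact_oracle(self, k1, k2):
        got = variant_probability(k1, k2)
        assert got == pytest.approx(oracle_probability(k1, k2), rel=1e-9)

    def test_balanced_column_passes_and_skewed_fails_threshold(self):
        assert variant_probability(10, 10) > 0.9
        assert variant_probability(19, 1) < 0.9

    def test_probability_monotone_in_minor_count(self):
        # strictly increasing until the posterior saturates at 1 in floats
        for total in (10, 20, 40):
            probs = [variant_probability(total - k2, k2) for k2 in range(1, total // 2)]
            for x, y in zip(probs, probs[1:]):
                assert x <= y
                if y < 1.0 - 1e-12:
                    assert x < y

    def test_call_carries_counts_and_coverage(self):
        calls = call_variants(self.column_msa(["C"] * 12 + ["T"] * 8))
        (call,) = calls
        assert call.kind == "snp"
        assert call.coverage == 20
        assert call.counts["C"] == 12 and call.counts["T"] == 8
        assert call.position == 1

    def test_deletion_and_homopolymer_flag(self):
        msa = MsaMatrix(contig_id="c", consensus="GGAAACC")
        msa.columns[(3, 0)] = {f"r{i}": ("A" if i < 10 else "-") for i in range(15)}
        (call,) = call_variants(msa)
        assert call.kind == "deletion"
        assert call.homopolymer  # inside the AAA run

    def test_adjacent_deletions_merge(self):
        msa = MsaMatrix(contig_id="c", consensus="ACGTACGT")
        for pos in (2, 3):
            msa.columns[(pos, 0)] = {
                f"r{i}": (msa.consensus[pos] if i < 10 else "-") for i in range(16)
            }
        calls = call_variants(msa)
        assert len(calls) == 1
        assert calls[0].kind == "deletion"
        assert calls[0].ref_allele == "GT"

    def test_insertion_call_from_rank_column(self):
        msa = MsaMatrix(contig_id="c", consensus="ACGTACGT")
        msa.columns[(4, 1)] = {f"r{i}": ("T" if i < 9 else "-") for i in range(18)}
        (call,) = call_variants(msa)
        assert call.kind == "insertion"
        assert call.ref_allele == "-" and call.alt_allele == "T"


class TestFilterSemantics:
    @staticmethod
    def call(kind="snp", coverage=50, probability=0.99, homopolymer=False):
        counts = {"A": coverage - 5, "G": 5}
        return VariantCall(
            contig_id="c", position=10, kind=kind,
            ref_allele="A" if kind != "insertion" else "-",
            alt_allele="G" if kind == "snp" else ("-" if kind == "deletion" else "G"),
            counts=counts, coverage=coverage, probability=probability,
            homopolymer=homopolymer,
        )

    def test_each_rule_rejects_with_its_reason(self):
        calls = [
            self.call(coverage=4),                       # below 5
            self.call(coverage=101),                     # above 100
            self.call(probability=0.89),                 # below 0.9
            self.call(kind="insertion", homopolymer=True),
            self.call(kind="deletion", homopolymer=True),
            self.call(kind="snp", homopolymer=True),     # SNP in hp context: kept
            self.call(),                                 # clean: kept
        ]
        kept, report = filter_variants(calls)
        assert len(kept) == 2
        assert report.counts == {
            "coverage_low": 1,
            "coverage_high": 1,
            "low_probability": 1,
            "homopolymer_indel": 2,
        }
        reasons = [r for _, r in report.rejected]
        assert reasons == ["coverage_low", "coverage_high", "low_probability",
                           "homopolymer_indel", "homopolymer_indel"]

    def test_filter_is_idempotent(self):
        calls = [self.call(), self.call(probability=0.95),
                 self.call(kind="deletion")]
        kept, _ = filter_variants(calls)
        again, report = filter_variants(kept)
        assert again == kept
        assert sum(report.counts.values()) == 0

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(min_coverage=10, max_coverage=5)


class TestSummaries:
    def test_transition_counting(self):
        calls = [TestFilterSemantics.call() for _ in range(3)]
        for c in calls:
            c.ref_allele, c.alt_allele = "A", "G"
        calls += [TestFilterSemantics.call() for _ in range(2)]
        for c in calls[3:]:
            c.ref_allele, c.alt_allele = "C", "T"
        spec = tabulate_changes(calls)
        assert spec["transitions"] == 5 and spec["transversions"] == 0
        assert int(spec["substitutions"].to_numpy().sum()) == 5

    def test_single_transversion(self):
        c = TestFilterSemantics.call()
        c.ref_allele, c.alt_allele = "A", "T"
        spec = tabulate_changes([c])
        assert spec["transversions"] == 1 and spec["transitions"] == 0

    def test_density_spacing_from_aggregate_frequency(self):
        """567 SNPs over 100 kbp -> 0.00567 SNP/bp, one per 176 bp."""
        contigs = {f"c{i}": (1000, 20) for i in range(100)}
        calls = []
        for i in range(567):
            c = TestFilterSemantics.call()
            c.contig_id = f"c{i % 100}"
            calls.append(c)
        _, summary = summarize_density(calls, contigs)
        assert summary["snp_per_bp"] == pytest.approx(0.00567)
        assert summary["snp_spacing_bp"] == 176

    def test_zero_calls(self):
        _, summary = summarize_density([], {"c": (100, 5)})
        assert summary["snp_per_bp"] == 0.0
        assert summary["snp_spacing_bp"] is None

    def test_length_weighted_mean_matches_global(self):
        contigs = {"a": (500, 5), "b": (1500, 10)}
        calls = []
        for cid, n in (("a", 3), ("b", 5)):
            for _ in range(n):
                c = TestFilterSemantics.call()
                c.contig_id = cid
                calls.append(c)
        table, summary = summarize_density(calls, contigs)
        weighted = (table["snp_per_bp"] * table["length"]).sum() / table["length"].sum()
        assert weighted == pytest.approx(summary["snp_per_bp"])

    def test_unknown_contig_rejected(self):
        with pytest.raises(KeyError):
            summarize_density([TestFilterSemantics.call()], {"other": (100, 5)})


class TestVcf:
    CONS = {"c": "ACGTAACGTACGT"}

    def test_snp_position_one_based(self, tmp_path):
        c = TestFilterSemantics.call()
        c.position, c.ref_allele, c.alt_allele = 9, "A", "G"
        path = tmp_path / "x.vcf"
        write_vcf([c], path, self.CONS)
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        fields = line.split("\t")
        assert fields[1] == "10" and fields[3] == "A" and fields[4] == "G"

    def test_deletion_left_anchored(self, tmp_path):
        c = TestFilterSemantics.call(kind="deletion")
        c.position, c.ref_allele, c.alt_allele = 5, "A", "-"
        path = tmp_path / "d.vcf"
        write_vcf([c], path, self.CONS)
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        fields = line.split("\t")
        assert fields[1] == "5"
        assert len(fields[3]) == 2 and len(fields[4]) == 1
        assert fields[3][0] == fields[4]

    def test_round_trip_record_count(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        calls = []
        for i, pos in enumerate((2, 5, 9)):
            c = TestFilterSemantics.call()
            c.position = pos
            calls.append(c)
        path = tmp_path / "rt.vcf"
        write_vcf(calls, path, self.CONS)
        with pysam.VariantFile(str(path)) as vf:
            records = list(vf)
        assert len(records) == 3
        assert [r.pos for r in records] == [3, 6, 10]

    def test_unknown_contig_rejected(self, tmp_path):
        c = TestFilterSemantics.call()
        c.contig_id = "nope"
        with pytest.raises(KeyError):
            write_vcf([c], tmp_path / "x.vcf", self.CONS)


class TestHomopolymerPositions:
    def test_run_and_shoulders_flagged(self):
        # GGAAACC: AAA run at 2-4 plus one shoulder each side
        assert homopolymer_positions("GGAAACC") == {1, 2, 3, 4, 5}

    def test_no_run_no_flags(self):
        assert homopolymer_positions("ACGTACGT") == set()
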