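"""Codon-level diversity: Nei–Gojobori counting against brute-force oracles."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from mitodiv import seq_diversity as sq
from mitodiv.seq_diversity import (
    AlignmentError,
    CodonAlignment,
    concatenate_genes,
    count_sites,
    diversity,
    pairwise_counts,
    read_alignment,
)


def oracle_translate(codon: str) -> str:
    """Independent translation route (string-level, table 2)."""
    return str(Seq(codon).translate(table=2))


def oracle_site_counts(codon: str) -> tuple[float, float]:
    """Exhaustive 9-change enumeration; changes to stops are nonsynonymous."""
    aa = oracle_translate(codon)
    syn = 0.0
    for pos, b in itertools.product(range(3), "ACGT"):
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        alt_aa = oracle_translate(alt)
        if alt_aa == aa and alt_aa != "*":
            syn += 1 / 3
    return syn, 3.0 - syn


class TestCountSites:
    def test_phenylalanine_third_position_twofold(self):
        sc = count_sites("TTT")
        assert sc.syn_sites == pytest.approx(1 / 3)
        assert sc.nonsyn_sites == pytest.approx(8 / 3)

    def test_glycine_third_position_fourfold(self):
        sc = count_sites("GGC")
        assert sc.syn_sites == pytest.approx(1.0)
        assert sc.nonsyn_sites == pytest.approx(2.0)

    def test_all_coding_codons_match_exhaustive_enumeration(self):
        for codon in sq.CODING_CODONS:
            syn, nonsyn = oracle_site_counts(codon)
            sc = count_sites(codon)
            assert sc.syn_sites == pytest.approx(syn), codon
            assert sc.nonsyn_sites == pytest.approx(nonsyn), codon

    def test_sites_partition_each_codon_into_three(self):
        for codon in sq.CODING_CODONS:
            sc = count_sites(codon)
            assert sc.syn_sites + sc.nonsyn_sites == pytest.approx(3.0)

    @pytest.mark.parametrize("bad", ["TAA", "TAG", "AGA", "AGG"])
    def test_stop_codons_rejected(self, bad):
        with pytest.raises(ValueError):
            count_sites(bad)

    def test_ambiguous_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("ANT")


def oracle_pathway(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Brute-force pathway enumeration with stop-avoiding intermediates."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        steps = []
        cur = codon_a
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if oracle_translate(nxt) == "*" and nxt != codon_b:
                blocked = True
                break
            syn = (
                oracle_translate(cur) == oracle_translate(nxt)
                and oracle_translate(nxt) != "*"
                and oracle_translate(cur) != "*"
            )
            steps.append(syn)
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths:
        return None  # all pathways stop-blocked; convention tested separately
    syn = np.mean([sum(p) for p in paths])
    return float(syn), float(len(diff) - syn)


class TestPairwiseCounts:
    def test_identical_sequences_have_zero_differences(self):
        sd, nd, ss, ns = pairwise_counts("ATGGCC", "ATGGCC")
        assert sd == 0 and nd == 0
        assert ss > 0 and ns > 0

    def test_single_synonymous_change(self):
        sd, nd, _, _ = pairwise_counts("TTT", "TTC")
        assert sd == 1.0 and nd == 0.0

    def test_two_step_codon_pairs_match_pathway_oracle(self, rng):
        codons = sq.CODING_CODONS
        checked = 0
        for _ in range(300):
            a, b = rng.choice(codons, 2)
            expected = oracle_pathway(a, b)
            if expected is None:
                continue
            sd, nd, _, _ = pairwise_counts(a, b)
            assert sd == pytest.approx(expected[0]), (a, b)
            assert nd == pytest.approx(expected[1]), (a, b)
            checked += 1
        assert checked > 200

    def test_gapped_codons_excluded_pairwise(self):
        sd_full, nd_full, ss_full, ns_full = pairwise_counts("TTTGGC", "TTCGGC")
        sd, nd, ss, ns = pairwise_counts("TTTGG-", "TTCGGC")
        assert (sd, nd) == (sd_full - 0, nd_full)
        assert ss < ss_full and ns < ns_full
        # only the first codon remains comparable
        assert sd == 1.0


class TestDiversity:
    def test_identical_pair_has_undefined_ratio(self):
        aln = CodonAlignment("sp", ["ATGGCC", "ATGGCC"], ["a", "b"])
        est = diversity(aln)
        assert est.pi_s == 0.0 and est.pi_n == 0.0
        assert est.ratio is None and not est.ratio_defined

    def test_single_pair_arithmetic(self):
        # 1 synonymous difference over the pair's synonymous sites
        aln = CodonAlignment("sp", ["TTTGGC", "TTCGGC"], ["a", "b"])
        est = diversity(aln)
        sd, nd, ss, ns = pairwise_counts("TTTGGC", "TTCGGC")
        assert est.pi_s == pytest.approx(sd / ss)
        assert est.pi_n == 0.0

    def test_multi_sequence_equals_mean_over_all_pairs(self, rng):
        seqs = [
            "".join(rng.choice(sq.CODING_CODONS, 40)) for _ in range(5)
        ]
        aln = CodonAlignment("sp", seqs, [f"i{k}" for k in range(5)])
        est = diversity(aln)
        ps, pn = [], []
        for a, b in itertools.combinations(seqs, 2):
            sd, nd, ss, ns = pairwise_counts(a, b)
            ps.append(sd / ss)
            pn.append(nd / ns)
        assert est.pi_s == pytest.approx(np.mean(ps))
        assert est.pi_n == pytest.approx(np.mean(pn))

    def test_invariant_to_sequence_order(self, rng):
        seqs = ["".join(rng.choice(sq.CODING_CODONS, 30)) for _ in range(4)]
        ids = list("abcd")
        est1 = diversity(CodonAlignment("sp", seqs, ids))
        est2 = diversity(CodonAlignment("sp", seqs[::-1], ids[::-1]))
        assert est1.pi_s == pytest.approx(est2.pi_s)
        assert est1.pi_n == pytest.approx(est2.pi_n)

    def test_single_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            diversity(CodonAlignment("sp", ["ATG"], ["a"]))


class TestReadAlignment:
    def test_identity_case(self):
        aln = read_alignment(">a\nATGGCC\n>b\nATGGCC\n")
        assert aln.n_sequences == 2 and aln.n_codons == 2

    def test_frame_offset_drops_leading_base(self):
        aln = read_alignment(">a\nCATGGCC\n>b\nCATGGCC\n", frame_offset=1)
        assert aln.n_codons == 2
        assert aln.sequences[0] == "ATGGCC"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            read_alignment(">a\nATGGCC\n>b\nATG\n")

    def test_non_iupac_symbols_rejected(self):
        with pytest.raises(AlignmentError):
            read_alignment(">a\nATXGCC\n>b\nATGGCC\n")

    def test_record_order_preserved(self, toy_fasta):
        aln = read_alignment(toy_fasta)
        assert aln.sequence_ids == ["ind1", "ind2", "ind3"]


class TestConcatenateGenes:
    def test_codon_additivity_and_spans(self):
        a = read_alignment(">x\nATGGCC\n>y\nATGGCC\n", gene="g1")
        b = read_alignment(">x\nTTTTTCGGA\n>y\nTTTTTCGGA\n", gene="g2")
        cat = concatenate_genes([a, b])
        assert cat.n_codons == 5
        assert cat.genes == [("g1", (0, 2)), ("g2", (2, 5))]

    def test_single_gene_identity(self):
        a = read_alignment(">x\nATGGCC\n>y\nATGGCC\n")
        assert concatenate_genes([a]) is a

    def test_disjoint_individuals_rejected(self):
        a = read_alignment(">x\nATG\n>y\nATG\n")
        b = read_alignment(">x\nTTT\n>z\nTTT\n")
        with pytest.raises(AlignmentError):
            concatenate_genes([a, b])


class TestDiversityTable:
    def test_min_individuals_filter_partitions_exactly(self):
        small = CodonAlignment("few", ["ATGGCC"] * 3, ["a", "b", "c"])
        big = CodonAlignment("many", ["ATGGCC"] * 4, list("abcd"))
        table, excl = sq.diversity_table([small, big])
        assert list(table["species"]) == ["many"]
        assert list(excl["species"]) == ["few"]
        assert list(excl["reason"]) == ["min-individuals"]
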