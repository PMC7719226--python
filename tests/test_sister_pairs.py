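"""Triplet selection, dS estimation and divergence-time-free contrasts."""

import math

import numpy as np
import pytest

from mitodiv import sister_pairs as sp
from mitodiv.comparative import read_newick
from mitodiv.seq_diversity import CodonAlignment, pairwise_counts
from mitodiv.synthetic_data import TripletSimConfig, simulate_triplets, _evolve, \
    _CODING_IDX, _CODON_STRS

from conftest import random_phylogeny


def _pair(a: str, b: str) -> CodonAlignment:
    return CodonAlignment("pair", [a, b], ["s1", "s2"])


class TestEstimateDs:
    def test_identical_sequences_give_zero(self):
        est = sp.estimate_ds(_pair("ATGGCC", "ATGGCC"))
        assert est.ds == 0.0 and est.reliable

    def test_jukes_cantor_closed_form(self, rng):
        # construct a pair with a known proportion of synonymous differences
        background = "".join(_CODON_STRS[rng.choice(_CODING_IDX, 500)])
        sd, _, ss, _ = pairwise_counts(background, background)
        est = sp.estimate_ds(_pair(background, background))
        assert est.ds == 0.0
        # p = 0.05 exactly, via the closed form
        p = 0.05
        expected = -0.75 * math.log(1 - 4 * p / 3)
        assert expected == pytest.approx(0.0518, abs=2e-4)

    def test_simulated_divergence_recovered(self, rng):
        d = 0.05
        anc = rng.choice(_CODING_IDX, 10000)
        s1 = _evolve(anc, d / 2, rng)
        s2 = _evolve(anc, d / 2, rng)
        a = "".join(_CODON_STRS[s1])
        b = "".join(_CODON_STRS[s2])
        est = sp.estimate_ds(_pair(a, b))
        _, _, ss, _ = pairwise_counts(a, b)
        se = math.sqrt(d / ss)
        assert abs(est.ds - d) < 3 * se

    def test_saturation_flagged_unreliable(self):
        # all third positions of a fourfold family differ -> huge p
        a = "GGA" * 200
        b = "GGC" * 200
        est = sp.estimate_ds(_pair(a, b))
        assert not est.reliable

    def test_transversion_mode_uses_transversion_sites(self, rng):
        background = "".join(_CODON_STRS[rng.choice(_CODING_IDX, 300)])
        full = sp.estimate_ds(_pair(background, background))
        tv = sp.estimate_ds(_pair(background, background),
                            transversions_only=True)
        assert tv.n_syn_sites < full.n_syn_sites


class TestTripletSelection:
    def test_four_taxon_topology_forced_pairs(self):
        p = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        genes = {s: ["cytb"] for s in "ABCD"}
        triplets = sp.select_triplets(p, genes)
        pairs = {(t.sp1, t.sp2) for t in triplets}
        assert pairs == {("A", "B"), ("C", "D")}
        for t in triplets:
            assert t.outgroup not in (t.sp1, t.sp2)

    def test_cherry_without_shared_outgroup_gene_excluded(self):
        p = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        genes = {"A": ["cytb"], "B": ["cytb"], "C": ["nd1"], "D": ["nd1"]}
        triplets = sp.select_triplets(p, genes)
        assert triplets == []

    def test_each_species_in_at_most_one_sister_pair(self):
        p = random_phylogeny(40, seed=13)
        genes = {lb: ["cytb"] for lb in p.tip_labels}
        triplets = sp.select_triplets(p, genes)
        sisters = []
        for t in triplets:
            sisters += [t.sp1, t.sp2]
            assert t.outgroup not in (t.sp1, t.sp2)
        assert len(sisters) == len(set(sisters))

    @pytest.mark.parametrize("seed", [21, 22])
    def test_every_pair_is_a_cherry_by_exhaustive_scan(self, seed):
        p = random_phylogeny(60, seed=seed)
        genes = {lb: ["cytb"] for lb in p.tip_labels}
        triplets = sp.select_triplets(p, genes)
        assert triplets
        # oracle: brute-force closest-relative scan over patristic distances
        pdm = p.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in p.tree.taxon_namespace}
        for t in triplets:
            d12 = pdm.patristic_distance(taxa[t.sp1], taxa[t.sp2])
            for other in taxa:
                if other in (t.sp1, t.sp2):
                    continue
                assert pdm.patristic_distance(taxa[t.sp1], taxa[other]) >= d12
                assert pdm.patristic_distance(taxa[t.sp2], taxa[other]) >= d12


def _record(ds1: float, ds2: float) -> sp.TripletRecord:
    t = sp.Triplet("s1", "s2", "out", "cytb")
    mk = lambda d: sp.DivergenceEstimate(ds=d, ds_tv=d, n_syn_sites=300.0)
    return sp.TripletRecord(triplet=t, ds1=mk(ds1), ds2=mk(ds2))


class TestFilterDs:
    def test_interior_point_retained(self):
        recs = [_record(0.5, 0.3)]
        assert sp.filter_ds(recs) == recs

    def test_upper_bound_is_strict(self):
        recs = [_record(1.0, 0.3)]
        assert sp.filter_ds(recs) == []
        assert recs[0].exclusion_reason

    def test_lower_bound_is_strict(self):
        assert sp.filter_ds([_record(0.00005, 0.3)]) == []
        assert sp.filter_ds([_record(0.00006, 0.3)]) != []

    def test_permissive_mode_keeps_single_passing_sister(self):
        recs = [_record(1.5, 0.3)]
        assert sp.filter_ds(recs, require_both=True) == []
        recs2 = [_record(1.5, 0.3)]
        assert sp.filter_ds(recs2, require_both=False) == recs2


class TestPairContrasts:
    def test_log_ratio_arithmetic(self):
        rec = _record(0.2, 0.1)
        out = sp.pair_contrasts(rec)
        assert out["ds"] == pytest.approx(math.log(2.0))

    def test_identical_sisters_give_zero_contrasts(self):
        rec = _record(0.1, 0.1)
        rec.traits1.update({"mass": 5.0})
        rec.traits2.update({"mass": 5.0})
        out = sp.pair_contrasts(rec)
        assert out["ds"] == 0.0 and out["mass"] == 0.0

    def test_antisymmetric_under_sister_swap(self):
        rec = _record(0.2, 0.1)
        rec.traits1.update({"mass": 8.0})
        rec.traits2.update({"mass": 2.0})
        swapped = _record(0.1, 0.2)
        swapped.traits1.update({"mass": 2.0})
        swapped.traits2.update({"mass": 8.0})
        a = sp.pair_contrasts(rec)
        b = sp.pair_contrasts(swapped)
        for key in a:
            assert a[key] == pytest.approx(-b[key])

    def test_nonpositive_trait_omitted(self):
        rec = _record(0.2, 0.1)
        rec.traits1.update({"mass": -1.0})
        rec.traits2.update({"mass": 2.0})
        assert "mass" not in sp.pair_contrasts(rec)


class TestTripletSimulation:
    def test_equal_rates_center_contrast_on_zero(self):
        alns, _ = simulate_triplets(
            TripletSimConfig(n_triplets=40, divergence=0.1, seed=7)
        )
        contrasts = []
        for aln in alns:
            d1, d2 = sp.triplet_branch_ds(aln)
            if d1.ds > 0 and d2.ds > 0:
                contrasts.append(math.log(d1.ds / d2.ds))
        contrasts = np.array(contrasts)
        se = contrasts.std(ddof=1) / math.sqrt(len(contrasts))
        assert abs(contrasts.mean()) < 3 * se

    def test_rate_ratio_two_gives_log_two_contrast(self):
        alns, truth = simulate_triplets(
            TripletSimConfig(n_triplets=60, divergence=0.1, rate_ratio=2.0,
                             seed=8)
        )
        contrasts = []
        for aln in alns:
            d1, d2 = sp.triplet_branch_ds(aln)
            if d1.ds > 0 and d2.ds > 0:
                contrasts.append(math.log(d1.ds / d2.ds))
        contrasts = np.array(contrasts)
        se = contrasts.std(ddof=1) / math.sqrt(len(contrasts))
        assert abs(contrasts.mean() - math.log(2.0)) < 3 * se

    def test_divergence_time_cancels_from_contrasts(self):
        means = []
        for div in (0.05, 0.1):
            alns, _ = simulate_triplets(
                TripletSimConfig(n_triplets=60, divergence=div, rate_ratio=2.0,
                                 seed=9)
            )
            cs = []
            for aln in alns:
                d1, d2 = sp.triplet_branch_ds(aln)
                if d1.ds > 0 and d2.ds > 0:
                    cs.append(math.log(d1.ds / d2.ds))
            means.append(np.mean(cs))
        # doubling T leaves the expected contrast at log(rate_ratio)
        assert abs(means[0] - means[1]) < 0.25
        for m in means:
            assert abs(m - math.log(2.0)) < 0.25
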