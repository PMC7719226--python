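"""Trees, contrasts and Pagel's lambda against GLS and grid oracles."""

import math

import numpy as np
import pytest

from mitodiv import comparative
from mitodiv.comparative import (
    TreeError,
    independent_contrasts,
    pagel_lambda,
    read_newick,
)
from mitodiv.comparative import _profile_loglik

from conftest import random_phylogeny


class TestReadNewick:
    def test_minimal_two_tip_tree(self):
        p = read_newick("(A:1,B:1);")
        assert p.n_tips == 2
        labels, C = p.vcv()
        assert np.allclose(np.diag(C), 1.0)
        assert C[0, 1] == 0.0

    def test_ultrametric_three_tip(self):
        p = read_newick("((A:1,B:1):1,C:2);")
        _, C = p.vcv()
        assert np.allclose(np.diag(C), 2.0)

    def test_polytomy_resolved_to_zero_length_binary(self):
        p = read_newick("(A:1,B:1,C:1);")
        for node in p.tree.preorder_node_iter():
            assert len(node.child_nodes()) in (0, 2)
        # total tree length unchanged by resolution
        total = sum(
            e.length for e in p.tree.preorder_edge_iter() if e.length
        )
        assert total == pytest.approx(3.0)

    def test_missing_branch_length_rejected(self):
        with pytest.raises(TreeError):
            read_newick("(A:1,B);")

    def test_malformed_text_rejected(self):
        with pytest.raises(TreeError):
            read_newick("not a tree at all (((")

    def test_underscores_preserved_in_labels(self):
        p = read_newick("(Mus_musculus:1,Rattus_rattus:1);")
        assert "Mus_musculus" in p.tip_labels


class TestIndependentContrasts:
    def test_two_tip_closed_form(self):
        p = read_newick("(A:1,B:1);")
        cs = independent_contrasts(p, {"A": 3.0, "B": 1.0})
        assert len(cs.contrasts) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(2 / math.sqrt(2))

    def test_constant_trait_gives_zero_contrasts(self):
        p = random_phylogeny(12, seed=3)
        trait = {lb: 7.5 for lb in p.tip_labels}
        cs = independent_contrasts(p, trait)
        assert np.allclose(cs.contrasts, 0.0)

    def test_contrast_count_is_tips_minus_one(self):
        for n in (2, 5, 9, 17):
            p = random_phylogeny(n, seed=n)
            trait = {lb: float(i) for i, lb in enumerate(p.tip_labels)}
            cs = independent_contrasts(p, trait)
            assert len(cs.contrasts) == n - 1

    def test_missing_trait_tips_pruned_first(self):
        p = random_phylogeny(8, seed=1)
        trait = {lb: float(i) for i, lb in enumerate(p.tip_labels)}
        dropped_tip = p.tip_labels[0]
        del trait[dropped_tip]
        cs = independent_contrasts(p, trait)
        assert len(cs.contrasts) == 6
        assert dropped_tip in cs.dropped

    def test_nonpositive_trait_dropped_under_log(self):
        p = random_phylogeny(6, seed=2)
        trait = {lb: float(i + 1) for i, lb in enumerate(p.tip_labels)}
        trait[p.tip_labels[2]] = -1.0
        cs = independent_contrasts(p, trait, log_transform=True)
        assert len(cs.contrasts) == 4

    @pytest.mark.parametrize("seed", [11, 29, 53, 87])
    def test_sum_of_squares_matches_gls_whitening_oracle(self, seed):
        """Contrasts carry the same REML quadratic form as GLS whitening."""
        rng = np.random.default_rng(seed)
        p = random_phylogeny(int(rng.integers(4, 9)), seed=seed)
        labels, C = p.vcv()
        x = rng.normal(size=len(labels)) * 3.0
        trait = dict(zip(labels, x))
        cs = independent_contrasts(p, trait)
        Ci = np.linalg.inv(C)
        ones = np.ones(len(labels))
        mu = (ones @ Ci @ x) / (ones @ Ci @ ones)
        ss_gls = float((x - mu) @ Ci @ (x - mu))
        assert np.sum(cs.contrasts**2) == pytest.approx(ss_gls, rel=1e-8)

    def test_child_swap_flips_contrast_signs_only(self):
        p1 = random_phylogeny(10, seed=5)
        p2 = random_phylogeny(10, seed=5)
        for node in p2.tree.preorder_internal_node_iter():
            kids = node.child_nodes()
            node.set_child_nodes(list(reversed(kids)))
        trait = {lb: float(i) * 1.3 for i, lb in enumerate(sorted(p1.tip_labels))}
        c1 = np.sort(np.abs(independent_contrasts(p1, trait).contrasts))
        c2 = np.sort(np.abs(independent_contrasts(p2, trait).contrasts))
        assert np.allclose(c1, c2)


def _simulate_lambda_trait(C, lam, rng, sigma=1.0):
    V = lam * C + (1 - lam) * np.diag(np.diag(C))
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(C)))
    return sigma * (L @ rng.standard_normal(len(C)))


class TestPagelLambda:
    def test_ml_is_at_least_as_good_as_boundaries(self):
        p = random_phylogeny(30, seed=9)
        labels, C = p.vcv()
        rng = np.random.default_rng(0)
        trait = dict(zip(labels, _simulate_lambda_trait(C, 0.6, rng)))
        fit = pagel_lambda(p, trait)
        x = np.array([trait[lb] for lb in labels])
        assert fit.logL_at_hat >= fit.logL_at_zero - 1e-9
        assert fit.logL_at_hat >= _profile_loglik(1.0, x, C) - 1e-9
        assert 0.0 <= fit.lambda_hat <= 1.0
        assert 0.0 <= fit.lrt_p <= 1.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_optimizer_matches_grid_scan_oracle(self, seed):
        p = random_phylogeny(40, seed=seed + 100)
        labels, C = p.vcv()
        rng = np.random.default_rng(seed)
        trait = dict(zip(labels, _simulate_lambda_trait(C, 0.5, rng)))
        fit = pagel_lambda(p, trait)
        x = np.array([trait[lb] for lb in labels])
        grid = np.arange(0.0, 1.0001, 0.001)
        ll = [_profile_loglik(g, x, C) for g in grid]
        assert abs(fit.lambda_hat - grid[int(np.argmax(ll))]) <= 0.005

    def test_independent_tips_yield_lambda_near_zero(self):
        p = random_phylogeny(50, seed=77)
        rng = np.random.default_rng(4)
        hats, ps = [], []
        for _ in range(20):
            trait = dict(zip(p.tip_labels, rng.normal(size=50)))
            fit = pagel_lambda(p, trait)
            hats.append(fit.lambda_hat)
            ps.append(fit.lrt_p)
        assert np.mean(hats) < 0.25
        # no signal: the LRT should mostly be non-significant
        assert np.mean(np.array(ps) < 0.05) < 0.5

    def test_brownian_trait_pushes_lambda_to_upper_bound(self):
        p = random_phylogeny(50, seed=78)
        labels, C = p.vcv()
        rng = np.random.default_rng(5)
        hats = []
        for _ in range(10):
            trait = dict(zip(labels, _simulate_lambda_trait(C, 1.0, rng)))
            hats.append(pagel_lambda(p, trait).lambda_hat)
        assert np.mean(hats) > 0.85

    def test_duplicate_zero_distance_tips_named_in_error(self):
        p = read_newick("((A:0.0,B:0.0):1,(C:1,D:1):0.0);")
        trait = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        with pytest.raises(TreeError, match="A.*B|B.*A"):
            pagel_lambda(p, trait)

    def test_requires_four_tips(self):
        p = read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(TreeError):
            pagel_lambda(p, {"A": 1.0, "B": 2.0, "C": 3.0})
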