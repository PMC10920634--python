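"""Supervised admixture EM, Nei distances, NJ trees, bootstrap support."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from paleocacao.popgen import (
    IneligibleItemError,
    admixture_em,
    ancestry_report,
    bootstrap_support,
    dissimilarity_matrix,
    group_mean_genotypes,
    item_group_nei,
    neighbor_joining,
    nei_distance,
)
from paleocacao.simulate import build_panel, sample_admixed_genotype

from _oracles import random_additive_tree


def genotype_mapping(panel, dosage_vector):
    return {l.id: d / 2 for l, d in zip(panel.loci, dosage_vector)}


@pytest.fixture(scope="module")
def panel500():
    return build_panel(n_groups=11, n_loci=500, divergence=0.15, seed=60)


class TestAdmixtureEM:
    def test_single_source_recovered(self, panel500):
        recov = []
        for seed in range(10):
            k = seed % 11
            g = sample_admixed_genotype(panel500, np.eye(11)[k], seed=seed)
            est = admixture_em(genotype_mapping(panel500, g), panel500, flag_ambiguous=False)
            assert int(np.argmax(est.q)) == k
            recov.append(est.q[k])
        # the MLE concentrates on the true source: high on average, never
        # below 0.8 even for unlucky genotype draws
        assert np.mean(recov) >= 0.9
        assert min(recov) >= 0.8

    def test_fifty_fifty_hybrid_recovered(self, panel500):
        q_true = np.zeros(11)
        q_true[[2, 7]] = 0.5
        devs = []
        for seed in range(5):
            g = sample_admixed_genotype(panel500, q_true, seed=100 + seed)
            est = admixture_em(genotype_mapping(panel500, g), panel500, flag_ambiguous=False)
            # the two sources carry essentially all the mass on every draw;
            # the split between them wobbles with the genotype sample
            assert est.q[2] + est.q[7] >= 0.9
            devs.append(max(abs(est.q[2] - 0.5), abs(est.q[7] - 0.5)))
            assert devs[-1] <= 0.2
        assert np.mean(devs) <= 0.1

    def test_loglik_monotone_and_reported(self, panel500):
        g = sample_admixed_genotype(panel500, np.full(11, 1 / 11), seed=61)
        est = admixture_em(genotype_mapping(panel500, g), panel500, flag_ambiguous=False)
        assert (np.diff(est.ll_history) >= -1e-8).all()
        assert np.isfinite(est.loglik)
        assert est.q.sum() == pytest.approx(1.0, abs=1e-9)
        assert (est.q >= 0).all()

    def test_initialization_independence(self, panel500):
        g = sample_admixed_genotype(panel500, np.eye(11)[3], seed=62)
        gm = genotype_mapping(panel500, g)
        rng = np.random.default_rng(63)
        qs = []
        for _ in range(3):
            q0 = rng.dirichlet(np.ones(11))
            est = admixture_em(
                gm, panel500, q0=q0, tol=1e-12, max_iter=100000, flag_ambiguous=False
            )
            qs.append(est.q)
        assert np.abs(qs[0] - qs[1]).max() < 1e-4
        assert np.abs(qs[0] - qs[2]).max() < 1e-4

    def test_identical_groups_flagged_ambiguous(self):
        panel = build_panel(n_groups=4, n_loci=300, divergence=0.2, seed=64)
        panel.freqs[:, 1] = panel.freqs[:, 0]  # duplicate group B := A
        g = sample_admixed_genotype(panel, [1.0, 0, 0, 0], seed=65)
        est = admixture_em(genotype_mapping(panel, g), panel)
        pair = (panel.groups[0], panel.groups[1])
        assert pair in est.ambiguous_pairs or pair[::-1] in est.ambiguous_pairs
        assert est.q[0] + est.q[1] >= 0.9  # the sum is identified

    def test_locus_floor_enforced(self, panel500):
        g = sample_admixed_genotype(panel500, np.eye(11)[0], seed=66)
        gm = dict(list(genotype_mapping(panel500, g).items())[:19])
        with pytest.raises(IneligibleItemError):
            admixture_em(gm, panel500)

    def test_parameter_recovery_error_bounded(self, panel500):
        """Random admixtures over 100-500 loci: mean |q_hat - q| <= 0.08."""
        rng = np.random.default_rng(67)
        errs = []
        for _ in range(15):
            q_true = rng.dirichlet(np.ones(11) * 0.5)
            g = sample_admixed_genotype(panel500, q_true, seed=rng)
            n_loci = int(rng.integers(100, 501))
            keep = rng.choice(500, size=n_loci, replace=False)
            gm = {panel500.loci[i].id: g[i] / 2 for i in keep}
            est = admixture_em(gm, panel500, flag_ambiguous=False)
            errs.append(np.abs(est.q - q_true).mean())
        assert np.mean(errs) <= 0.08


class TestNeiDistance:
    def test_identical_profiles_zero(self):
        p = np.array([0.3, 0.7, 0.5])
        assert nei_distance(p, p, 10**6, 10**6) == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_two_locus_oracle(self):
        # hand-evaluated large-n limit: J_x, J_y, J_xy from the definitions
        px, py = np.array([0.2, 0.8]), np.array([0.9, 0.1])
        jx = ((0.2**2 + 0.8**2) + (0.8**2 + 0.2**2)) / 2
        jy = ((0.9**2 + 0.1**2) + (0.1**2 + 0.9**2)) / 2
        jxy = ((0.2 * 0.9 + 0.8 * 0.1) + (0.8 * 0.1 + 0.2 * 0.9)) / 2
        expected = -np.log(jxy / np.sqrt(jx * jy))
        assert nei_distance(px, py, 10**7, 10**7) == pytest.approx(expected, abs=1e-5)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(68)
        px, py = rng.random(50), rng.random(50)
        assert nei_distance(px, py, 8, 5) == nei_distance(py, px, 5, 8)

    def test_resampled_halves_of_one_group_near_zero(self):
        panel = build_panel(n_groups=2, n_loci=400, divergence=0.3, seed=69)
        rng = np.random.default_rng(70)
        g = np.array([rng.binomial(2, panel.freqs[:, 0]) for _ in range(16)])
        d = nei_distance(g[:8].mean(0) / 2, g[8:].mean(0) / 2, 8, 8)
        assert d < 0.02

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            nei_distance([], [], 5, 5)
        with pytest.raises(ValueError):
            nei_distance([0.5], [0.5], 0, 5)


class TestDissimilarity:
    def test_identical_and_opposite(self):
        g = pd.DataFrame(
            [[0.0] * 10, [0.0] * 10, [1.0] * 10],
            index=["a", "b", "c"],
        )
        dm = dissimilarity_matrix(g)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0

    def test_bruteforce_fixture(self):
        rng = np.random.default_rng(71)
        X = rng.choice([0.0, 0.5, 1.0], size=(5, 10))
        g = pd.DataFrame(X, index=list("abcde"))
        dm = dissimilarity_matrix(g)
        for i in range(5):
            for j in range(5):
                expected = np.mean([abs(X[i, l] - X[j, l]) for l in range(10)])
                assert dm[i, j] == pytest.approx(expected)

    def test_missing_pair_errors(self):
        g = pd.DataFrame(
            [[0.0, np.nan], [np.nan, 1.0], [0.5, 0.5]], index=["a", "b", "c"]
        )
        with pytest.raises(ValueError):
            dissimilarity_matrix(g)


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
        dm = DistanceMatrix(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
            ["A", "B", "C", "D"],
        )
        tree = neighbor_joining(dm)
        recovered = tree.tip_tip_distances(["A", "B", "C", "D"])
        for i in "ABCD":
            for j in "ABCD":
                assert recovered[i, j] == pytest.approx(dm[i, j], abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_additive_trees_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        labels, D, _ = random_additive_tree(n, rng)
        tree = neighbor_joining(DistanceMatrix(D, labels))
        rec = tree.tip_tip_distances(labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert rec[a, b] == pytest.approx(D[labels.index(a), labels.index(b)], abs=1e-6)

    def test_star_matrix_accepted(self):
        dm = DistanceMatrix(2 * (1 - np.eye(4)), list("ABCD"))
        tree = neighbor_joining(dm)
        assert {t.name for t in tree.tips()} == set("ABCD")
        assert min(n.length or 0 for n in tree.non_tips()) >= 0

    def test_leaf_set_preserved(self, cacao_panel):
        g = group_mean_genotypes(cacao_panel).iloc[:10]
        tree = neighbor_joining(dissimilarity_matrix(g))
        assert {t.name for t in tree.tips()} == set(g.index)


class TestBootstrap:
    def test_supports_bounded_and_deterministic(self, cacao_panel):
        g = group_mean_genotypes(cacao_panel).iloc[:12, :100]
        a = bootstrap_support(g, n_replicates=25, seed=7)
        b = bootstrap_support(g, n_replicates=25, seed=7)
        assert a.supports == b.supports
        assert all(0 <= v <= 100 for v in a.supports.values())

    def test_zero_replicates_gives_bare_tree(self, cacao_panel):
        g = group_mean_genotypes(cacao_panel).iloc[:8, :50]
        res = bootstrap_support(g, n_replicates=0)
        assert res.supports is None and res.tree is not None

    def test_separated_groups_get_high_support(self):
        """Cleanly diverged groups form clades with near-full support."""
        panel = build_panel(
            n_groups=11, n_loci=460, divergence=0.2, seed=72,
            group_sizes=[2] * 11,
        )
        g = group_mean_genotypes(panel)
        res = bootstrap_support(g, n_replicates=150, seed=73)
        for k, name in enumerate(panel.groups):
            pair = frozenset(a for a, grp in zip(panel.acc_ids, panel.acc_groups) if grp == k)
            assert res.supports.get(pair, 0.0) >= 95.0


class TestReporting:
    def test_single_source_item_concordant(self, panel500):
        g = sample_admixed_genotype(panel500, np.eye(11)[4], seed=74)
        gm = genotype_mapping(panel500, g)
        from paleocacao.snpcall import ItemGenotype

        item = ItemGenotype("it1", gm, {})
        est = admixture_em(item, panel500, flag_ambiguous=False)
        nei = item_group_nei(item, panel500)
        report, excluded = ancestry_report([est], {"it1": nei})
        assert excluded == []
        row = report.iloc[0]
        assert row.admixture_top_group == panel500.groups[4]
        assert row.concordant

    def test_items_below_locus_floor_listed_separately(self, panel500):
        g = sample_admixed_genotype(panel500, np.eye(11)[0], seed=75)
        gm = dict(list(genotype_mapping(panel500, g).items())[:19])
        from paleocacao.popgen import AncestryEstimate

        est = AncestryEstimate(
            "tiny", list(panel500.groups), np.full(11, 1 / 11), -1.0, 19, 1, np.array([-1.0])
        )
        report, excluded = ancestry_report([est], {})
        assert excluded == ["tiny"] and report.empty
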