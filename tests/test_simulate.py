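"""Synthetic data: exact tables, noise, multinomial sampling, gene trees."""

import numpy as np
import pytest

from cfdiamond.cf_data import cfs_from_gene_trees
from cfdiamond.coalescent import NetworkParameters, cf_system, evaluate_cfs
from cfdiamond.network import make_partition
from cfdiamond.simulate import (
    SimulationConfig,
    perturb_gaussian,
    sample_gene_tree_quartets,
    simulate_gene_trees,
    true_cf_table,
)

CF_COLS = ["CF12_34", "CF13_24", "CF14_23"]


class TestTrueCFTable:
    def test_reference_network_has_70_complete_rows(self, n2222_table):
        assert len(n2222_table) == 70
        sums = n2222_table.df[CF_COLS].to_numpy().sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_cherry_cherry_row_value(self, n2222_table):
        row = n2222_table.quad_row(("E", "F", "G", "H"))  # class (0,0,2,2)
        assert row[0] == pytest.approx(0.966809, abs=5e-7)
        assert row[1] == row[2] == pytest.approx(np.exp(-3.0) / 3, abs=1e-12)

    def test_pendant_lengths_never_matter(self, n2222):
        """Clade stems of singleton clades are pendant and leave CFs unchanged."""
        p = make_partition(["A"], ["B"], ["C"], ["D", "E"])
        t1 = true_cf_table(p, NetworkParameters(t0=0.1, t1=9.0, t2=0.2))
        t2 = true_cf_table(p, NetworkParameters(t0=5.0, t1=0.3, t2=7.0))
        assert np.allclose(t1.df[CF_COLS].to_numpy(),
                           t2.df[CF_COLS].to_numpy(), atol=1e-15)

    def test_three_taxon_clade_rows(self):
        """A 9-taxon network's table is complete, including quartets with
        three taxa from the big clade (tree CFs from the caterpillar)."""
        truth = make_partition(["A", "B"], ["C", "D"], ["E", "F"],
                               ["G", "H", "I"])
        table = true_cf_table(truth)
        assert len(table) == 126  # C(9,4)
        row = table.quad_row(("A", "G", "H", "I"))
        major = 1 - 2 / 3 * np.exp(-1.0)  # caterpillar internal branch 1.0
        # the GH|AI split pairs A with I: canonical slot CF14_23
        assert row[2] == pytest.approx(major, abs=1e-12)
        assert row[0] == row[1] == pytest.approx(np.exp(-1.0) / 3, abs=1e-12)


class TestPerturbGaussian:
    def test_sigma_zero_is_identity(self, n2222_table):
        out = perturb_gaussian(n2222_table, 0.0, seed=1)
        assert np.allclose(out.df[CF_COLS].to_numpy(),
                           n2222_table.df[CF_COLS].to_numpy(), atol=0)

    def test_reproducible_given_seed(self, n2222_table):
        a = perturb_gaussian(n2222_table, 5e-4, seed=9).df[CF_COLS].to_numpy()
        b = perturb_gaussian(n2222_table, 5e-4, seed=9).df[CF_COLS].to_numpy()
        assert np.array_equal(a, b)

    def test_empirical_sd_matches_sigma(self, n2222_table):
        sigma = 5e-4
        out = perturb_gaussian(n2222_table, sigma, seed=4)
        delta = out.df[CF_COLS].to_numpy() - n2222_table.df[CF_COLS].to_numpy()
        assert np.std(delta) == pytest.approx(sigma, rel=0.10)

    def test_renormalized_rows_sum_to_one(self, n2222_table):
        out = perturb_gaussian(n2222_table, 1e-2, seed=5, renormalize=True)
        sums = out.df[CF_COLS].to_numpy().sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_config_validation(self, n2222):
        with pytest.raises(ValueError):
            SimulationConfig(partition=n2222, sigma=-1.0)


class TestMultinomialQuartets:
    def test_single_gene_rows_are_one_hot(self, n2222):
        t = sample_gene_tree_quartets(n2222, ngenes=1, seed=2)
        vals = t.df[CF_COLS].to_numpy()
        assert np.all(np.sort(vals, axis=1)[:, :2] == 0.0)
        assert np.all(vals.max(axis=1) == 1.0)

    def test_reproducible_given_seed(self, n2222):
        a = sample_gene_tree_quartets(n2222, ngenes=100, seed=6).df[CF_COLS]
        b = sample_gene_tree_quartets(n2222, ngenes=100, seed=6).df[CF_COLS]
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_law_of_large_numbers(self, n2222, n2222_table):
        t = sample_gene_tree_quartets(n2222, ngenes=1_000_000, seed=8)
        delta = t.df[CF_COLS].to_numpy() - n2222_table.df[CF_COLS].to_numpy()
        assert np.abs(delta).max() < 0.005


class TestGeneTreeSimulation:
    def test_output_is_valid_newick_with_expected_leaves(self, n2222):
        import dendropy

        trees = simulate_gene_trees(n2222, ngenes=20, seed=1)
        assert len(trees) == 20
        for nwk in trees[:5]:
            tree = dendropy.Tree.get(data=nwk, schema="newick")
            labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
            assert labels == set("ABCDEFGH")

    def test_reproducible_given_seed(self, n2222):
        assert simulate_gene_trees(n2222, ngenes=10, seed=3) == \
            simulate_gene_trees(n2222, ngenes=10, seed=3)

    def test_counted_cfs_match_exact_values(self, n2222, study_params):
        """Quartet frequencies from full gene trees agree with the CF
        polynomials within Monte-Carlo error (the oracle-agreement check)."""
        k = 10_000
        trees = simulate_gene_trees(n2222, study_params, ngenes=k, seed=12)
        counted = cfs_from_gene_trees(trees, taxa=list("ABCDEFGH"))
        exact = evaluate_cfs((2, 2, 2, 2), study_params)
        system = cf_system((2, 2, 2, 2))
        checks = {
            ("E", "F", "G", "H"): (0, 0, 2, 2),
            ("A", "C", "E", "G"): (1, 1, 1, 1),
            ("A", "B", "C", "D"): (2, 2, 0, 0),
            ("A", "B", "G", "H"): (2, 0, 0, 2),
        }
        for quad, cls in checks.items():
            obs = counted.quad_row(quad)
            i = system.a_index(cls, 1)
            exp = exact[i:i + 3]
            se = np.sqrt(exp * (1 - exp) / k)
            # slots 2/3 of these classes are exchangeable; compare sorted
            assert np.all(np.abs(np.sort(obs) - np.sort(exp)) <= 3 * se.max() + 1e-12)

    def test_gamma_zero_follows_minor_parent_only(self):
        """With gamma = 0 the hybrid clade always joins clade 2: CFs equal
        the displayed-tree values."""
        p = make_partition(["A", "B"], ["C", "D"], ["E", "F"], ["G", "H"])
        params = NetworkParameters(gamma=0.0)
        k = 4000
        trees = simulate_gene_trees(p, params, ngenes=k, seed=21)
        counted = cfs_from_gene_trees(trees, taxa=list("ABCDEFGH"))
        exact = evaluate_cfs((2, 2, 2, 2), params)
        system = cf_system((2, 2, 2, 2))
        quad, cls = ("A", "B", "E", "F"), (2, 0, 2, 0)
        obs = counted.quad_row(quad)
        exp = exact[system.a_index(cls, 1): system.a_index(cls, 1) + 3]
        se = np.sqrt(exp * (1 - exp) / k)
        assert np.all(np.abs(np.sort(obs) - np.sort(exp)) <= 4 * se.max() + 1e-12)

    def test_oversized_clades_rejected(self):
        p = make_partition(["A", "B", "C", "D"], ["E"], ["F"], ["G"])
        with pytest.raises(ValueError, match="three taxa"):
            simulate_gene_trees(p, ngenes=1, seed=0)
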