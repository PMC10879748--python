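"""The coalescent CF engine: closed forms, identities and the MC oracle."""

import itertools

import numpy as np
import pytest
import sympy as sp

from cfdiamond.coalescent import (
    NetworkParameters,
    PARAM_SYMBOLS,
    QuartetClassError,
    cf_polynomials,
    cf_system,
    class_slot_splits,
    evaluate_cfs,
    informative_classes,
    mc_quartet_cfs,
)

z0, z1, z2, z3, z01, z02, z13, z23, g = PARAM_SYMBOLS


class TestInformativeClasses:
    def test_reference_network_has_19(self):
        classes = informative_classes((2, 2, 2, 2))
        assert len(classes) == 19
        assert classes == sorted(classes)
        assert all(sum(c) == 4 and max(c) <= 2 for c in classes)

    def test_five_taxon_network_classes(self):
        assert informative_classes((1, 1, 1, 2)) == [
            (0, 1, 1, 2), (1, 0, 1, 2), (1, 1, 0, 2), (1, 1, 1, 1),
        ]

    def test_four_taxon_signature_single_class(self):
        assert informative_classes((1, 1, 1, 1)) == [(1, 1, 1, 1)]


class TestCFPolynomials:
    def test_cherry_cherry_closed_form(self):
        """The class (0,0,2,2) CFs: 1 - (2/3) z2 z23 z3 and two equal minors."""
        p1, p2, p3 = cf_polynomials((0, 0, 2, 2))
        assert sp.expand(p1 - (1 - sp.Rational(2, 3) * z2 * z23 * z3)) == 0
        assert sp.expand(p2 - sp.Rational(1, 3) * z2 * z23 * z3) == 0
        assert p2 == p3

    def test_all_singletons_closed_form(self):
        """Class (1,1,1,1): hybrid taxon joins clade 1 with probability gamma."""
        p1, _, _ = cf_polynomials((1, 1, 1, 1))
        expected = g * (1 - sp.Rational(2, 3) * z13) \
            + (1 - g) * sp.Rational(1, 3) * z23
        assert sp.expand(p1 - expected) == 0

    @pytest.mark.parametrize("cls", informative_classes((2, 2, 2, 2)))
    def test_triples_sum_to_one_symbolically(self, cls):
        assert sp.expand(sum(cf_polynomials(cls)) - 1) == 0

    @pytest.mark.parametrize("cls", [c for c in informative_classes((2, 2, 2, 2))
                                     if c[0] == 0])
    def test_classes_without_hybrid_clade_ignore_hybrid_parameters(self, cls):
        free = set().union(*(p.free_symbols for p in cf_polynomials(cls)))
        assert free.isdisjoint({g, z0, z01, z02})

    @pytest.mark.parametrize("cls", informative_classes((2, 2, 2, 2)))
    def test_minor_equality_iff_same_clade_pair(self, cls):
        _, p2, p3 = cf_polynomials(cls)
        if max(cls) == 2:
            assert sp.expand(p2 - p3) == 0
        else:
            assert sp.expand(p2 - p3) != 0

    def test_star_tree_limit_is_uniform(self):
        params = NetworkParameters(t0=0, t1=0, t2=0, t3=0, t01=0, t02=0,
                                   t13=0, t23=0, gamma=0.3)
        a = evaluate_cfs((2, 2, 2, 2), params)
        assert np.allclose(a, 1 / 3)

    def test_invalid_class_rejected(self):
        with pytest.raises(QuartetClassError):
            cf_polynomials((3, 1, 0, 0))
        with pytest.raises(QuartetClassError):
            cf_polynomials((1, 1, 1, 0))


class TestCFSystem:
    def test_reference_system_shape(self):
        system = cf_system((2, 2, 2, 2))
        assert len(system.polys) == 57
        assert len(system.parameter_symbols()) == 9

    def test_five_taxon_system_shape(self):
        assert len(cf_system((1, 1, 1, 2)).polys) == 12

    def test_numeric_triples_sum_to_one(self):
        params = NetworkParameters(t0=0.3, t1=1.7, t2=0.6, t3=2.2, t01=0.4,
                                   t02=1.1, t13=0.8, t23=0.5, gamma=0.41)
        a = evaluate_cfs((2, 2, 2, 2), params)
        assert a.shape == (57,)
        assert np.all((a > 0) & (a < 1))
        assert np.allclose(a.reshape(-1, 3).sum(axis=1), 1.0, atol=1e-12)

    def test_example_numeric_value(self, study_params):
        system = cf_system((2, 2, 2, 2))
        a = evaluate_cfs((2, 2, 2, 2), study_params)
        i = system.a_index((0, 0, 2, 2), 1)
        expected = 1 - 2 / 3 * np.exp(-3.0)
        assert a[i] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.966809, abs=5e-7)


def displayed_tree_cfs(cls, params: NetworkParameters, minor: bool):
    """Independent oracle: quartet CFs on the displayed tree via four-point.

    Deleting one hybrid edge makes the network a tree; leaves are placed at
    their clade junctions (pendant edges cancel in the four-point formula)
    and each split's internal length is (d(a,c)+d(b,d)-d(a,b)-d(c,d))/2.
    """
    import networkx as nx

    t = params
    G = nx.Graph()
    G.add_edge("J0", "h", weight=t.t0)
    G.add_edge("J1", "v1", weight=t.t1)
    G.add_edge("J2", "v2", weight=t.t2)
    G.add_edge("J3", "v3", weight=t.t3)
    G.add_edge("v1", "v3", weight=t.t13)
    G.add_edge("v2", "v3", weight=t.t23)
    if minor:
        G.add_edge("h", "v2", weight=t.t02)
    else:
        G.add_edge("h", "v1", weight=t.t01)
    place = []
    for clade, count in enumerate(cls):
        place.extend([f"J{clade}"] * count)
    d = dict(nx.all_pairs_dijkstra_path_length(G))

    def dist(i, j):
        return d[place[i]][place[j]]

    out = {}
    for k in (1, 2, 3):
        a, b = 0, k
        c, e = [x for x in range(4) if x not in (a, b)]
        T = (dist(a, c) + dist(b, e) - dist(a, b) - dist(c, e)) / 2
        out[k] = T
    best = max(out, key=out.get)
    T = max(out[best], 0.0)
    cfs = {}
    for k in (1, 2, 3):
        cfs[k] = 1 - 2 / 3 * np.exp(-T) if k == best and T > 1e-12 \
            else 1 / 3 * np.exp(-T)
    slots = class_slot_splits(cls)
    return np.array([cfs[k] for k in slots])


class TestDisplayedTreeLimit:
    """At gamma = 1 (or 0) the network CFs equal the displayed tree's."""

    @pytest.mark.parametrize("gamma, minor", [(1.0, False), (0.0, True)])
    @pytest.mark.parametrize("cls", informative_classes((2, 2, 2, 2)))
    def test_gamma_limits(self, cls, gamma, minor):
        params = NetworkParameters(t0=0.7, t1=1.3, t2=0.5, t3=1.9, t01=0.6,
                                   t02=1.4, t13=0.9, t23=1.2, gamma=gamma)
        fn = sp.lambdify(PARAM_SYMBOLS, list(cf_polynomials(cls)))
        engine = np.array(fn(*params.z_values()), dtype=float)
        oracle = displayed_tree_cfs(cls, params, minor=minor)
        assert np.allclose(engine, oracle, atol=1e-12)


class TestMonteCarloOracle:
    """Coalescent simulation agrees with the symbolic CF polynomials."""

    NSIM = 40_000

    @pytest.mark.parametrize("cls", [
        (0, 0, 2, 2), (1, 1, 1, 1), (2, 2, 0, 0), (2, 0, 1, 1),
        (1, 0, 1, 2), (2, 0, 0, 2),
    ])
    def test_agreement_within_three_standard_errors(self, cls):
        params = NetworkParameters(t0=0.8, t1=1.1, t2=0.7, t3=1.4, t01=0.9,
                                   t02=0.6, t13=1.2, t23=0.8, gamma=0.35)
        fn = sp.lambdify(PARAM_SYMBOLS, list(cf_polynomials(cls)))
        exact = np.array(fn(*params.z_values()), dtype=float)
        mc = np.array(mc_quartet_cfs(cls, params, nsim=self.NSIM, seed=2024))
        se = np.sqrt(exact * (1 - exact) / self.NSIM)
        assert np.all(np.abs(mc - exact) <= 3 * se + 1e-12)

    def test_single_draw_is_one_hot(self):
        triple = mc_quartet_cfs((0, 0, 2, 2), NetworkParameters(), nsim=1, seed=5)
        assert sorted(triple) == [0.0, 0.0, 1.0]

    def test_reproducible_given_seed(self):
        params = NetworkParameters()
        a = mc_quartet_cfs((1, 1, 1, 1), params, nsim=500, seed=11)
        b = mc_quartet_cfs((1, 1, 1, 1), params, nsim=500, seed=11)
        assert a == b
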