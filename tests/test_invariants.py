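"""Invariant derivation, soundness, symmetry, the printed basis, and caching."""

import json

import numpy as np
import pytest

from cfdiamond.coalescent import evaluate_cfs_at, cf_system
from cfdiamond.invariants import (
    InvariantCacheError,
    derive_invariants,
    evaluate_printed_1112,
    get_invariants,
    load_invariants,
    permute_to_swapped,
    resolve_printed_1112_indices,
    store_invariants,
    swap_signature,
    trivial_invariants,
)
from cfdiamond.network import supported_signatures

from conftest import random_z_gamma


class TestTrivialInvariants:
    def test_five_taxon_network_has_seven(self):
        inv = trivial_invariants((1, 1, 1, 2))
        assert inv.n_trivial == 7
        assert len(inv.trivial_a_polys()) == 7

    def test_class_1111_contributes_no_minor_equality(self):
        # 4 classes, one of them (1,1,1,1): 4 sum-to-one + 3 minor equalities
        classes = cf_system((1, 1, 1, 2)).classes
        assert sum(1 for c in classes if max(c) == 2) == 3

    def test_vanish_on_model_cfs(self):
        inv = trivial_invariants((2, 2, 2, 2))
        zg = random_z_gamma(50, np.random.default_rng(0))
        vals = inv.evaluate(evaluate_cfs_at((2, 2, 2, 2), zg))
        assert np.abs(vals).max() < 1e-12


class TestDerivedInvariants:
    @pytest.mark.parametrize("sig", supported_signatures())
    def test_soundness_on_1000_random_draws(self, sig):
        """Every invariant vanishes on model CFs for any parameters."""
        inv = get_invariants(sig)
        zg = random_z_gamma(1000, np.random.default_rng(123))
        vals = inv.evaluate(evaluate_cfs_at(sig, zg))
        assert np.abs(vals).max() < 1e-10

    @pytest.mark.parametrize("sig", supported_signatures())
    def test_nontrivial_invariants_exist(self, sig):
        """All signatures except (2,1,1,1), whose CF image is full-dimensional."""
        inv = get_invariants(sig)
        if sig == (2, 1, 1, 1):
            assert inv.n_nontrivial == 0
        else:
            assert inv.n_nontrivial >= 1

    def test_lifted_a_polynomials_vanish_symbolically(self):
        """Substituting the CF polynomials into a lifted invariant gives zero."""
        import sympy as sp

        inv = get_invariants((1, 1, 1, 2))
        system = cf_system((1, 1, 1, 2))
        subs = dict(zip(inv.a_symbols(), system.polys))
        for poly in inv.nontrivial_a_polys():
            assert sp.expand(poly.subs(subs)) == 0

    def test_off_variety_vector_is_detected(self):
        """A perturbed CF vector violates at least one nontrivial invariant."""
        inv = get_invariants((1, 1, 1, 2))
        zg = random_z_gamma(1, np.random.default_rng(7))
        a = evaluate_cfs_at((1, 1, 1, 2), zg)[0]
        a = a.copy()
        a[5] += 0.1
        vals = inv.evaluate(a)
        assert np.abs(vals[7:]).max() > 1e-6  # beyond the 7 trivial ones

    def test_discrimination_of_wrong_partitions(self, n2222):
        """CFs from the true network score positively on wrong partitions."""
        from cfdiamond.cf_data import map_to_a_vector
        from cfdiamond.inference import invariant_score
        from cfdiamond.network import make_partition, symmetric_partner
        from cfdiamond.coalescent import NetworkParameters
        from cfdiamond.simulate import true_cf_table

        wrong = [
            make_partition(["A", "C"], ["B", "D"], ["E", "F"], ["G", "H"]),
            make_partition(["G", "H"], ["C", "D"], ["E", "F"], ["A", "B"]),
            make_partition(["A", "B"], ["C", "D"], ["G", "H"], ["E", "F"]),
        ]
        inv = get_invariants((2, 2, 2, 2))
        rng = np.random.default_rng(99)
        hits = 0
        total = 0
        for _ in range(20):
            t = rng.uniform(0.05, 3.0, size=8)
            gam = rng.uniform(0.05, 0.95)
            params = NetworkParameters(*t, gamma=gam)
            table = true_cf_table(
                make_partition(["A", "B"], ["C", "D"], ["E", "F"], ["G", "H"]),
                params,
            )
            for p in wrong:
                total += 1
                if invariant_score(map_to_a_vector(table, p), inv) > 1e-6:
                    hits += 1
        assert hits / total >= 0.95

    def test_swapped_signature_is_permuted_image(self):
        """The swap of clades 1 and 2 is a model symmetry of the invariants."""
        inv = get_invariants((2, 1, 2, 2))
        mapped = permute_to_swapped(inv)
        assert mapped.signature == (2, 2, 1, 2)
        zg = random_z_gamma(100, np.random.default_rng(42))
        vals = mapped.evaluate(evaluate_cfs_at((2, 2, 1, 2), zg))
        assert np.abs(vals).max() < 1e-10

    def test_self_symmetric_sets_closed_under_swap(self):
        """Swapping clades 1 and 2 permutes the invariant set onto itself."""
        inv = get_invariants((2, 2, 2, 2))
        perm = permute_to_swapped(inv)
        assert set(perm.polys) == set(inv.polys)

    def test_elimination_route_agrees_with_interpolation(self):
        """Groebner elimination generators vanish and are in the derived span."""
        inv_elim = derive_invariants((1, 1, 1, 2), method="symbolic-elimination")
        assert inv_elim.n_nontrivial >= 1
        zg = random_z_gamma(200, np.random.default_rng(8))
        a = evaluate_cfs_at((1, 1, 1, 2), zg)
        assert np.abs(inv_elim.evaluate(a)).max() < 1e-10


class TestPrintedBasis:
    def test_resolution_structure(self):
        """The triple without a minor-equality relation is class (1,1,1,1)."""
        mapping = resolve_printed_1112_indices()
        assert mapping[28][0] == (1, 1, 1, 1)
        assert mapping[29][0] == (1, 1, 1, 1)
        assert mapping[30][0] == (1, 1, 1, 1)
        # majors of the pair classes map to slot 1
        for major_idx in (7, 22, 31):
            cls, slot = mapping[major_idx]
            assert max(cls) == 2 and slot == 1

    def test_all_ten_vanish_on_model_cfs(self):
        zg = random_z_gamma(100, np.random.default_rng(17))
        a = evaluate_cfs_at((1, 1, 1, 2), zg)
        vals = evaluate_printed_1112(a)
        assert vals.shape[0] == 10
        assert int(np.sum(np.abs(vals).max(axis=1) < 1e-8)) == 10

    def test_printed_polynomials_vanish_modulo_derived_set(self):
        """The derived set captures the printed relations: both vanish on
        100 random model samples while generic perturbations do not."""
        zg = random_z_gamma(100, np.random.default_rng(18))
        a = evaluate_cfs_at((1, 1, 1, 2), zg)
        derived = get_invariants((1, 1, 1, 2))
        assert np.abs(derived.evaluate(a)).max() < 1e-8
        assert np.abs(evaluate_printed_1112(a)).max() < 1e-8


class TestCache:
    def test_store_load_round_trip(self, tmp_path):
        inv = get_invariants((1, 2, 2, 1))
        path = tmp_path / "sig.json"
        store_invariants(inv, path)
        loaded = load_invariants((1, 2, 2, 1), path)
        assert loaded.polys == inv.polys
        assert loaded.provenance == inv.provenance

    def test_cache_shipped_for_all_15_signatures(self):
        from cfdiamond.invariants import cache_path

        for sig in supported_signatures():
            assert cache_path(sig).exists()

    def test_tampered_coefficient_detected(self, tmp_path):
        inv = get_invariants((1, 1, 2, 2))
        path = tmp_path / "sig.json"
        store_invariants(inv, path)
        payload = json.loads(path.read_text())
        payload["polys"][0][0][0] += 1
        path.write_text(json.dumps(payload))
        with pytest.raises(InvariantCacheError, match="checksum"):
            load_invariants((1, 1, 2, 2), path)

    def test_wrong_model_polynomials_fail_revalidation(self, tmp_path):
        inv = get_invariants((1, 1, 2, 2))
        path = tmp_path / "sig.json"
        # re-sign a corrupted payload so only re-validation can catch it
        from cfdiamond.invariants import _canonical_payload, _checksum

        coeff, idxs = inv.polys[0][0]
        bad_poly = ((coeff + 1, idxs),) + inv.polys[0][1:]
        corrupt = type(inv)(
            signature=inv.signature,
            polys=(bad_poly,) + inv.polys[1:],
            provenance=inv.provenance,
            max_degree=inv.max_degree,
        )
        payload = _canonical_payload(corrupt)
        payload["checksum"] = _checksum(dict(payload))
        path.write_text(json.dumps(payload))
        with pytest.raises(InvariantCacheError, match="vanish"):
            load_invariants((1, 1, 2, 2), path)
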