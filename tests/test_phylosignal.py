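"""Phylogenetic-signal machinery: pruning vs enumeration, rate fitting vs a
grid scan, delta behavior, permutation-test invariances."""

import itertools

import dendropy
import numpy as np
import pytest

from lbd_atlas import phylosignal as ps


def tree_from(newick: str) -> dendropy.Tree:
    return ps.prepare_tree(
        dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    )


def arrays_from(newick: str) -> ps.TreeArrays:
    return ps.TreeArrays(tree_from(newick).seed_node)


# ---------------------------------------------------------------------------
# Enumeration oracle: sum over all internal-state assignments

def _edges(arrays):
    out = []
    for i in range(arrays.n_nodes):
        kids = arrays.children[i]
        if kids is not None:
            for c in kids:
                out.append((i, c, arrays.edge_len[c]))
    return out


def enum_likelihood_and_posteriors(arrays, states, q):
    """Brute-force joint enumeration over internal node states."""
    leaf_state = dict(zip(arrays.leaf_indices.tolist(), states.tolist()))
    internal = arrays.internal_indices.tolist()
    edges = _edges(arrays)

    def p_edge(si, sj, t):
        stay = 0.5 * (1 + np.exp(-2 * q * t))
        return stay if si == sj else 1 - stay

    total = 0.0
    post = {i: np.zeros(2) for i in internal}
    for assignment in itertools.product([0, 1], repeat=len(internal)):
        state = dict(zip(internal, assignment))
        state.update(leaf_state)
        term = 0.5  # flat root prior
        for parent, child, t in edges:
            term *= p_edge(state[parent], state[child], t)
        total += term
        for i in internal:
            post[i][state[i]] += term
    posteriors = np.array([post[i] / total for i in internal])
    return np.log(total), posteriors


FIXTURE_TREES = [
    "((A:1,B:1):1,(C:1,D:1):1);",
    "((A:0.3,B:1.7):0.4,(C:2.1,(D:0.9,E:0.2):0.5):1.1);",
    "(((A:1,B:2):0.5,(C:0.4,D:0.6):1.2):0.7,(E:1.5,F:0.8):0.9);",
    "((A:0.1,(B:0.2,(C:0.3,D:0.4):0.5):0.6):0.7,E:0.8);",
]


class TestPruningVsEnumeration:
    @pytest.mark.parametrize("newick", FIXTURE_TREES)
    @pytest.mark.parametrize("q", [0.1, 0.7, 3.0])
    def test_likelihood_matches_enumeration(self, newick, q):
        arrays = arrays_from(newick)
        rng = np.random.default_rng(42)
        for _ in range(3):
            states = rng.integers(0, 2, size=arrays.n_leaves)
            expected, _ = enum_likelihood_and_posteriors(arrays, states, q)
            assert ps.mk_loglik(arrays, states, q) == pytest.approx(
                expected, abs=1e-10)

    @pytest.mark.parametrize("newick", FIXTURE_TREES)
    def test_posteriors_match_enumeration(self, newick):
        arrays = arrays_from(newick)
        rng = np.random.default_rng(7)
        states = rng.integers(0, 2, size=arrays.n_leaves)
        if states.all() or not states.any():
            states[0] = 1 - states[0]
        q = ps.fit_mk(arrays, states).q
        _, expected = enum_likelihood_and_posteriors(arrays, states, q)
        got = ps.ancestral_posteriors(arrays, states, q)
        assert np.abs(got["posteriors"] - expected).max() < 1e-10
        assert np.allclose(got["posteriors"].sum(axis=1), 1.0, atol=1e-12)


class TestMkLimits:
    def test_vanishing_rate_with_discordant_tips(self):
        arrays = arrays_from("(A:1,B:1);")
        states = np.array([0, 1])
        assert ps.mk_loglik(arrays, states, 1e-8) < -15

    def test_saturation_limit_gives_independent_uniform_tips(self):
        for newick in FIXTURE_TREES:
            arrays = arrays_from(newick)
            states = np.zeros(arrays.n_leaves, dtype=int)
            states[0] = 1
            expected = arrays.n_leaves * np.log(0.5)
            assert ps.mk_loglik(arrays, states, 1e3) == pytest.approx(
                expected, abs=1e-6)

    def test_invalid_rate_rejected(self):
        arrays = arrays_from("(A:1,B:1);")
        with pytest.raises(ValueError):
            ps.mk_loglik(arrays, np.array([0, 1]), 0.0)


class TestFitMk:
    def test_matches_dense_grid_scan_on_fixture(self):
        arrays = arrays_from(FIXTURE_TREES[1])
        states = np.array([1, 1, 0, 0, 0])  # clade pattern, interior optimum
        fit = ps.fit_mk(arrays, states)
        grid = np.logspace(-8, 3, 10_000)
        ll = [ps.mk_loglik(arrays, states, q) for q in grid]
        best = int(np.argmax(ll))
        assert fit.loglik >= ll[best] - 1e-9
        # fitted rate at least as good as any grid point, and in its basin
        assert ps.mk_loglik(arrays, states, fit.q) >= ll[best] - 1e-9
        assert grid[max(best - 2, 0)] <= fit.q <= grid[min(best + 2, len(grid) - 1)]

    def test_clade_partitioned_trait_fits_slow_rate(self):
        arrays = arrays_from("((A:0.1,B:0.1):10,(C:0.1,D:0.1):10);")
        fit = ps.fit_mk(arrays, np.array([1, 1, 0, 0]))
        grid = np.logspace(-8, 3, 2_000)
        ll = [ps.mk_loglik(arrays, np.array([1, 1, 0, 0]), q) for q in grid]
        assert fit.loglik >= max(ll) - 1e-9
        assert fit.q < 1.0  # an order of magnitude below the saturated case

    def test_saturated_trait_fits_fast_rate(self):
        arrays = arrays_from(
            "((A:0.01,B:0.01):0.01,(C:0.01,D:0.01):0.01);")
        fit = ps.fit_mk(arrays, np.array([1, 0, 1, 0]))
        assert fit.q > 10


class TestDelta:
    def test_flat_posteriors_give_delta_one(self):
        assert ps.delta_from_entropies(np.full(5, np.log(2))) == pytest.approx(1.0)

    def test_certain_posteriors_hit_entropy_floor_cap(self):
        m = 7
        expected = m * np.log(2) / (m * ps.H_MIN)
        assert ps.delta_from_entropies(np.zeros(m)) == pytest.approx(expected)

    def test_clade_trait_outscores_random_trait(self):
        """On a 64-leaf balanced tree, a clade-confined presence pattern has
        larger delta than a random pattern with the same prevalence in at
        least 95 of 100 seeded draws."""
        newick = _balanced_newick(64)
        arrays = arrays_from(newick)
        labels = arrays.leaf_labels
        clade_states = ps.states_for(arrays, set(labels[:16]))
        # the first 16 labels of a balanced tree form one clade
        delta_clade = ps.compute_delta(arrays, clade_states)
        rng = np.random.default_rng(2024)
        wins = 0
        for _ in range(100):
            rand_states = rng.permutation(clade_states)
            if delta_clade > ps.compute_delta(arrays, rand_states):
                wins += 1
        assert wins >= 95


def _balanced_newick(n, bl=1.0):
    tips = [f"T{i:03d}:{bl}" for i in range(n)]
    while len(tips) > 1:
        tips = [
            f"({tips[2 * i]},{tips[2 * i + 1]}):{bl}"
            for i in range(len(tips) // 2)
        ]
    return tips[0] + ";"


class TestBuildTrait:
    TREE = "((A:1,B:1):1,(C:1,D:1):1);"

    def test_all_present_subtree_skipped_invariant(self):
        status, trait = ps.build_trait({"A", "B"}, tree_from(self.TREE), min_leaves=2)
        assert status == "skipped_invariant_trait" and trait is None

    def test_mrca_spans_tree_with_scattered_species(self):
        status, trait = ps.build_trait({"A", "C"}, tree_from(self.TREE), min_leaves=2)
        assert status == "tested"
        assert trait.n_leaves == 4
        present = {
            lab for lab, s in zip(trait.arrays.leaf_labels, trait.states) if s
        }
        assert present == {"A", "C"}

    def test_small_subtree_skipped_at_boundary(self):
        newick = _balanced_newick(32)
        tree = tree_from(newick)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        species = {labels[0], labels[15]}  # MRCA subtends exactly 16 leaves
        status, _ = ps.build_trait(species, tree, min_leaves=17)
        assert status == "skipped_small_subtree"
        status, _ = ps.build_trait(species, tree, min_leaves=16)
        assert status == "tested"

    def test_species_absent_from_tree_rejected(self):
        with pytest.raises(KeyError, match="ZZ"):
            ps.build_trait({"A", "ZZ"}, tree_from(self.TREE))


class TestPermutationTest:
    def _trait(self, newick, present):
        arrays = arrays_from(newick)
        return ps.TraitVector(arrays=arrays, states=ps.states_for(arrays, present))

    def test_clade_confined_trait_maximally_significant(self):
        """16 present species forming one clade of a 64-leaf tree: no
        permutation beats the observed delta except by tie, so p = 1/101 in
        at least 9 of 10 seeds."""
        newick = _balanced_newick(64)
        arrays = arrays_from(newick)
        trait = ps.TraitVector(
            arrays=arrays, states=ps.states_for(arrays, set(arrays.leaf_labels[:16]))
        )
        hits = sum(
            ps.permutation_test(trait, n_perm=100, seed=s).p_value
            == pytest.approx(1 / 101)
            for s in range(10)
        )
        assert hits >= 9

    def test_zero_permutations_rejected(self):
        trait = self._trait("((A:1,B:1):1,(C:1,D:1):1);", {"A", "C"})
        with pytest.raises(ValueError):
            ps.permutation_test(trait, n_perm=0, seed=1)

    def test_reproducible_for_fixed_seed(self):
        trait = self._trait(_balanced_newick(16), {"T000", "T001", "T005"})
        a = ps.permutation_test(trait, n_perm=30, seed=9)
        b = ps.permutation_test(trait, n_perm=30, seed=9)
        assert a == b

    def test_p_value_invariant_under_monotone_transform(self):
        """The permutation p-value depends on the statistic only through
        ranks: delta and minus-summed-entropy give exactly equal p."""
        trait = self._trait(_balanced_newick(16), set(f"T{i:03d}" for i in range(5)))
        p_delta = ps.permutation_test(
            trait, n_perm=40, seed=3, stat=ps.compute_delta).p_value
        p_ent = ps.permutation_test(
            trait, n_perm=40, seed=3, stat=ps.negative_entropy_sum).p_value
        assert p_delta == p_ent

    def test_invariant_under_tip_relabeling(self):
        """Relabeling tips together with their states (tree isomorphism,
        rotated child order) changes neither delta nor p."""
        t1 = "((A:1,B:2):0.5,((C:0.7,D:0.3):0.4,E:1.1):0.6);"
        t2 = "(((D:0.3,C:0.7):0.4,E:1.1):0.6,(B:2,A:1):0.5);"
        relabel = {"A": "V", "B": "W", "C": "X", "D": "Y", "E": "Z"}
        t2 = "".join(relabel.get(ch, ch) for ch in t2)
        tr1 = self._trait(t1, {"A", "C", "D"})
        tr2 = self._trait(t2, {"V", "X", "Y"})
        d1, d2 = ps.compute_delta(tr1.arrays, tr1.states), ps.compute_delta(
            tr2.arrays, tr2.states)
        assert d1 == pytest.approx(d2, rel=1e-9)
        p1 = ps.permutation_test(tr1, n_perm=25, seed=8).p_value
        p2 = ps.permutation_test(tr2, n_perm=25, seed=8).p_value
        assert p1 == p2


class TestScreenClusters:
    def test_empty_candidate_set(self):
        tree = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        results, summary = ps.screen_clusters({}, tree)
        assert results == [] and summary["frac_signal"] is None

    def test_small_subtree_excluded_from_fractions(self):
        tree = tree_from(_balanced_newick(32))
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        candidates = {
            "small": set(labels[:2]),
            "big": set(labels[::3]),
        }
        results, summary = ps.screen_clusters(
            candidates, tree, min_leaves=20, n_perm=20, seed=1)
        by_id = {r.cluster_id: r for r in results}
        assert by_id["small"].status == "skipped_small_subtree"
        assert summary["n_tested"] == 1 and summary["n_skipped"] == 1
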