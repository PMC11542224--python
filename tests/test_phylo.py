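"""Tree inference and comparison: NJ, RF, monophyly, parsimony, congruence.

Oracles: dendropy's bipartition machinery for RF, exhaustive labelings for
parsimony, and additive matrices generated from known trees for NJ.
"""

import itertools

import dendropy
import numpy as np
import pytest

from erosym import phylo


def random_binary_tree(labels, rng, min_bl=0.1, max_bl=1.0):
    """Random topology with branch lengths; returns (newick, edge lengths)."""
    nodes = [(l, f"{l}") for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
        a, b = nodes.pop(int(i)), nodes.pop(int(j))
        la, lb = rng.uniform(min_bl, max_bl, 2)
        nodes.append((min(a[0], b[0]), f"({a[1]}:{la:.6f},{b[1]}:{lb:.6f})"))
    (a, b) = nodes
    l = rng.uniform(min_bl, max_bl)
    return f"({a[1]}:{l / 2:.6f},{b[1]}:{l / 2:.6f});"


def tree_distances(newick):
    """Path-length (additive) distances between all tips."""
    t = dendropy.Tree.get(data=newick, schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    labels = sorted(x.label for x in t.taxon_namespace)
    D = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                ta = t.taxon_namespace.get_taxon(a)
                tb = t.taxon_namespace.get_taxon(b)
                D[i, j] = pdm.patristic_distance(ta, tb)
    return labels, D


class TestPDistance:
    def test_identical_and_simple(self):
        loci = {"l1": {"A": "AAAA", "B": "AAAT", "C": "AAAA"}}
        taxa, D = phylo.pdistance_matrix(loci)
        i, j = taxa.index("A"), taxa.index("B")
        assert D[i, j] == pytest.approx(0.25)
        assert D[taxa.index("A"), taxa.index("C")] == 0.0

    def test_jc_closed_form(self):
        assert phylo.jukes_cantor(0.25) == pytest.approx(-0.75 * np.log(1 - 1 / 3), abs=1e-9)

    def test_gapped_sites_excluded_pairwise(self):
        loci = {"l1": {"A": "AA-A", "B": "AATA"}}
        _, D = phylo.pdistance_matrix(loci)
        assert D[0, 1] == 0.0

    def test_saturated_distance_raises(self):
        with pytest.raises(ValueError, match="saturated"):
            phylo.jukes_cantor(0.8)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        t = phylo.nj_tree(["A", "B", "C"], D)
        # closed-form: a=(5+9-10)/2=2, b=(5+10-9)/2=3, c=(9+10-5)/2=7
        lens = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lens == pytest.approx({"A": 2.0, "B": 3.0, "C": 7.0})

    def test_additive_four_taxon_exact(self, rng):
        nwk = "((A:1.0,B:2.0):1.5,(C:0.5,D:3.0):1.5);"
        labels, D = tree_distances(nwk)
        t = phylo.nj_tree(labels, D)
        assert phylo.is_monophyletic(t, {"A", "B"})
        # branch lengths recovered: tip-to-tip path lengths match input
        _, D2 = tree_distances(
            t.as_string(schema="newick", unquoted_underscores=True, suppress_rooting=True)
        )
        assert np.allclose(D, D2, atol=1e-9)

    def test_additive_recovery_randomized(self, rng):
        labels = [f"t{i}" for i in range(8)]
        hits = 0
        for _ in range(30):
            nwk = random_binary_tree(labels, rng)
            true = phylo.tree_from_newick(nwk)
            labs, D = tree_distances(nwk)
            inferred = phylo.nj_tree(labs, D)
            hits += phylo.rf_distance(true, inferred)[0] == 0
        assert hits == 30

    def test_agrees_with_skbio_on_noisy_matrices(self, rng):
        # independent implementation cross-check on non-additive inputs
        import io as _io

        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        labels = [f"t{i}" for i in range(7)]
        agree = 0
        for _ in range(10):
            nwk = random_binary_tree(labels, rng)
            labs, D = tree_distances(nwk)
            D = D + rng.uniform(0, 0.02, D.shape)
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            mine = phylo.nj_tree(labs, D)
            theirs = skbio_nj(DistanceMatrix(D, labs))
            buf = _io.StringIO()
            theirs.write(buf, format="newick")
            theirs_dp = phylo.tree_from_newick(buf.getvalue())
            agree += phylo.rf_distance(mine, theirs_dp)[0] == 0
        assert agree >= 9  # tie-breaking may differ on rare degenerate inputs

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            phylo.nj_tree(["A", "B", "C"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))


class TestRobinsonFoulds:
    def test_identical_zero(self):
        t1 = phylo.tree_from_newick("((A,B),(C,D));")
        t2 = phylo.tree_from_newick("((B,A),(D,C));")
        assert phylo.rf_distance(t1, t2) == (0, 0.0)

    def test_single_nni_on_caterpillar(self):
        t1 = phylo.tree_from_newick("(A,(B,(C,(D,(E,F)))));")
        t2 = phylo.tree_from_newick("(A,(C,(B,(D,(E,F)))));")
        assert phylo.rf_distance(t1, t2)[0] == 2

    def test_maximally_different_six_taxon(self):
        t1 = phylo.tree_from_newick("(A,(B,(C,(D,(E,F)))));")
        t2 = phylo.tree_from_newick("(A,(D,(F,(B,(E,C)))));")
        raw, norm = phylo.rf_distance(t1, t2)
        assert raw == 6 and norm == 1.0

    def test_tip_mismatch_reports_difference(self):
        t1 = phylo.tree_from_newick("((A,B),C);")
        t2 = phylo.tree_from_newick("((A,B),D);")
        with pytest.raises(ValueError, match="only-in-first=\\['C'\\]"):
            phylo.rf_distance(t1, t2)

    def test_matches_dendropy_oracle(self, rng):
        labels = [f"t{i}" for i in range(7)]
        for _ in range(25):
            n1, n2 = (random_binary_tree(labels, rng) for _ in range(2))
            mine = phylo.rf_distance(
                phylo.tree_from_newick(n1), phylo.tree_from_newick(n2)
            )[0]
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=tns)
            d1.encode_bipartitions(), d2.encode_bipartitions()
            oracle = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert mine == oracle

    def test_metric_properties(self, rng):
        labels = [f"t{i}" for i in range(6)]
        trees = [phylo.tree_from_newick(random_binary_tree(labels, rng)) for _ in range(6)]
        for a, b, c in itertools.permutations(trees, 3):
            dab = phylo.rf_distance(a, b)[0]
            assert dab == phylo.rf_distance(b, a)[0]
            assert dab <= phylo.rf_distance(a, c)[0] + phylo.rf_distance(c, b)[0]
        for t in trees:
            assert phylo.rf_distance(t, t)[0] == 0


class TestMonophyly:
    @pytest.mark.parametrize(
        "newick,tips,expected",
        [
            ("((A,B),(C,D));", {"A", "B"}, True),
            ("((A,C),(B,D));", {"A", "B"}, False),
            ("((A,B),(C,D));", {"A"}, True),  # singleton by definition
        ],
    )
    def test_cases(self, newick, tips, expected):
        assert phylo.is_monophyletic(phylo.tree_from_newick(newick), tips) is expected

    def test_empty_and_full_rejected(self):
        t = phylo.tree_from_newick("((A,B),C);")
        with pytest.raises(ValueError):
            phylo.is_monophyletic(t, set())
        with pytest.raises(ValueError):
            phylo.is_monophyletic(t, {"A", "B", "C"})


def brute_force_parsimony(tree, tip_states):
    """Exhaustive minimum over all internal-node binary labelings."""
    internals = [n for n in tree.postorder_internal_node_iter()]
    states = sorted(set(tip_states.values()), key=str)
    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), combo))

        def state_of(n):
            return tip_states[n.taxon.label] if n.is_leaf() else assign[id(n)]

        changes = sum(
            state_of(child) != state_of(parent)
            for parent in internals
            for child in parent.child_nodes()
        )
        best = changes if best is None else min(best, changes)
    return best


class TestFitch:
    def test_uniform_states_zero(self):
        t = phylo.tree_from_newick("((A,B),(C,D));")
        assert phylo.fitch_min_transitions(t, dict.fromkeys("ABCD", 0)) == 0

    def test_single_hot_tip(self):
        t = phylo.tree_from_newick("((A,B),(C,D));")
        assert phylo.fitch_min_transitions(t, {"A": 1, "B": 0, "C": 0, "D": 0}) == 1

    def test_matches_exhaustive_oracle(self, rng):
        for trial in range(60):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            t = phylo.tree_from_newick(random_binary_tree(labels, rng))
            states = {l: int(rng.integers(0, 2)) for l in labels}
            assert phylo.fitch_min_transitions(t, states) == brute_force_parsimony(t, states)

    def test_rooting_invariance(self, rng):
        labels = [f"t{i}" for i in range(8)]
        nwk = random_binary_tree(labels, rng)
        t = phylo.tree_from_newick(nwk)
        states = {l: int(i % 2) for i, l in enumerate(labels)}
        base = phylo.fitch_min_transitions(t, states)
        for lf in list(t.leaf_node_iter())[:4]:
            t2 = phylo.tree_from_newick(nwk)
            node = next(
                x for x in t2.leaf_node_iter() if x.taxon.label == lf.taxon.label
            )
            t2.reroot_at_edge(node.edge, update_bipartitions=False)
            assert phylo.fitch_min_transitions(t2, states) == base

    def test_polytomy_exact(self, rng):
        t = phylo.tree_from_newick("((A,B,C,D),(E,F),(G,H,I));")
        states = {l: (1 if l in "ADEG" else 0) for l in "ABCDEFGHI"}
        assert phylo.fitch_min_transitions(t, states) == brute_force_parsimony(t, states)

    def test_unlabeled_tip_rejected(self):
        t = phylo.tree_from_newick("((A,B),C);")
        with pytest.raises(ValueError, match="unlabeled"):
            phylo.fitch_min_transitions(t, {"A": 1, "B": 0})


class TestBootstrap:
    def _loci(self, rng, n_sites=2000):
        # strongly tree-like data: two clades with many fixed differences
        base = "".join(rng.choice(list("ACGT"), n_sites))
        clade2 = "".join(
            c if rng.random() > 0.2 else "ACGT"[(("ACGT".index(c)) + 1) % 4] for c in base
        )
        def noisy(s, eps=0.005):
            return "".join(
                c if rng.random() > eps else "ACGT"[(("ACGT".index(c)) + 2) % 4] for c in s
            )
        return {"l": {"A": noisy(base), "B": noisy(base), "C": noisy(clade2), "D": noisy(clade2)}}

    def test_high_signal_full_support(self, rng):
        t = phylo.bootstrap_support(self._loci(rng), n_replicates=50, seed=1)
        supports = [n.label for n in t.postorder_internal_node_iter() if n.label]
        assert supports and all(float(s) == 100.0 for s in supports)

    def test_deterministic_given_seed(self, rng):
        loci = self._loci(rng)
        t1 = phylo.bootstrap_support(loci, n_replicates=20, seed=7)
        t2 = phylo.bootstrap_support(loci, n_replicates=20, seed=7)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_replicate_count_validated(self, rng):
        with pytest.raises(ValueError):
            phylo.bootstrap_support(self._loci(rng), n_replicates=0, seed=1)


class TestTanglegram:
    def test_identical_topologies_fully_congruent(self):
        sym = phylo.tree_from_newick("((s1,s2),(s3,s4));")
        host = phylo.tree_from_newick("((h1,h2),(h3,h4));")
        rep = phylo.tanglegram_congruence(
            sym, host, {f"s{i}": f"h{i}" for i in range(1, 5)}
        )
        assert rep.shared_bipartition_fraction == 1.0
        assert rep.normalized_rf == 0.0
        assert all(rep.node_congruence.values())

    def test_shared_fraction_complements_rf(self, rng):
        labels = [f"x{i}" for i in range(6)]
        t1 = phylo.tree_from_newick(random_binary_tree(labels, rng))
        t2 = phylo.tree_from_newick(random_binary_tree(labels, rng))
        rep = phylo.tanglegram_congruence(t1, t2, {l: l for l in labels})
        assert rep.shared_bipartition_fraction + rep.normalized_rf == pytest.approx(1.0)
        _, nrf = phylo.rf_distance(t1, t2)
        assert rep.normalized_rf == pytest.approx(nrf)

    def test_many_to_one_collapsed(self):
        sym = phylo.tree_from_newick("(((s1a,s1b),s2),(s3,s4));")
        host = phylo.tree_from_newick("((h1,h2),(h3,h4));")
        rep = phylo.tanglegram_congruence(
            sym, host,
            {"s1a": "h1", "s1b": "h1", "s2": "h2", "s3": "h3", "s4": "h4"},
        )
        assert rep.shared_bipartition_fraction == 1.0

    def test_too_few_mapped_tips_rejected(self):
        sym = phylo.tree_from_newick("((s1,s2),s3);")
        host = phylo.tree_from_newick("((h1,h2),h3);")
        with pytest.raises(ValueError, match="need >= 4"):
            phylo.tanglegram_congruence(sym, host, {"s1": "h1", "s2": "h2", "s3": "h3"})
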