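"""12-state GTR distances, Neighbor Joining, bootstrap and Profile NJ."""

import numpy as np
import pytest

from its1kit.phylo import (
    Node,
    bootstrap_support,
    distance_matrix,
    estimate_gtr,
    gtr_distance,
    jc12_distance,
    nj,
    profile_nj,
    random_gtr12,
    support_class,
    uniform_gtr12,
)
from its1kit.simulate import random_tree, simulate_alignment


class TestEstimateGTR:
    def test_identical_rows_pseudocount_only_and_balance(self):
        rows = [np.array([0, 1, 2, 3, 4, 5] * 10)] * 2
        m = estimate_gtr(rows)
        flux = m.pi[:, None] * m.Q
        assert np.max(np.abs(flux - flux.T)) < 1e-9
        assert m.Q.sum(axis=1) == pytest.approx(np.zeros(12), abs=1e-12)

    def test_single_symbol_alignment_rejected(self):
        rows = [np.zeros(30, dtype=int)] * 3
        with pytest.raises(ValueError, match="degenerate"):
            estimate_gtr(rows)

    def test_pi_recovery_from_simulation(self):
        """Frequencies simulated under a known model are recovered within
        3-sigma multinomial error (2 taxa, 10,000 sites)."""
        model = random_gtr12(7)
        tree = random_tree(2, 0.3, seed=3)
        rows = simulate_alignment(tree, model, 10_000, seed=9)
        est = estimate_gtr(list(rows.values()))
        sigma = np.sqrt(model.pi * (1 - model.pi) / 20_000)
        assert np.all(np.abs(est.pi - model.pi) < 3 * sigma + 5e-3)

    def test_unit_expected_rate(self):
        model = random_gtr12(11)
        assert -(model.pi * np.diag(model.Q)).sum() == pytest.approx(1.0)


class TestDistances:
    def test_identical_rows_distance_zero(self):
        m = uniform_gtr12()
        r = np.arange(12).repeat(5)
        assert gtr_distance(r, r, m) == 0.0

    def test_jc12_closed_form_properties(self):
        assert jc12_distance(0.0) == 0.0
        ps = np.linspace(0, 0.9, 50)
        ds = [jc12_distance(p) for p in ps]
        assert all(a < b for a, b in zip(ds, ds[1:]))
        assert jc12_distance(11 / 12) == 10.0  # saturation

    def test_gtr_uniform_limit_matches_jc12(self):
        """With uniform pi and equal exchangeabilities the ML distance
        equals the closed form within 1e-6."""
        m = uniform_gtr12()
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 400
            r1 = rng.integers(0, 12, n)
            r2 = r1.copy()
            k = int(rng.integers(10, 150))
            pos = rng.choice(n, k, replace=False)
            r2[pos] = rng.integers(0, 12, k)
            p = float((r1 != r2).mean())
            assert gtr_distance(r1, r2, m) == pytest.approx(jc12_distance(p), abs=1e-6)

    def test_no_shared_columns_rejected(self):
        m = uniform_gtr12()
        r1 = np.array([0, 1, -1, -1])
        r2 = np.array([-1, -1, 0, 1])
        with pytest.raises(ValueError, match="shared"):
            gtr_distance(r1, r2, m)


class TestNJ:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = nj(D, list("ABC"))
        lens = {ch.label: ch.length for ch in tree.children}
        assert lens == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_additive_four_taxon_exact(self):
        D = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        tree = nj(D, list("ABCD"))
        pd = tree.pairwise_distances()
        expected = {("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
                    ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9}
        for k, v in expected.items():
            assert pd[k] == pytest.approx(v, abs=1e-9)

    def test_additive_random_trees_recovered(self):
        """NJ reproduces 30 random additive trees exactly (4-12 taxa)."""
        for seed in range(30):
            tree = random_tree(int(np.random.default_rng(seed).integers(4, 13)), 0.8, seed=seed)
            pd = tree.pairwise_distances()
            labels = sorted(tree.leaf_labels())
            D = np.array(
                [[0.0 if a == b else pd[tuple(sorted((a, b)))] for b in labels] for a in labels]
            )
            out = nj(D, labels)
            assert out.bipartitions() == tree.bipartitions(), f"seed {seed}"
            opd = out.pairwise_distances()
            for k, v in pd.items():
                assert opd[k] == pytest.approx(v, abs=1e-9)

    def test_star_matrix_tie_rule_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        t1 = nj(D.copy(), list("ABCD"))
        t2 = nj(D.copy(), list("ABCD"))
        assert t1.newick() == t2.newick()

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            nj(D, list("ABC"))

    def test_agrees_with_dendropy_on_random_matrix(self):
        """Independent NJ oracle: dendropy's nj_tree on the same matrix
        yields the same unrooted topology."""
        import dendropy

        rng = np.random.default_rng(13)
        tree = random_tree(8, 0.6, seed=21)
        pd = tree.pairwise_distances()
        labels = sorted(tree.leaf_labels())
        noise = rng.uniform(0.0, 0.02, size=(8, 8))
        noise = (noise + noise.T) / 2
        D = np.array(
            [[0.0 if a == b else pd[tuple(sorted((a, b)))] for b in labels] for a in labels]
        ) + noise
        np.fill_diagonal(D, 0.0)
        ours = nj(D, labels)

        csv_rows = ["," + ",".join(labels)]
        for i, a in enumerate(labels):
            csv_rows.append(a + "," + ",".join(str(D[i, j]) for j in range(8)))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=iter("\n".join(csv_rows).splitlines(True)),
            delimiter=",",
        )
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        d_splits = set()
        all_taxa = frozenset(labels)
        anchor = min(labels)
        for edge in dtree.preorder_edge_iter():
            side = frozenset(
                lf.taxon.label for lf in edge.head_node.leaf_iter()
            )
            if anchor in side:
                side = all_taxa - side
            if 2 <= len(side) <= len(labels) - 2:
                d_splits.add(side)
        assert ours.bipartitions() == d_splits


@pytest.fixture(scope="module")
def clade_rows():
    def leaf(l, ln):
        return Node(label=l, length=ln)

    c1 = Node(length=1.5, children=[
        Node(length=0.1, children=[leaf("t0", 0.05), leaf("t1", 0.05)]), leaf("t2", 0.05)
    ])
    c2 = Node(length=1.5, children=[
        Node(length=0.1, children=[leaf("t3", 0.05), leaf("t4", 0.05)]), leaf("t5", 0.05)
    ])
    root = Node(children=[c1, c2])
    rows = simulate_alignment(root, uniform_gtr12(), 1200, seed=4)
    labels = sorted(rows)
    return [rows[l] for l in labels], labels


class TestBootstrap:
    def test_saturated_signal_gives_full_support(self, clade_rows):
        rows, labels = clade_rows
        _, sup = bootstrap_support(rows, labels, uniform_gtr12(), n_replicates=30, seed=5)
        clade_split = frozenset(["t3", "t4", "t5"])
        assert sup[clade_split] == 100.0

    def test_supports_reproducible_and_bounded(self, clade_rows):
        rows, labels = clade_rows
        _, s1 = bootstrap_support(rows, labels, uniform_gtr12(), n_replicates=20, seed=9)
        _, s2 = bootstrap_support(rows, labels, uniform_gtr12(), n_replicates=20, seed=9)
        assert s1 == s2
        assert all(0.0 <= v <= 100.0 for v in s1.values())

    def test_support_classes(self):
        assert support_class(None) == "none"
        assert support_class(40) == "none"
        assert support_class(75) == "open"
        assert support_class(95) == "closed"


class TestProfileNJ:
    def test_unreachable_threshold_reduces_to_plain_nj(self, clade_rows):
        rows, labels = clade_rows
        res = profile_nj(rows, labels, uniform_gtr12(), n_replicates=20,
                         support_threshold=101, seed=6)
        assert res.iterations == 1
        assert res.profiles == [[]]
        base = nj(distance_matrix(rows, uniform_gtr12()), labels)
        assert res.tree.bipartitions() == base.bipartitions()

    def test_well_separated_clades_condense_then_stop(self, clade_rows):
        rows, labels = clade_rows
        res = profile_nj(rows, labels, uniform_gtr12(), n_replicates=20,
                         support_threshold=70, seed=6)
        assert res.iterations == 2
        condensed = res.profiles[0]
        assert condensed, "at least one clade condensed in iteration 1"
        for group in condensed:
            assert set(group) <= {"t0", "t1", "t2"} or set(group) <= {"t3", "t4", "t5"}

    def test_leaf_set_conserved(self, clade_rows):
        rows, labels = clade_rows
        res = profile_nj(rows, labels, uniform_gtr12(), n_replicates=20,
                         support_threshold=70, seed=8)
        assert res.tree.leaf_labels() == frozenset(labels)

    def test_deterministic_for_fixed_seed(self, clade_rows):
        rows, labels = clade_rows
        r1 = profile_nj(rows, labels, uniform_gtr12(), n_replicates=15, seed=3)
        r2 = profile_nj(rows, labels, uniform_gtr12(), n_replicates=15, seed=3)
        assert r1.tree.newick() == r2.tree.newick()
        assert r1.iterations == r2.iterations


def test_topology_recovery_under_gtr_simulation():
    """Trees simulated under the 12-state model are recovered by
    distance+NJ for internal edges of length >= 0.05."""
    model = random_gtr12(3)
    ok = 0
    for seed in range(5):
        tree = random_tree(6, 0.3, seed=40 + seed)
        # enforce a minimum internal edge length
        def bump(node):
            for ch in node.children:
                if not ch.is_leaf() and ch.length < 0.05:
                    ch.length = 0.05
                bump(ch)
        bump(tree)
        rows = simulate_alignment(tree, model, 1000, seed=50 + seed)
        labels = sorted(rows)
        out = nj(distance_matrix([rows[l] for l in labels], model), labels)
        ok += out.bipartitions() == tree.bipartitions()
    assert ok >= 4
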