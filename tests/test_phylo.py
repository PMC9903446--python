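"""Phylogeny tests: exhaustive-summation likelihood oracle, closed forms,
neighbor joining examples, search monotonicity and simulation recovery."""

import itertools
import math

import numpy as np
import pytest

from cmschimera.amova import DistanceMatrix
from cmschimera.phylo import (
    Node,
    PhyloModel,
    PhyloTree,
    bootstrap_supports,
    empirical_frequencies,
    hky85_loglik,
    jc_distance_matrix,
    ml_search,
    nj_tree,
    prob_matrix,
    rate_matrix,
)
from cmschimera.synthetic import simulate_on_tree
from conftest import balanced_six_taxon_tree, random_dna, random_resolved_tree


def bruteforce_loglik(tree, alignment, model):
    """Likelihood by exhaustive summation over ancestral state assignments."""
    nodes = list(tree.root.walk())
    parent = {}
    for n in nodes:
        for c in n.children:
            parent[id(c)] = n
    internal = [n for n in nodes if n.children]
    P = {id(n): prob_matrix(model, n.length) for n in nodes if n is not tree.root}
    length = len(next(iter(alignment.values())))
    total = 0.0
    for site in range(length):
        site_like = 0.0
        for states in itertools.product(range(4), repeat=len(internal)):
            assign = {id(n): s for n, s in zip(internal, states)}
            p = model.freqs[assign[id(tree.root)]]
            for n in nodes:
                if n is tree.root:
                    continue
                up = assign[id(parent[id(n)])]
                if n.children:
                    p *= P[id(n)][up, assign[id(n)]]
                else:
                    c = alignment[n.name][site].upper()
                    if c in "ACGT":
                        p *= P[id(n)][up, "ACGT".index(c)]
                    else:
                        p *= 1.0  # missing: sum over leaf states is 1
            site_like += p
        total += math.log(site_like)
    return total


class TestTransitionProbabilities:
    @pytest.mark.parametrize("kappa,freqs", [
        (1.0, (0.25, 0.25, 0.25, 0.25)),
        (4.0, (0.3, 0.2, 0.3, 0.2)),
        (0.5, (0.1, 0.4, 0.2, 0.3)),
    ])
    def test_rows_stochastic_and_detailed_balance(self, kappa, freqs):
        model = PhyloModel(kappa, freqs)
        pi = np.array(freqs)
        for t in (0.0, 0.05, 0.7, 3.0):
            P = prob_matrix(model, t)
            assert P.sum(axis=1) == pytest.approx([1.0] * 4, abs=1e-12)
            flow = pi[:, None] * P
            assert np.allclose(flow, flow.T, atol=1e-12)

    def test_mean_rate_is_one(self):
        model = PhyloModel(3.0, (0.3, 0.2, 0.3, 0.2))
        Q = rate_matrix(model)
        assert -float(np.sum(np.array(model.freqs) * np.diag(Q))) == pytest.approx(1.0)

    def test_kappa_one_equal_freqs_is_jukes_cantor(self):
        model = PhyloModel(1.0, (0.25,) * 4)
        for t in (0.01, 0.2, 1.5):
            P = prob_matrix(model, t)
            same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
            diff = 0.25 - 0.25 * math.exp(-4.0 * t / 3.0)
            expected = np.full((4, 4), diff)
            np.fill_diagonal(expected, same)
            assert np.allclose(P, expected, atol=1e-10)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            PhyloModel(0.0, (0.25,) * 4)
        with pytest.raises(ValueError):
            PhyloModel(2.0, (0.5, 0.5, 0.25, 0.25))


class TestHky85Loglik:
    def test_zero_length_identical_single_site(self):
        tree = PhyloTree(Node(children=[Node("A", 0.0), Node("B", 0.0)]))
        model = PhyloModel(2.0, (0.25,) * 4)
        ll = hky85_loglik(tree, {"A": "C", "B": "C"}, model)
        assert ll == pytest.approx(math.log(0.25), abs=1e-12)

    def test_two_leaf_jc_closed_form(self):
        model = PhyloModel(1.0, (0.25,) * 4)
        t1, t2 = 0.13, 0.24
        tree = PhyloTree(Node(children=[Node("A", t1), Node("B", t2)]))
        T = t1 + t2
        same = 0.25 * (0.25 + 0.75 * math.exp(-4.0 * T / 3.0))
        diff = 0.25 * (0.25 - 0.25 * math.exp(-4.0 * T / 3.0))
        assert hky85_loglik(tree, {"A": "A", "B": "A"}, model) == pytest.approx(
            math.log(same), abs=1e-10
        )
        assert hky85_loglik(tree, {"A": "A", "B": "G"}, model) == pytest.approx(
            math.log(diff), abs=1e-10
        )

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for trial in range(8):
            n_taxa = int(rng.integers(3, 5))
            labels = [f"t{i}" for i in range(n_taxa)]
            tree = random_resolved_tree(labels, rng)
            n_sites = int(rng.integers(1, 6))
            alignment = {
                l: "".join(rng.choice(list("ACGTN-"), size=n_sites)) for l in labels
            }
            model = PhyloModel(
                float(rng.uniform(0.5, 6.0)),
                tuple(np.array([0.3, 0.2, 0.3, 0.2])),
            )
            got = hky85_loglik(tree, alignment, model)
            want = bruteforce_loglik(tree, alignment, model)
            assert got == pytest.approx(want, abs=1e-8)

    def test_invariant_to_leaf_order_and_rerooting(self):
        model = PhyloModel(3.0, (0.3, 0.2, 0.3, 0.2))
        aln = {"A": "ACGTA", "B": "ACGTT", "C": "AGGTA", "D": "ACTTA"}
        # same unrooted 4-taxon tree rooted at either internal node
        t1 = PhyloTree(
            Node(children=[
                Node(children=[Node("A", 0.1), Node("B", 0.2)], length=0.15),
                Node("C", 0.3),
                Node("D", 0.25),
            ])
        )
        t2 = PhyloTree(
            Node(children=[
                Node(children=[Node("C", 0.3), Node("D", 0.25)], length=0.15),
                Node("B", 0.2),
                Node("A", 0.1),
            ])
        )
        assert hky85_loglik(t1, aln, model) == pytest.approx(
            hky85_loglik(t2, aln, model), abs=1e-10
        )

    def test_label_mismatch_rejected(self):
        tree = PhyloTree(Node(children=[Node("A", 0.1), Node("B", 0.1)]))
        with pytest.raises(ValueError, match="labels"):
            hky85_loglik(tree, {"A": "AC", "X": "AC"}, PhyloModel())


class TestNeighborJoining:
    def test_three_taxon_additive_solution(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 2.0, 3.0], [2.0, 0.0, 3.0], [3.0, 3.0, 0.0]]),
        )
        tree = nj_tree(d)
        lengths = {n.name: n.length for n in tree.root.leaves}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0})

    def test_ultrametric_four_taxon_topology_recovered(self):
        # ((A,B),(C,D)): within-pair distance 2, across 6
        labels = ["A", "B", "C", "D"]
        m = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 2],
                [6, 6, 2, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(labels, m))
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_identical_rows_give_star_like_tree(self):
        d = DistanceMatrix(["A", "B", "C", "D"], np.ones((4, 4)) - np.eye(4))
        tree = nj_tree(d)
        internal = [
            n for n in tree.root.walk() if n.children and n is not tree.root
        ]
        assert all(n.length == pytest.approx(0.0, abs=1e-12) for n in internal)

    def test_negative_lengths_clamped(self):
        m = np.array(
            [
                [0, 1, 9, 9],
                [1, 0, 9, 9],
                [9, 9, 0, 17.9],
                [9, 9, 17.9, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], m))
        assert all(
            (n.length or 0.0) >= 0.0 for n in tree.root.walk() if n is not tree.root
        )

    def test_fewer_than_three_rejected(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(d)


class TestMlSearch:
    def test_recovers_true_six_taxon_topology(self):
        true = balanced_six_taxon_tree()
        root_seq = random_dna(np.random.default_rng(2), 1000)
        aln = simulate_on_tree(true, root_seq, 4.0, (0.3, 0.2, 0.3, 0.2), seed=2)
        got = ml_search(aln, nj_tree(jc_distance_matrix(aln)))
        assert got.bipartitions() == true.bipartitions()

    def test_never_decreases_loglik(self):
        true = balanced_six_taxon_tree()
        aln = simulate_on_tree(
            true, random_dna(np.random.default_rng(4), 300), 3.0, (0.25,) * 4, seed=4
        )
        start = nj_tree(jc_distance_matrix(aln))
        for n in start.root.walk():
            if n is not start.root:
                n.length = max(n.length or 0.0, 1e-9)
        model = PhyloModel(4.0, empirical_frequencies(aln))
        start_ll = hky85_loglik(start, aln, model)
        out = ml_search(aln, start, model=model)
        assert out.loglik >= start_ll - 1e-9

    def test_already_optimal_start_is_stable(self):
        true = balanced_six_taxon_tree()
        aln = simulate_on_tree(
            true, random_dna(np.random.default_rng(6), 400), 3.0, (0.25,) * 4, seed=6
        )
        first = ml_search(aln, nj_tree(jc_distance_matrix(aln)))
        second = ml_search(aln, first)
        assert second.bipartitions() == first.bipartitions()
        assert second.loglik == pytest.approx(first.loglik, abs=1e-4)
        assert second.loglik >= first.loglik - 1e-9

    def test_three_taxon_lengths_match_grid_oracle(self):
        labels = ["A", "B", "C"]
        true = PhyloTree(
            Node(children=[Node("A", 0.1), Node("B", 0.2), Node("C", 0.15)])
        )
        aln = simulate_on_tree(
            true, random_dna(np.random.default_rng(8), 500), 1.0, (0.25,) * 4, seed=8
        )
        model = PhyloModel(1.0, (0.25,) * 4)
        out = ml_search(aln, true, optimize=("bl",), model=model)
        grid = np.linspace(0.01, 0.4, 14)
        best = -np.inf
        for ta in grid:
            for tb in grid:
                for tc in grid:
                    tree = PhyloTree(
                        Node(children=[Node("A", ta), Node("B", tb), Node("C", tc)])
                    )
                    best = max(best, hky85_loglik(tree, aln, model))
        assert out.loglik >= best - 1e-6


class TestBootstrap:
    def test_single_replicate_supports_are_zero_or_one(self):
        true = balanced_six_taxon_tree()
        aln = simulate_on_tree(
            true, random_dna(np.random.default_rng(9), 300), 2.0, (0.25,) * 4, seed=9
        )
        _, supports = bootstrap_supports(aln, n_reps=1, seed=1)
        assert set(supports.values()) <= {0.0, 1.0}

    def test_clean_four_taxon_signal_gets_high_support(self):
        true = PhyloTree(
            Node(children=[
                Node(children=[Node("A", 0.05), Node("B", 0.05)], length=0.3),
                Node("C", 0.05),
                Node("D", 0.05),
            ])
        )
        aln = simulate_on_tree(
            true, random_dna(np.random.default_rng(10), 500), 2.0, (0.25,) * 4, seed=10
        )
        tree, supports = bootstrap_supports(aln, n_reps=100, seed=3)
        assert tree.bipartitions() == {frozenset({"C", "D"})} or tree.bipartitions() == {
            frozenset({"A", "B"})
        }
        assert all(v >= 0.9 for v in supports.values())

    def test_star_like_data_gets_low_support(self):
        # iid sequences carry no topology signal
        rng = np.random.default_rng(12)
        aln = {l: random_dna(rng, 200) for l in "ABCD"}
        _, supports = bootstrap_supports(aln, n_reps=50, seed=5)
        assert all(v < 0.9 for v in supports.values())
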