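"""Likelihood engine: pruning oracle, optimizers, pairwise distances."""

import itertools

import numpy as np
import pytest
import scipy.linalg

from chondroclock import (
    Alignment,
    SequenceRecord,
    SimulationScenario,
    build_jtt,
    estimate_alpha,
    optimize_branch_lengths,
    p_distance,
    pairwise_ml_distance,
    simulate_alignment,
    site_log_likelihoods,
)
from chondroclock.likelihood import TreeLikelihood
from chondroclock.models import AA_INDEX
from chondroclock.trees import Node, PhyloTree, read_newick
from conftest import random_aa


def brute_force_site_loglik(tree, columns, model):
    """Sum over every assignment of internal-node states, tiny cases only."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_tip]
    tips = [n for n in nodes if n.is_tip]
    Ps = {}
    out = []
    for col in columns:
        total = 0.0
        for c, (r, w) in enumerate(zip(model.category_rates, model.category_weights)):
            for n in nodes:
                if n.parent is not None:
                    Ps[id(n)] = scipy.linalg.expm(model.Q * (n.length * r))
            s = 0.0
            for assign in itertools.product(range(20), repeat=len(internals)):
                state = {id(n): a for n, a in zip(internals, assign)}
                term = model.frequencies[state[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    parent_state = state[id(n.parent)]
                    if n.is_tip:
                        obs = AA_INDEX.get(col[n.name], -1)
                        term *= 1.0 if obs < 0 else Ps[id(n)][parent_state, obs]
                    else:
                        term *= Ps[id(n)][parent_state, state[id(n)]]
                s += term
            total += w * s
        total *= 1.0 - model.p_inv
        if model.p_inv > 0:
            obs = {AA_INDEX.get(col[t.name], -1) for t in tips}
            obs.discard(-1)
            if len(obs) == 0:
                total += model.p_inv
            elif len(obs) == 1:
                total += model.p_inv * model.frequencies[obs.pop()]
        out.append(np.log(total))
    return np.array(out)


class TestPruningOracle:
    @pytest.mark.parametrize("p_inv", [0.0, 0.15])
    def test_three_taxon_two_sites(self, p_inv):
        model = build_jtt(alpha=0.6, p_inv=p_inv)
        tree = read_newick("((A:0.2,B:0.5):0.1,C:0.3);")
        aln = Alignment(
            [SequenceRecord("A", "MK"), SequenceRecord("B", "ML"),
             SequenceRecord("C", "-K")]
        )
        got = site_log_likelihoods(aln, tree, model).values
        cols = [{"A": "M", "B": "M", "C": "-"}, {"A": "K", "B": "L", "C": "K"}]
        cols = [
            {"A": aln.records[0].residues[j], "B": aln.records[1].residues[j],
             "C": aln.records[2].residues[j]}
            for j in range(2)
        ]
        want = brute_force_site_loglik(tree, cols, model)
        assert np.abs(got - want).max() < 1e-8

    def test_four_taxon_three_sites(self, rng, jtt):
        tree = read_newick("((A:0.3,B:0.1):0.2,(C:0.4,D:0.05):0.15);")
        seqs = {n: random_aa(rng, 3) for n in "ABCD"}
        aln = Alignment([SequenceRecord(n, seqs[n]) for n in "ABCD"])
        got = site_log_likelihoods(aln, tree, jtt).values
        cols = [{n: seqs[n][j] for n in "ABCD"} for j in range(3)]
        want = brute_force_site_loglik(tree, cols, jtt)
        assert np.abs(got - want).max() < 1e-8

    def test_zero_distance_limit(self, jtt):
        tree = read_newick("(A:0,B:0);")
        aln = Alignment([SequenceRecord("A", "W"), SequenceRecord("B", "W")])
        got = site_log_likelihoods(aln, tree, jtt).total
        assert got == pytest.approx(np.log(jtt.frequencies[AA_INDEX["W"]]), abs=1e-6)

    def test_root_placement_invariance(self, rng, jtt):
        t1 = read_newick("((A:0.2,B:0.5):0.1,(C:0.3,D:0.4):0.2);")
        t2 = read_newick("(A:0.2,(B:0.5,(C:0.3,D:0.4):0.3):0.0);")
        aln = Alignment([SequenceRecord(n, random_aa(rng, 40)) for n in "ABCD"])
        assert site_log_likelihoods(aln, t1, jtt).total == pytest.approx(
            site_log_likelihoods(aln, t2, jtt).total, abs=1e-8
        )

    def test_tip_order_invariance(self, rng, jtt):
        aln = Alignment([SequenceRecord(n, random_aa(rng, 25)) for n in "ABCD"])
        shuffled = Alignment([aln.records[i] for i in (2, 0, 3, 1)])
        tree = read_newick("((A:0.2,B:0.5):0.1,(C:0.3,D:0.4):0.2);")
        assert site_log_likelihoods(aln, tree, jtt).total == pytest.approx(
            site_log_likelihoods(shuffled, tree, jtt).total, abs=1e-10
        )

    def test_taxon_mismatch_errors(self, rng, jtt):
        aln = Alignment([SequenceRecord(n, random_aa(rng, 5)) for n in "ABX"])
        tree = read_newick("((A:0.1,B:0.1):0.1,C:0.1);")
        with pytest.raises(ValueError, match="mismatch"):
            site_log_likelihoods(aln, tree, jtt)


def _four_taxon_timetree():
    def internal(name, age, *children):
        n = Node(name, age=age)
        for c in children:
            n.add_child(c)
        return n

    return PhyloTree(
        internal("r", 200.0,
                 internal("i", 100.0, Node("A"), Node("B")),
                 internal("j", 120.0, Node("C"), Node("D")))
    )


class TestBranchOptimization:
    def test_recovers_true_lengths(self, jtt):
        """Simulated data at 1e5 sites recovers branch lengths within 5%."""
        scenario = SimulationScenario(
            timetree=_four_taxon_timetree(), model=jtt, n_sites=100_000,
            seed=9, mean_rate=0.1, sigma2=0.0,
        )
        aln, true_lens = simulate_alignment(scenario)
        start = read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        fitted, _ = optimize_branch_lengths(start, aln, jtt)
        got_tips = {n.name: n.length for n in fitted.tips()}
        for tip in "ABCD":
            assert got_tips[tip] == pytest.approx(true_lens[tip], rel=0.05)
        # only the sum of the two root-adjacent internal branches is identifiable
        internal_sum = sum(
            n.length for n in fitted.postorder() if n.parent is not None and not n.is_tip
        )
        assert internal_sum == pytest.approx(
            true_lens["i"] + true_lens["j"], rel=0.05
        )

    def test_optimum_is_fixed_point(self, rng, jtt):
        aln = Alignment([SequenceRecord(n, random_aa(rng, 200)) for n in "ABCD"])
        tree = read_newick("((A:0.2,B:0.5):0.1,(C:0.3,D:0.4):0.2);")
        once, logl1 = optimize_branch_lengths(tree, aln, jtt)
        twice, logl2 = optimize_branch_lengths(once, aln, jtt)
        assert logl2 == pytest.approx(logl1, abs=1e-4)
        for a, b in zip(once.postorder(), twice.postorder()):
            if a.parent is not None:
                assert b.length == pytest.approx(a.length, abs=1e-3)

    def test_ascent_from_random_starts(self, rng, jtt):
        aln = Alignment([SequenceRecord(n, random_aa(rng, 60)) for n in "ABCD"])
        base = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        for _ in range(20):
            tree = base.copy()
            for n in tree.postorder():
                if n.parent is not None:
                    n.length = float(rng.uniform(0.01, 3.0))
            before = site_log_likelihoods(aln, tree, jtt).total
            _, after = optimize_branch_lengths(tree, aln, jtt)
            assert after >= before - 1e-8


class TestEstimateAlpha:
    def test_parameter_recovery(self):
        model = build_jtt(alpha=0.5)
        scenario = SimulationScenario(
            timetree=_four_taxon_timetree(), model=model, n_sites=10_000,
            seed=21, mean_rate=0.15, sigma2=0.0,
        )
        aln, _ = simulate_alignment(scenario)
        start = read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        alpha_hat, _, _ = estimate_alpha(aln, start, build_jtt(alpha=1.0))
        assert alpha_hat == pytest.approx(0.5, abs=0.1)

    def test_homogeneous_data_hits_upper_bound(self):
        model = build_jtt(alpha=1.0, n_categories=1)  # rate-homogeneous truth
        scenario = SimulationScenario(
            timetree=_four_taxon_timetree(), model=model, n_sites=3000,
            seed=22, mean_rate=0.1, sigma2=0.0,
        )
        aln, _ = simulate_alignment(scenario)
        start = read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        with pytest.warns(UserWarning, match="bound"):
            alpha_hat, _, _ = estimate_alpha(
                aln, start, build_jtt(alpha=1.0), bounds=(0.02, 50.0)
            )
        assert alpha_hat > 40.0

    def test_beats_alpha_grid(self, rng):
        model = build_jtt(alpha=0.4)
        scenario = SimulationScenario(
            timetree=_four_taxon_timetree(), model=model, n_sites=1500,
            seed=23, mean_rate=0.12, sigma2=0.0,
        )
        aln, _ = simulate_alignment(scenario)
        start = read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        alpha_hat, fitted, logl_hat = estimate_alpha(aln, start, build_jtt())
        for alpha in np.linspace(0.05, 5.0, 50):
            other = TreeLikelihood(fitted, aln, build_jtt(alpha=float(alpha)))
            assert logl_hat >= other.log_likelihood() - 1e-6


class TestPairwiseDistances:
    def test_identical_sequences(self, jtt):
        assert pairwise_ml_distance("MKVLW" * 10, "MKVLW" * 10, jtt) < 1e-6

    def test_distance_recovery(self, jtt):
        root = Node("r", age=150.0)
        root.add_child(Node("A"))
        root.add_child(Node("B"))
        scenario = SimulationScenario(
            timetree=PhyloTree(root), model=jtt, n_sites=10_000, seed=31,
            mean_rate=1.0 / 15.0, sigma2=0.0,  # total path = 0.2 subs/site
        )
        aln, true_lens = simulate_alignment(scenario)
        assert true_lens["A"] + true_lens["B"] == pytest.approx(0.2)
        d = pairwise_ml_distance(aln.records[0].residues, aln.records[1].residues, jtt)
        assert d == pytest.approx(0.2, abs=0.02)

    def test_matches_grid_search(self, rng, jtt):
        a, b = random_aa(rng, 300), random_aa(rng, 300)
        mask = rng.random(300) < 0.8
        b = "".join(x if m else y for x, y, m in zip(a, b, mask))
        d = pairwise_ml_distance(a, b, jtt)
        grid = np.arange(1e-4, 3.0, 1e-4)

        counts = np.zeros((20, 20))
        for x, y in zip(a, b):
            counts[AA_INDEX[x], AA_INDEX[y]] += 1

        def loglik(t):
            Pmix = np.einsum(
                "c,cij->ij", jtt.category_weights, jtt.category_transition_matrices(t)
            )
            return (counts * np.log(jtt.frequencies[:, None] * Pmix)).sum()

        best = grid[np.argmax([loglik(t) for t in grid[:: 10]]) * 10]
        # refine around the coarse best
        fine = grid[(grid > best - 0.01) & (grid < best + 0.01)]
        best = fine[np.argmax([loglik(t) for t in fine])]
        assert d == pytest.approx(best, abs=1e-3)

    def test_p_distance_examples(self):
        assert p_distance("ACGT", "ACGA") == 0.25
        assert p_distance("MKVL", "MKVL") == 0.0
        with pytest.raises(ValueError):
            p_distance("", "")

    def test_p_distance_matches_column_count(self, rng):
        a, b = random_aa(rng, 120), random_aa(rng, 120)
        want = sum(x != y for x, y in zip(a, b)) / 120
        assert p_distance(a, b) == pytest.approx(want)
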