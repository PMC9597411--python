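"""Orthology HMM: emissions, forward pass, posteriors, fitting."""

import itertools

import numpy as np
import pytest

import trifrac as tf
from trifrac.hmm import PERMS, EmissionEngine, init_from_fit
from trifrac.models import relabel
from trifrac.trees import SpeciesTree, TreeNode

from conftest import (
    arb_model,
    brute_force_loglik,
    brute_force_posterior,
    make_pillar,
    make_pillarset,
)


class TestLeafState:
    def test_three_tracks_is_T_for_any_permutation(self):
        p = make_pillar(0, {"A": (1, 1, 1)})
        for perm in PERMS:
            v = tf.leaf_state(p, "A", perm)
            assert v[0] == 1.0 and v.sum() == 1.0

    def test_two_tracks_map_to_duplicated_state(self):
        p = make_pillar(0, {"A": (1, 0, 1)})
        v = tf.leaf_state(p, "A", (0, 1, 2))  # tracks 1,3 -> {LF, MF}
        assert v[2] == 1.0 and v.sum() == 1.0

    def test_no_tracks_is_missing_data(self):
        p = make_pillar(0, {"A": (1, 1, 1), "B": (0, 0, 0)})
        assert np.array_equal(tf.leaf_state(p, "B", (2, 1, 0)), np.ones(7))


class TestEmission:
    def test_single_leaf_tree_closed_form(self):
        """One genome, stem u: retaining only the LF-mapped track has
        emission P(T -> S_LF)(u)."""
        u = 0.4
        tree = SpeciesTree([TreeNode(0, u, "A")])
        m = arb_model()
        P = tf.transition_matrix(m, u)
        p = make_pillar(0, {"A": (1, 0, 0)})
        got = tf.emission_likelihood(p, ((0, 1, 2),), m, tree)
        assert got == pytest.approx(P[0, 4], abs=1e-14)

    def test_fully_retained_pillar_state_independent(self, two_genome_tree):
        p = make_pillar(0, {"A": (1, 1, 1), "B": (1, 1, 1)})
        m = arb_model()
        vals = {
            tf.emission_likelihood(p, (pa, pb), m, two_genome_tree, ["A", "B"])
            for pa in PERMS
            for pb in PERMS
        }
        assert len({round(v, 15) for v in vals}) == 1

    def test_two_leaf_tree_matches_internal_state_summation(self, two_genome_tree):
        """Direct sum over the crown node's 7 states is the pruning value."""
        m = arb_model(arrival=tf.Arrival("MF", 0.3, 1.2))
        tree = two_genome_tree
        p = make_pillar(0, {"A": (1, 0, 1), "B": (0, 1, 0)})
        state = ((1, 0, 2), (2, 0, 1))
        va = tf.leaf_state(p, "A", state[0])
        vb = tf.leaf_state(p, "B", state[1])
        pi = tf.root_distribution(m)
        P_stem = tf.transition_matrix(m, tree.root.length)
        Pa = tf.transition_matrix(m, 0.3)
        Pb = tf.transition_matrix(m, 0.25)
        total = 0.0
        for s0 in range(7):  # state at the polyploidy
            for s1 in range(7):  # state at the crown
                total += (
                    pi[s0]
                    * P_stem[s0, s1]
                    * (Pa[s1] @ va)
                    * (Pb[s1] @ vb)
                )
        got = tf.emission_likelihood(p, state, m, tree, ["A", "B"])
        assert got == pytest.approx(total, rel=1e-12)

    @pytest.mark.parametrize("pattern", [
        {"A": (1, 1, 1), "B": (1, 0, 1)},
        {"A": (0, 1, 0), "B": (0, 0, 1)},
        {"A": (1, 1, 0), "B": (0, 0, 0)},
    ])
    def test_engine_matches_reference(self, two_genome_tree, pattern):
        ps = make_pillarset([pattern])
        m = arb_model()
        eng = EmissionEngine(ps, two_genome_tree)
        em = eng.emissions(m)
        for si, joint in enumerate(itertools.product(PERMS, repeat=2)):
            ref = tf.emission_likelihood(
                ps.pillars[0], joint, m, two_genome_tree, ps.genome_names
            )
            assert em[eng.inverse[0], si] == pytest.approx(ref, abs=1e-13)

    def test_too_many_genomes_rejected(self):
        names = list("ABCDEF")
        ps = make_pillarset([{g: (1, 1, 1) for g in names}])
        nodes = [TreeNode(i, 0.1, n) for i, n in enumerate(names)]
        root = TreeNode(6, 0.1, None, [0, 1, 2, 3, 4, 5])
        for n in nodes:
            n.parent = 6
        with pytest.raises(NotImplementedError):
            EmissionEngine(ps, SpeciesTree(nodes + [root]))


PATTERNS_2G = [
    {"A": (1, 1, 1), "B": (1, 0, 1)},
    {"A": (1, 0, 1), "B": (0, 1, 1)},
    {"A": (1, 1, 0), "B": (1, 1, 1)},
    {"A": (0, 0, 1), "B": (1, 1, 0)},
]


class TestForwardOracle:
    @pytest.mark.parametrize("n_pillars,theta", [(3, 0.07), (4, 0.12)])
    def test_two_genomes_match_path_enumeration(self, two_genome_tree, n_pillars, theta):
        ps = make_pillarset(PATTERNS_2G[:n_pillars])
        m = tf.build_model(
            "3g", {"sigma": 0.9, "f_T": 0.5, "f_D": 0.6, "g_T": 1.2, "g_D": 1.4}
        )
        eng = EmissionEngine(ps, two_genome_tree)
        E = eng.emissions(m)[eng.inverse]
        expected = brute_force_loglik(E, theta, 2)
        got = tf.forward_loglik(ps, m, two_genome_tree, tf.HMMParameters(theta), engine=eng)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_three_genomes_match_path_enumeration(self):
        tree = tf.SpeciesTree.from_newick("((A:0.3,B:0.25):0.1,C:0.4):0.2;")
        ps = make_pillarset(
            [
                {"A": (1, 0, 1), "B": (1, 1, 1), "C": (0, 1, 0)},
                {"A": (1, 0, 0), "B": (0, 1, 1), "C": (0, 1, 1)},
            ]
        )
        m = arb_model()
        eng = EmissionEngine(ps, tree)
        E = eng.emissions(m)[eng.inverse]
        expected = brute_force_loglik(E, 0.05, 3)
        got = tf.forward_loglik(ps, m, tree, tf.HMMParameters(0.05), engine=eng)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_break_re_initialises_the_chain(self, two_genome_tree):
        ps = make_pillarset(PATTERNS_2G)
        ps.breaks = {2}
        m = arb_model()
        eng = EmissionEngine(ps, two_genome_tree)
        E = eng.emissions(m)[eng.inverse]
        brk = np.zeros(4, dtype=bool)
        brk[2] = True
        expected = brute_force_loglik(E, 0.07, 2, breaks=brk)
        got = tf.forward_loglik(ps, m, two_genome_tree, tf.HMMParameters(0.07), engine=eng)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_all_triplicated_theta_independent(self, two_genome_tree):
        ps = make_pillarset([{"A": (1, 1, 1), "B": (1, 1, 1)}] * 3)
        m = arb_model()
        lls = {
            round(
                tf.forward_loglik(ps, m, two_genome_tree, tf.HMMParameters(th)), 12
            )
            for th in (0.0, 0.1, 0.4)
        }
        assert len(lls) == 1
        # and equals the sum of per-pillar log emissions
        e = tf.emission_likelihood(
            ps.pillars[0], (PERMS[0], PERMS[0]), m, two_genome_tree, ["A", "B"]
        )
        assert lls.pop() == pytest.approx(3 * np.log(e), rel=1e-10)

    def test_theta_one_rejected(self):
        with pytest.raises(ValueError):
            tf.HMMParameters(1.0)


class TestPosterior:
    def test_posteriors_match_path_enumeration(self, two_genome_tree):
        ps = make_pillarset(PATTERNS_2G[:3])
        m = arb_model()
        eng = EmissionEngine(ps, two_genome_tree)
        E = eng.emissions(m)[eng.inverse]
        res = tf.posterior_decode(
            ps, m, two_genome_tree, tf.HMMParameters(0.07), floor=0.0, engine=eng
        )
        for i in range(3):
            expected = brute_force_posterior(E, 0.07, 2, i)
            dense = np.zeros(36)
            for s, v in res.sparse[i].items():
                dense[s] = v
            assert np.allclose(dense, expected, atol=1e-9)

    def test_uniform_posterior_for_uninformative_pillars(self, two_genome_tree):
        ps = make_pillarset([{"A": (1, 1, 1), "B": (1, 1, 1)}] * 2)
        res = tf.posterior_decode(ps, arb_model(), two_genome_tree, tf.HMMParameters(0.1))
        assert res.map_posterior[0] == pytest.approx(1 / 36, rel=1e-9)
        assert res.map_states[0] == 0  # lexicographic tie-break

    def test_posterior_sums_and_marginal_consistency(self, small_sim, four_genome_tree):
        ps, _, res_floored = small_sim
        res = tf.posterior_decode(
            ps, arb_model(), four_genome_tree, tf.HMMParameters(0.02), floor=0.0
        )
        sums = [sum(d.values()) for d in res.sparse]
        assert np.allclose(sums, 1.0, atol=1e-8)
        # the floored store loses at most floor * n_states of mass per pillar
        floored_sums = [sum(d.values()) for d in res_floored.sparse]
        assert min(floored_sums) >= 1.0 - 1e-6 * 1296
        assert np.allclose(res.perm_marginals.sum(axis=2), 1.0, atol=1e-8)
        # track->subgenome rows are distributions (permutations are bijections)
        assert np.allclose(res.track_subgenome.sum(axis=3), 1.0, atol=1e-8)
        # MAP state posterior bounds every stored state's posterior
        for i, d in enumerate(res.sparse):
            assert res.map_posterior[i] >= max(d.values()) - 1e-12

    def test_frozen_chain_keeps_map_constant_within_blocks(self, two_genome_tree):
        ps = make_pillarset(PATTERNS_2G)
        res = tf.posterior_decode(
            ps, arb_model(), two_genome_tree, tf.HMMParameters(1e-12)
        )
        assert len(set(res.map_states.tolist())) == 1

    def test_loglik_invariant_under_subgenome_relabeling(self, two_genome_tree):
        ps = make_pillarset(PATTERNS_2G)
        m = arb_model()
        base = tf.forward_loglik(ps, m, two_genome_tree, tf.HMMParameters(0.05))
        for perm in itertools.permutations(range(3)):
            m2 = relabel(m, perm)
            ll = tf.forward_loglik(ps, m2, two_genome_tree, tf.HMMParameters(0.05))
            assert ll == pytest.approx(base, abs=1e-9)


class TestFit:
    @pytest.fixture(scope="class")
    @staticmethod
    def sim_2g(two_genome_tree):
        cfg = tf.SimulationConfig(
            tree=two_genome_tree,
            model=tf.build_model("null", {"sigma": 0.8}),
            seed=5,
            n_pillars=2000,
            theta=0.05,
        )
        return tf.simulate_pillars(cfg)[0]

    def test_sigma_recovery_under_null(self, sim_2g, two_genome_tree):
        res = tf.fit(sim_2g, "null", two_genome_tree, n_starts=1)
        assert res.converged
        assert res.model.params["sigma"] == pytest.approx(0.8, abs=0.1)
        assert res.hmm.theta == pytest.approx(0.05, abs=0.02)

    def test_nested_families_never_lose_likelihood(self, sim_2g, two_genome_tree):
        lls = []
        prev = None
        for family in ("null", "1d", "3g", "arb"):
            init = None if prev is None else init_from_fit(prev, family)
            res = tf.fit(
                sim_2g, family, two_genome_tree, n_starts=1, standardize=False, init=init
            )
            lls.append(res.loglik)
            prev = res
        assert all(b >= a - 1e-4 for a, b in zip(lls, lls[1:]))
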