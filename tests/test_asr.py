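import itertools

import numpy as np
import pytest

from cladon.asr import (
    AA_ALPHABET,
    SubstitutionModel,
    marginal_asr,
    site_log_likelihood,
    transition_probability,
)
from cladon.io import PhyloTree, ValidationError


def _brute_force_posteriors(tree, seqs, model):
    """Joint enumeration over all internal-node states, marginalized.

    Independent of the pruning code: walks every assignment of states to
    internal nodes and accumulates joint probabilities directly.
    """
    nodes = list(tree.tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    k = model.k
    index = {s: i for i, s in enumerate(model.alphabet)}
    L = len(next(iter(seqs.values())))
    P = {
        id(n): model.transition_probability(n.edge.length)
        for n in nodes
        if n is not tree.tree.seed_node
    }
    post = {id(n): np.zeros((L, k)) for n in internal}
    lls = np.zeros(L)
    for site in range(L):
        total = 0.0
        acc = {id(n): np.zeros(k) for n in internal}
        for assign in itertools.product(range(k), repeat=len(internal)):
            states = {id(n): s for n, s in zip(internal, assign)}
            prob = model.stationary_freqs[states[id(tree.tree.seed_node)]]
            ok = True
            for n in nodes:
                if n is tree.tree.seed_node:
                    continue
                parent_state = states[id(n.parent_node)]
                if n.is_leaf():
                    sym = seqs[n.taxon.label][site]
                    if sym in index:
                        prob *= P[id(n)][parent_state, index[sym]]
                    # missing symbol: sum over states = row sum = 1
                else:
                    prob *= P[id(n)][parent_state, states[id(n)]]
            total += prob
            for n in internal:
                acc[id(n)][states[id(n)]] += prob
        lls[site] = np.log(total)
        for n in internal:
            post[id(n)][site] = acc[id(n)] / total
    return post, float(lls.sum())


def _all_rooted_topologies(labels):
    """Every rooted binary leaf-labeled topology over ``labels`` (Newick)."""
    labels = list(labels)
    if len(labels) == 1:
        return [labels[0]]
    out = []
    first, rest = labels[0], labels[1:]
    for r in range(0, len(rest)):
        for combo in itertools.combinations(rest, r):
            left = [first] + list(combo)
            right = [x for x in rest if x not in combo]
            if not right:
                continue
            for lt in _all_rooted_topologies(left):
                for rt in _all_rooted_topologies(right):
                    out.append(f"({lt},{rt})")
    return out


class TestTransitionProbability:
    def test_zero_time_identity(self):
        m = SubstitutionModel.jc()
        assert np.allclose(transition_probability(m, 0.0), np.eye(4))

    def test_long_time_stationary(self):
        m = SubstitutionModel.jc()
        assert np.allclose(transition_probability(m, 500.0), 0.25, atol=1e-9)

    def test_jc_closed_form(self):
        m = SubstitutionModel.jc()
        p = transition_probability(m, 0.1)
        diag = 0.25 + 0.75 * np.exp(-4 * 0.1 / 3)
        assert np.allclose(np.diag(p), diag)
        assert p[0, 1] == pytest.approx((1 - diag) / 3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            transition_probability(SubstitutionModel.jc(), -0.1)

    def test_poisson_model_rows_stochastic(self):
        m = SubstitutionModel.poisson()
        p = transition_probability(m, 0.37)
        assert p.shape == (20, 20)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_custom_model_validation(self):
        q = np.array([[-1.0, 1.0], [0.5, -0.5]])
        pi = np.array([1 / 3, 2 / 3])
        m = SubstitutionModel.custom(("R", "Y"), q, pi)
        assert np.allclose(m.transition_probability(1.0).sum(axis=1), 1.0)
        with pytest.raises(ValidationError, match="reversible|balance"):
            SubstitutionModel.custom(
                ("R", "Y"), q, np.array([0.5, 0.5])
            )


class TestSiteLikelihood:
    def test_single_tip_prior_only(self):
        t = PhyloTree.from_newick("A;")
        ll = site_log_likelihood(t, SubstitutionModel.jc(), {"A": "A"})
        assert ll == pytest.approx(np.log(0.25))

    def test_star_tree_equals_enumeration(self):
        m = SubstitutionModel.jc()
        t = PhyloTree.from_newick("(A:0.1,B:0.1,C:0.1);")
        P = m.transition_probability(0.1)
        idx = {"A": 0, "C": 1}
        brute = sum(
            0.25 * P[x, idx["A"]] * P[x, idx["A"]] * P[x, idx["C"]]
            for x in range(4)
        )
        ll = site_log_likelihood(t, m, {"A": "A", "B": "A", "C": "C"})
        assert ll == pytest.approx(np.log(brute))

    def test_invariant_to_child_ordering(self):
        m = SubstitutionModel.jc()
        a = site_log_likelihood(
            PhyloTree.from_newick("((A:0.1,B:0.2):0.1,C:0.3);"), m,
            {"A": "A", "B": "C", "C": "G"},
        )
        b = site_log_likelihood(
            PhyloTree.from_newick("(C:0.3,(B:0.2,A:0.1):0.1);"), m,
            {"A": "A", "B": "C", "C": "G"},
        )
        assert a == pytest.approx(b)

    def test_missing_branch_length_rejected(self):
        t = PhyloTree.from_newick("(A:0.1,B);")
        with pytest.raises(ValidationError, match="branch length"):
            site_log_likelihood(t, SubstitutionModel.jc(), {"A": "A", "B": "C"})


class TestMarginalASR:
    def test_three_tip_star_posterior(self):
        t = PhyloTree.from_newick("(A:0.1,B:0.1,C:0.1);")
        rec = marginal_asr(t, {"A": "A", "B": "A", "C": "C"}, SubstitutionModel.jc())
        root = rec.node_order[0]
        assert rec.node_posteriors[root][0, 0] == pytest.approx(0.964, abs=1e-3)
        assert rec.map_sequences[root] == "A"

    def test_zero_branches_identical_tips(self):
        t = PhyloTree.from_newick("(A:0.0,B:0.0,C:0.0);")
        rec = marginal_asr(t, {"A": "A", "B": "A", "C": "A"}, SubstitutionModel.jc())
        post = rec.node_posteriors[rec.node_order[0]]
        assert post[0, 0] == pytest.approx(1.0)

    def test_posterior_rows_sum_to_one(self):
        t = PhyloTree.from_newick("((A:0.2,B:0.3):0.1,(C:0.4,D:0.1):0.2);")
        rec = marginal_asr(
            t, {"A": "ACGT", "B": "AC-T", "C": "ACGA", "D": "NCGT"},
            SubstitutionModel.jc(),
        )
        for post in rec.node_posteriors.values():
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_bruteforce_on_small_trees(self):
        """Marginal posteriors equal joint enumeration marginalized, and the
        total log-likelihood matches, on several 4-tip topologies."""
        m = SubstitutionModel.jc()
        rng = np.random.default_rng(5)
        for nwk in [
            "((A:{a},B:{b}):{c},(C:{d},D:{e}):{f});",
            "(((A:{a},B:{b}):{c},C:{d}):{e},D:{f});",
        ]:
            bl = {k: round(float(v), 3) for k, v in
                  zip("abcdef", rng.uniform(0.05, 0.8, 6))}
            t = PhyloTree.from_newick(nwk.format(**bl))
            seqs = {"A": "ACG", "B": "AC-", "C": "GCG", "D": "ACT"}
            rec = marginal_asr(t, seqs, m)
            brute_post, brute_ll = _brute_force_posteriors(t, seqs, m)
            assert rec.total_log_likelihood == pytest.approx(brute_ll, abs=1e-10)
            for node in t.tree.preorder_node_iter():
                if node.is_leaf():
                    continue
                label = [
                    lab for lab in rec.node_order
                    if np.allclose(
                        rec.node_posteriors[lab], brute_post[id(node)], atol=1e-9
                    )
                ]
                assert label, "no matching posterior for an internal node"

    def test_pulley_principle(self):
        """Total log-likelihood is invariant to root placement."""
        m = SubstitutionModel.jc()
        base = "((A:0.2,B:0.3):0.15,(C:0.4,D:0.1):0.25);"
        seqs = {"A": "ACGTA", "B": "ACGTC", "C": "GGGTA", "D": "ACTTA"}
        ref = marginal_asr(PhyloTree.from_newick(base), seqs, m).total_log_likelihood
        for tip in "ABCD":
            t = PhyloTree.from_newick(base)
            node = t.tree.find_node_with_taxon_label(tip)
            t.tree.reroot_at_edge(node.edge, length1=node.edge.length / 2,
                                  length2=node.edge.length / 2,
                                  update_bipartitions=False)
            ll = marginal_asr(PhyloTree(t.tree), seqs, m).total_log_likelihood
            assert ll == pytest.approx(ref, abs=1e-9)

    def test_tip_sequence_mismatch_lists_offenders(self):
        t = PhyloTree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValidationError, match="B"):
            marginal_asr(t, {"A": "A", "Z": "C"}, SubstitutionModel.jc())

    def test_amino_acid_reconstruction(self):
        t = PhyloTree.from_newick("(A:0.05,B:0.05,C:0.05);")
        rec = marginal_asr(
            t, {"A": "MKL", "B": "MKL", "C": "MKV"},
            SubstitutionModel.poisson(),
        )
        root = rec.node_order[0]
        assert rec.map_sequences[root] == "MKL"
        assert rec.alphabet == AA_ALPHABET


def test_recovery_at_short_branches():
    """Posterior mass concentrates on the true ancestral state as branch
    lengths shrink: >= 99% of sites recovered at t = 0.01."""
    from cladon.simulate import SimulationParams, simulate_codon_evolution

    rng = np.random.default_rng(17)
    t = PhyloTree.from_newick(
        "((A:0.01,B:0.01):0.01,(C:0.01,D:0.01):0.01);"
    )
    params = SimulationParams(seed=17, L_codons=400)
    model = SubstitutionModel.jc()
    aln = simulate_codon_evolution(t, "stationary", params, rng=rng)
    rec = marginal_asr(t, aln, model)
    # with four near-identical tips the root MAP should match the consensus
    seqs = [r.sequence for r in aln]
    consensus = "".join(
        max("ACGT", key=lambda b: sum(s[i] == b for s in seqs))
        for i in range(len(seqs[0]))
    )
    root_map = rec.map_sequences[rec.node_order[0]]
    agree = np.mean([a == b for a, b in zip(root_map, consensus)])
    assert agree >= 0.99
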