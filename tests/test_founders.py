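"""GTR likelihood, MCMC sampler and founder-state inference."""

import itertools

import dendropy
import numpy as np
import pytest

from matriloop.founders import (
    ChainConfig,
    OUTGROUP_ID,
    StarModelData,
    TreeNode,
    _StarSampler,
    build_family_tree,
    build_star_data,
    founder_posterior,
    mcmc_sample,
    pruning_likelihood,
    select_inference_set,
)
from matriloop.gtr import GTRParams, TransitionCalculator, jc_p_same
from matriloop.pedigree import Individual, PedigreeSet


# ---------------------------------------------------------------------------
# oracles


def enumeration_likelihood(root, patterns, params):
    """Sum over all internal-node state assignments (exhaustive oracle)."""
    internals, edges, leaves = [], [], []

    def collect(node, parent_idx):
        if node.is_leaf:
            leaves.append((node.name, parent_idx, node.length))
        else:
            internals.append(node)
            idx = len(internals) - 1
            if parent_idx is not None:
                edges.append((parent_idx, idx, node.length))
            for child in node.children:
                collect(child, idx)

    collect(root, None)
    calc = TransitionCalculator(params)
    pi = np.asarray(params.freqs)
    n_sites = len(next(iter(patterns.values())))
    total = 0.0
    for site in range(n_sites):
        site_sum = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            prob = pi[assign[0]]
            for parent, child, t in edges:
                prob *= calc.probability_matrix(t)[assign[parent], assign[child]]
            for name, parent, t in leaves:
                state = patterns[name][site]
                P = calc.probability_matrix(t)
                if state < 0:
                    prob *= P[assign[parent], :].sum()
                else:
                    prob *= P[assign[parent], state]
            site_sum += prob
        total += np.log(site_sum)
    return total


def random_tree(rng, n_leaves):
    nodes = [TreeNode(name=f"L{i}", length=float(rng.uniform(0.01, 0.8)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        k = 2 if len(nodes) == 2 else int(rng.integers(2, min(3, len(nodes)) + 1))
        picks = [nodes.pop(int(rng.integers(len(nodes)))) for _ in range(k)]
        nodes.append(TreeNode(length=float(rng.uniform(0.01, 0.8)), children=picks))
    root = nodes[0]
    root.length = 0.0
    return root


def random_params(rng):
    return GTRParams(
        rates=tuple(rng.dirichlet(np.ones(6))),
        freqs=tuple(rng.dirichlet(np.full(4, 5.0))),
    )


# ---------------------------------------------------------------------------
# model basics


class TestGTR:
    def test_rows_sum_to_one_and_detailed_balance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            params = random_params(rng)
            assert params.detailed_balance_residual() < 1e-12
            Q = params.rate_matrix()
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
            calc = TransitionCalculator(params)
            for t in (0.0, 0.01, 0.5, 5.0):
                P = calc.probability_matrix(t)
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
                assert np.all(P >= 0)

    def test_jukes_cantor_closed_form_on_one_branch(self):
        calc = TransitionCalculator(GTRParams.jukes_cantor())
        for t in (0.0, 0.001, 0.05, 0.3, 2.0):
            P = calc.probability_matrix(t)
            assert np.allclose(np.diag(P), jc_p_same(t), atol=1e-12)
            off = P[~np.eye(4, dtype=bool)]
            assert np.allclose(off, (1 - jc_p_same(t)) / 3, atol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GTRParams(rates=(-1, 1, 1, 1, 1, 1), freqs=(0.25,) * 4)
        with pytest.raises(ValueError):
            GTRParams(rates=(1,) * 6, freqs=(0.5, 0.5, 0.1, 0.1))


class TestPruning:
    def test_zero_branch_identical_state_gives_log_frequency(self):
        params = random_params(np.random.default_rng(3))
        root = TreeNode(children=[TreeNode(name="leaf", length=0.0)])
        for state in range(4):
            ll = pruning_likelihood(root, {"leaf": np.array([state])}, params)
            assert ll == pytest.approx(np.log(params.freqs[state]), abs=1e-12)

    def test_matches_enumeration_on_small_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_leaves = int(rng.integers(2, 7))
            root = random_tree(rng, n_leaves)
            params = random_params(rng)
            n_sites = int(rng.integers(1, 4))
            patterns = {
                f"L{i}": rng.integers(-1, 4, size=n_sites)
                for i in range(n_leaves)
            }
            fast = pruning_likelihood(root, patterns, params)
            slow = enumeration_likelihood(root, patterns, params)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_invariant_under_leaf_reordering(self):
        rng = np.random.default_rng(9)
        root = random_tree(rng, 5)
        params = random_params(rng)
        patterns = {f"L{i}": rng.integers(0, 4, size=6) for i in range(5)}
        ll = pruning_likelihood(root, patterns, params)
        for node in [root] + [c for c in root.children if not c.is_leaf]:
            node.children = list(reversed(node.children))
        assert pruning_likelihood(root, patterns, params) == pytest.approx(
            ll, abs=1e-12
        )


class TestEligibility:
    def _pedigree(self):
        ped = PedigreeSet()
        ped.add(Individual("F", None, "fam", is_founder=True, sampled=False))
        ped.add(Individual("a", "F", "fam"))       # dam of b -> proximal
        ped.add(Individual("b", "a", "fam"))       # dam of c -> proximal
        ped.add(Individual("c", "b", "fam"))       # terminal
        for i in range(3):
            ped.add(Individual(f"x{i}", "F", "fam"))
        return ped

    def test_proximal_dam_and_granddam_dropped(self):
        eligible, excluded = select_inference_set(self._pedigree())
        assert eligible == {"fam": ["c", "x0", "x1", "x2"]}
        assert excluded == {}

    def test_minimum_four_rule(self):
        ped = PedigreeSet()
        ped.add(Individual("F", None, "small", is_founder=True, sampled=False))
        for i in range(3):
            ped.add(Individual(f"s{i}", "F", "small"))
        eligible, excluded = select_inference_set(ped)
        assert eligible == {}
        assert "too few horses (3" in excluded["small"]

    def test_fixture_eligibility_matches_published_counts(self, fixture_data):
        eligible, excluded = select_inference_set(fixture_data.pedigree)
        assert set(excluded) == {"Bint Karima", "Nafaa"}
        expected = {
            row.family: int(row.n_available)
            for row in fixture_data.family_info.itertuples()
            if row.family not in ("Bint Karima", "Nafaa")
        }
        assert {f: len(v) for f, v in eligible.items()} == expected
        assert len(eligible) == 12

    def test_cycle_detection(self):
        ped = PedigreeSet()
        ped.add(Individual("a", "b", "fam"))
        ped.add(Individual("b", "a", "fam"))
        with pytest.raises(Exception, match="cycle"):
            select_inference_set(ped)


class TestFamilyTree:
    def test_star_tree_shape_and_newick_round_trip(self):
        tree = build_family_tree("fam", ["l1", "l2", "l3", "l4"])
        assert len(tree.root.leaves()) == 5
        assert tree.mrca.name == "fam_founder"
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert taxa == {"l1", "l2", "l3", "l4", OUTGROUP_ID}

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            build_family_tree("fam", ["l1", "l2", "l3"])


# ---------------------------------------------------------------------------
# sampler


def _star_data(rng, k=4, n_sites=50, t_true=0.01, outgroup_t=0.05,
               params=None):
    """Simulate leaf states down a star tree with known branch lengths."""
    params = params or GTRParams.jukes_cantor()
    calc = TransitionCalculator(params)
    pi = np.asarray(params.freqs)
    root_states = rng.choice(4, size=n_sites, p=pi)
    P_leaf = calc.probability_matrix(t_true)
    P_out = calc.probability_matrix(outgroup_t)
    leaf_states = np.stack(
        [
            np.array([rng.choice(4, p=P_leaf[s]) for s in root_states])
            for _ in range(k)
        ],
        axis=1,
    )
    out_states = np.array([rng.choice(4, p=P_out[s]) for s in root_states])
    return StarModelData(
        leaf_ids=tuple(f"l{i}" for i in range(k)),
        leaf_states=leaf_states.astype(np.int8),
        outgroup_states=out_states.astype(np.int8),
        weights=np.ones(n_sites),
        analysis_pattern_index=np.arange(n_sites),
        analysis_positions=tuple(range(15440, 15440 + n_sites)),
        target_states=root_states.astype(np.int8),
    )


class TestSampler:
    def test_star_likelihood_equals_general_pruning(self):
        rng = np.random.default_rng(11)
        data = _star_data(rng, k=5, n_sites=20)
        cfg = ChainConfig(n_iterations=10)
        sampler = _StarSampler(data, cfg, np.random.default_rng(0))
        # same model evaluated by Felsenstein pruning on the rooted tree
        mrca = TreeNode(
            name="mrca",
            length=sampler.branches[5],
            children=[
                TreeNode(name=f"l{i}", length=sampler.branches[i])
                for i in range(5)
            ],
        )
        root = TreeNode(
            children=[mrca, TreeNode(name="og", length=sampler.branches[6])]
        )
        patterns = {f"l{i}": data.leaf_states[:, i] for i in range(5)}
        patterns["og"] = data.outgroup_states
        ll = pruning_likelihood(root, patterns, sampler.params)
        assert sampler.loglik == pytest.approx(ll, abs=1e-8)

    def test_fixed_seed_reproduces_sample_stream(self):
        rng = np.random.default_rng(13)
        data = _star_data(rng, k=4, n_sites=30)
        cfg = ChainConfig(n_iterations=2000, n_chains=2)
        s1 = mcmc_sample(data, cfg, seed=42)
        s2 = mcmc_sample(data, cfg, seed=42)
        assert np.array_equal(s1.founder_states, s2.founder_states)
        assert np.array_equal(s1.log_likelihood, s2.log_likelihood)
        assert np.array_equal(s1.branch_lengths, s2.branch_lengths)

    def test_prior_only_run_recovers_branch_prior_mean(self):
        data = StarModelData(
            leaf_ids=("l0", "l1", "l2", "l3"),
            leaf_states=np.zeros((0, 4), dtype=np.int8),
            outgroup_states=np.zeros(0, dtype=np.int8),
            weights=np.zeros(0),
            analysis_pattern_index=np.zeros(0, dtype=int),
            analysis_positions=(),
            target_states=np.zeros(0, dtype=np.int8),
        )
        cfg = ChainConfig(n_iterations=40000)
        samples = mcmc_sample(data, cfg, seed=7)
        mean = samples.branch_lengths.mean()
        assert abs(mean - cfg.branch_prior_mean) < 0.01

    def test_branch_length_recovery_within_three_posterior_sd(self):
        rng = np.random.default_rng(19)
        data = _star_data(rng, k=6, n_sites=1000, t_true=0.01)
        cfg = ChainConfig(n_iterations=30000)
        samples = mcmc_sample(data, cfg, seed=3)
        leaf_draws = samples.branch_lengths[:, :, :6].reshape(-1, 6).mean(axis=1)
        post_mean = leaf_draws.mean()
        post_sd = leaf_draws.std()
        assert abs(post_mean - 0.01) < 3 * post_sd

    def test_nonpositive_chain_length_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iterations=0)


class TestFounderPosterior:
    def test_identical_leaves_tiny_branches_give_match(self):
        # leaves identical to the outgroup with strong data: founder state
        # posterior concentrates completely on the shared haplotype
        rng = np.random.default_rng(23)
        data = _star_data(rng, k=5, n_sites=400, t_true=1e-4, outgroup_t=1e-4)
        data = StarModelData(
            **{
                **data.__dict__,
                "target_states": data.leaf_states[:, 0].copy(),
                "leaf_states": np.repeat(
                    data.leaf_states[:, :1], 5, axis=1
                ),
                "outgroup_states": data.leaf_states[:, 0].copy(),
            }
        )
        cfg = ChainConfig(n_iterations=10000)
        samples = mcmc_sample(data, cfg, seed=5)
        result = founder_posterior(samples, config=cfg)
        assert result.posterior_match > 0.99

    def test_matches_exhaustive_bayes_at_fixed_parameters(self):
        # one site, four leaves, long fixed branches under Jukes-Cantor:
        # the founder draw distribution equals the closed-form posterior
        params = GTRParams.jukes_cantor()
        calc = TransitionCalculator(params)
        t_leaf, t_out = 0.4, 0.8
        leaf_states = np.array([[0, 0, 1, 2]], dtype=np.int8)  # A A C G
        out_state = np.array([3], dtype=np.int8)  # T
        data = StarModelData(
            leaf_ids=("a", "b", "c", "d"),
            leaf_states=leaf_states,
            outgroup_states=out_state,
            weights=np.ones(1),
            analysis_pattern_index=np.array([0]),
            analysis_positions=(15440,),
            target_states=np.array([0], dtype=np.int8),
        )
        cfg = ChainConfig(n_iterations=10)
        sampler = _StarSampler(data, cfg, np.random.default_rng(0))
        sampler.params = params
        sampler.branches = np.array([t_leaf] * 4 + [t_out, 0.0])
        sampler._rebuild_all()
        P = calc.probability_matrix(t_leaf)
        Po = calc.probability_matrix(t_out)
        post = np.array(
            [
                0.25
                * np.prod([P[s, x] for x in leaf_states[0]])
                * Po[s, out_state[0]]
                for s in range(4)
            ]
        )
        post /= post.sum()
        rng = np.random.default_rng(99)
        sampler.rng = rng
        draws = np.array([sampler.draw_founder_states()[0] for _ in range(20000)])
        freq = np.bincount(draws, minlength=4) / len(draws)
        assert np.allclose(freq, post, atol=0.01)

    def test_match_probability_nondecreasing_in_identical_leaves(self):
        # with more identical descendants the founder-state posterior mass
        # on the shared state can only grow (fixed parameters)
        params = GTRParams.jukes_cantor()
        cfg = ChainConfig(n_iterations=10)
        masses = []
        for k in (2, 4, 8):
            data = StarModelData(
                leaf_ids=tuple(f"l{i}" for i in range(k)),
                leaf_states=np.zeros((1, k), dtype=np.int8),
                outgroup_states=np.array([1], dtype=np.int8),
                weights=np.ones(1),
                analysis_pattern_index=np.array([0]),
                analysis_positions=(15440,),
                target_states=np.array([0], dtype=np.int8),
            )
            sampler = _StarSampler(data, cfg, np.random.default_rng(0))
            sampler.params = params
            sampler.branches = np.array([0.1] * k + [0.2, 0.2])
            sampler._rebuild_all()
            pi = np.asarray(params.freqs)
            post = pi * sampler.prod[0]
            masses.append(post[0] / post.sum())
        assert masses[0] < masses[1] < masses[2]

    def test_requires_minimum_retained_samples(self):
        rng = np.random.default_rng(29)
        data = _star_data(rng, k=4, n_sites=10)
        cfg = ChainConfig(n_iterations=1000)  # retains < 1000 draws
        samples = mcmc_sample(data, cfg, seed=1)
        with pytest.raises(ValueError, match="1000"):
            founder_posterior(samples, config=cfg)
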