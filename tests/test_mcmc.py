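"""Posterior MCMC: proposals, O(T) move evaluation, prior recovery,
posterior correctness, edge marginals, mean-field MI bound."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from graphdyn._util import log2sumexp
from graphdyn.dynamics import BinaryDynamics, TimeSeries, simulate
from graphdyn.dynamics import stacked_log_likelihood
from graphdyn.graphs import (
    ConfigurationModelPrior,
    ErdosRenyiPrior,
    LoopyMultigraph,
    SimpleGraph,
)
from graphdyn.mcmc import (
    MultigraphChain,
    SamplerConfig,
    SimpleGraphChain,
    edge_marginals,
    mf_mi_estimate,
    run_sampler,
)
from graphdyn.measures import exact_mc_mi


def flat_series(N, T=1):
    return TimeSeries(np.zeros((N, T), dtype=np.int8))


def make_er_chain(rng, N=5, E=5, T=20, J=1.0):
    prior = ErdosRenyiPrior(N, E)
    dyn = BinaryDynamics.glauber(J)
    g = prior.sample(rng)
    x = simulate(dyn, g, T, rng)
    return SimpleGraphChain(x, dyn, prior, prior.sample(rng)), prior, dyn, x


class TestHingeFlip:
    def test_triangle_has_no_valid_moves(self, rng):
        # the complete graph on 3 vertices is the only simple graph with
        # N = 3, E = 3: every proposal makes a self-loop or multiedge
        prior = ErdosRenyiPrior(3, 3)
        g = next(iter(prior.support()))
        chain = SimpleGraphChain(flat_series(3, 2), BinaryDynamics.glauber(0.0), prior, g)
        for _ in range(200):
            move, _ = chain.propose(rng)
            assert move is None

    def test_single_edge_moves_enumerate(self, rng):
        prior = ErdosRenyiPrior(3, 1)
        g = SimpleGraph(3, frozenset({(0, 1)}))
        chain = SimpleGraphChain(flat_series(3, 2), BinaryDynamics.glauber(0.0), prior, g)
        seen = set()
        for _ in range(500):
            move, logq = chain.propose(rng)
            assert logq == 0.0
            if move is not None:
                seen.add(move[2])  # the proposed new edge
        assert seen == {(0, 2), (1, 2)}

    def test_edge_count_preserved(self, rng):
        chain, prior, _, _ = make_er_chain(rng)
        for _ in range(2000):
            chain.step(rng)
        assert chain.current_graph().edge_count == prior.E


class TestDoubleEdgeSwap:
    def test_four_path_swaps(self, rng):
        # edges {0-1, 2-3}: swaps lead to {0-2,1-3} or {0-3,1-2}
        prior = ConfigurationModelPrior((1, 1, 1, 1))
        g = LoopyMultigraph.from_dict(4, {(0, 1): 1, (2, 3): 1})
        chain = MultigraphChain(flat_series(4, 2), BinaryDynamics.glauber(0.0), prior, g)
        outcomes = set()
        for _ in range(300):
            move, logq = chain.propose(rng)
            assert logq == 0.0
            new = LoopyMultigraph.from_edge_instances(4, [move[4], move[5]])
            outcomes.add(new.multiedges)
        assert outcomes == {
            LoopyMultigraph.from_dict(4, {(0, 2): 1, (1, 3): 1}).multiedges,
            LoopyMultigraph.from_dict(4, {(0, 3): 1, (1, 2): 1}).multiedges,
        }

    def test_degrees_preserved_over_long_run(self, rng):
        prior = ConfigurationModelPrior((3, 2, 2, 2, 1))
        g = prior.sample(rng)
        chain = MultigraphChain(flat_series(5, 2), BinaryDynamics.glauber(0.0), prior, g)
        for _ in range(10000):
            chain.step(rng)
        assert tuple(chain.current_graph().degrees()) == prior.degrees

    def test_flat_likelihood_recovers_stub_matching_law(self, rng):
        # chi-square of long-run sample frequencies against the exact
        # multigraph probabilities on the enumerated k = (2,2,2) support
        prior = ConfigurationModelPrior((2, 2, 2))
        support = list(prior.support())
        probs = np.array([2.0 ** prior.log_prob(g) for g in support])
        key = {g.multiedges: i for i, g in enumerate(support)}
        res = run_sampler(
            flat_series(3), BinaryDynamics.glauber(0.0), prior,
            SamplerConfig(Q=6000, delta=3), rng,
        )
        counts = np.zeros(len(support))
        for s in res.graphs:
            counts[key[s.multiedges]] += 1
        assert chisquare(counts, probs * len(res.graphs)).pvalue > 0.01


class TestDeltaLogJoint:
    def test_matches_full_recomputation_simple(self, rng):
        chain, *_ = make_er_chain(rng, N=5, E=5, T=20, J=1.0)
        checked = 0
        while checked < 300:
            move, _ = chain.propose(rng)
            if move is None:
                continue
            before = chain.log_joint_from_scratch()
            delta = chain.delta_log_joint(move)
            # apply the move through step with a forced-accept replay:
            # verify against an independent chain built on the moved graph
            edges = list(chain.edges)
            edges[move[0]] = move[2]
            moved = SimpleGraph(chain.N, frozenset(edges))
            after = SimpleGraphChain(
                TimeSeries(chain.x), chain.dyn, chain.prior, moved
            ).log_joint_from_scratch()
            assert delta == pytest.approx(after - before, abs=1e-9)
            chain.step(rng)
            checked += 1

    def test_matches_full_recomputation_multigraph(self, rng):
        prior = ConfigurationModelPrior((3, 2, 2, 2, 1))
        dyn = BinaryDynamics.sis(lam=0.8)
        g = prior.sample(rng)
        x = simulate(dyn, g, 20, rng)
        chain = MultigraphChain(x, dyn, prior, g)
        for _ in range(300):
            move, _ = chain.propose(rng)
            before = chain.log_joint_from_scratch()
            delta = chain.delta_log_joint(move)
            instances = list(chain.instances)
            instances[move[0]] = move[4]
            instances[move[1]] = move[5]
            moved = LoopyMultigraph.from_edge_instances(chain.N, instances)
            after = MultigraphChain(
                TimeSeries(chain.x), dyn, prior, moved
            ).log_joint_from_scratch()
            if math.isfinite(before) and math.isfinite(after):
                assert delta == pytest.approx(after - before, abs=1e-9)
            chain.step(rng)

    def test_cache_stays_coherent_through_run(self, rng):
        chain, *_ = make_er_chain(rng, J=2.0)
        for i in range(500):
            if i % 50 == 0:
                assert chain.log_joint == pytest.approx(
                    chain.log_joint_from_scratch(), abs=1e-8
                )
            chain.step(rng)


class TestRunSampler:
    def test_t1_series_recovers_prior_marginals(self, rng):
        # no transitions -> flat likelihood -> posterior equals the prior;
        # each pair carries an edge with probability E / C(N,2)
        prior = ErdosRenyiPrior(5, 4)
        res = run_sampler(flat_series(5), BinaryDynamics.glauber(1.0), prior,
                          SamplerConfig(Q=2000, delta=3), rng)
        marg = edge_marginals(res.graphs)
        iu = np.triu_indices(5, k=1)
        expected = 4 / 10
        assert np.abs(marg.pi[iu].mean() - expected) < 0.02
        assert np.abs(marg.pi[iu] - expected).max() < 0.1

    def test_posterior_matches_enumeration(self, rng):
        prior = ErdosRenyiPrior(4, 3)
        dyn = BinaryDynamics.glauber(1.0)
        g = prior.sample(rng)
        x = simulate(dyn, g, 20, rng)
        graphs = list(prior.support())
        logp = np.array([prior.log_prob(gg) for gg in graphs])
        A = np.stack([gg.adjacency_matrix() for gg in graphs]).astype(float)
        ll = stacked_log_likelihood(dyn, A, x)
        post = np.exp2(logp + ll - log2sumexp(logp + ll))
        key = {gg.edges: i for i, gg in enumerate(graphs)}
        res = run_sampler(x, dyn, prior, SamplerConfig(Q=3000, delta=5), rng)
        freq = np.zeros(len(graphs))
        for s in res.graphs:
            freq[key[s.edges]] += 1
        freq /= freq.sum()
        assert 0.5 * np.abs(freq - post).sum() < 0.05

    def test_diagnostics_and_reproducibility(self):
        prior = ErdosRenyiPrior(4, 3)
        dyn = BinaryDynamics.glauber(0.5)
        g = prior.sample(np.random.default_rng(3))
        x = simulate(dyn, g, 15, np.random.default_rng(4))
        a = run_sampler(x, dyn, prior, SamplerConfig(Q=50), np.random.default_rng(5))
        b = run_sampler(x, dyn, prior, SamplerConfig(Q=50), np.random.default_rng(5))
        assert 0.0 < a.acceptance_rate < 1.0
        assert [g1.edges for g1 in a.graphs] == [g2.edges for g2 in b.graphs]


class TestEdgeMarginals:
    def test_identical_samples_clamp(self):
        g = SimpleGraph(3, frozenset({(0, 1)}))
        marg = edge_marginals([g] * 50)
        assert marg.pi[0, 1] == pytest.approx(1 - 1 / 51)
        assert marg.pi[0, 2] == pytest.approx(1 / 51)

    def test_two_graph_mixture_is_half(self):
        a = SimpleGraph(3, frozenset({(0, 1)}))
        b = SimpleGraph(3, frozenset({(0, 2)}))
        marg = edge_marginals([a, b] * 25)
        assert marg.pi[0, 1] == pytest.approx(0.5)
        assert marg.pi[0, 2] == pytest.approx(0.5)

    def test_multigraph_histograms_normalize(self, rng):
        prior = ConfigurationModelPrior((2, 2, 2))
        samples = [prior.sample(rng) for _ in range(40)]
        marg = edge_marginals(samples)
        for probs in marg.hist.values():
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        # unseen-edge log-probability stays finite for any in-support graph
        for g in prior.support():
            assert math.isfinite(marg.log_prob(g))

    def test_mixed_types_rejected(self):
        with pytest.raises(TypeError):
            edge_marginals(
                [SimpleGraph(2, frozenset({(0, 1)})),
                 LoopyMultigraph.from_dict(2, {(0, 1): 1})]
            )


class TestMeanFieldEstimate:
    def test_independent_dynamics_gives_prior_factorization_gap(self, rng):
        # J = 0: the posterior equals the prior, so the edge marginals all
        # approach E / C(N,2) = 1/2. Under the fixed-edge-count ensemble the
        # edges are *not* independent, so the factorized approximation pays
        # exactly H_MF - H_G = 6 - log2(20) bits: the bound is negative, as
        # the estimator's construction allows, rather than zero
        est = mf_mi_estimate(
            ErdosRenyiPrior(4, 3), BinaryDynamics.glauber(0.0), 10, 12,
            SamplerConfig(Q=300, delta=3), rng,
        )
        gap = math.log2(20) - 6.0
        assert est.value == pytest.approx(gap, abs=max(3 * est.se, 0.1))
        assert est.value <= 0 + 3 * est.se  # still a lower bound on I = 0

    def test_lower_bounds_exact_estimator(self, rng):
        prior = ErdosRenyiPrior(4, 3)
        dyn = BinaryDynamics.glauber(1.0)
        exact = exact_mc_mi(prior, dyn, 30, 400, rng)
        mf = mf_mi_estimate(prior, dyn, 30, 20, SamplerConfig(Q=400, delta=5), rng)
        assert mf.value <= exact.I + 3 * math.hypot(mf.se, exact.se["I"])


class TestPersistence:
    def test_posterior_archive_round_trip(self, tmp_path, rng):
        prior = ErdosRenyiPrior(4, 3)
        dyn = BinaryDynamics.glauber(0.5)
        g = prior.sample(rng)
        x = simulate(dyn, g, 10, rng)
        post = run_sampler(x, dyn, prior, SamplerConfig(Q=20, delta=2), rng)
        from graphdyn.mcmc import load_posterior_samples, save_posterior_samples

        path = tmp_path / "samples.txt"
        save_posterior_samples(post, path, metadata={"seed": 0})
        back = load_posterior_samples(path, N=4)
        assert [s.edges for s in back] == [s.edges for s in post.graphs]
        assert (tmp_path / "samples.txt.json").exists()

    def test_marginals_csv(self, tmp_path):
        from graphdyn.mcmc import marginals_to_csv

        marg = edge_marginals([SimpleGraph(3, frozenset({(0, 1)}))] * 10)
        path = tmp_path / "pi.csv"
        marginals_to_csv(marg, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "i,j,pi" and len(lines) == 4
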