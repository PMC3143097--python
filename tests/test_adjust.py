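"""Degree-aware adjustments: buckets, degree-matched nulls, z-scores,
centrality log-ratio."""

import numpy as np
import pytest

from netprio import (
    DiffusionConfig,
    DiseasePrior,
    ScoreVector,
    adjust_candidate_degree,
    adjust_centrality,
    adjust_seed_degree,
    assign_buckets,
    build_restart_vector,
    candidate_degree_peers,
    centrality,
    propagate,
    sample_degree_matched_seeds,
)

from conftest import make_random_network


def uniform_prior(seeds):
    return DiseasePrior("D", {s: 1.0 for s in seeds})


class TestBuckets:
    def test_partition_covers_all_nodes(self, random_net, rng):
        seeds = list(random_net.nodes[:4])
        ba = assign_buckets(random_net, seeds, rng)
        members = [g for b in ba.buckets.values() for g in b]
        assert sorted(members) == sorted(random_net.nodes)

    def test_each_seed_in_its_own_bucket(self, random_net, rng):
        seeds = list(random_net.nodes[:5])
        ba = assign_buckets(random_net, seeds, rng)
        for s in seeds:
            assert s in ba.buckets[s]

    def test_nearest_degree_brute_force(self, random_net, rng):
        seeds = list(random_net.nodes[::10])
        ba = assign_buckets(random_net, seeds, rng)
        owner = {g: s for s, members in ba.buckets.items() for g in members}
        for g in random_net.nodes:
            if g in seeds:
                continue
            dists = {
                s: abs(
                    random_net.weighted_degree(s)
                    - random_net.weighted_degree(g)
                )
                for s in seeds
            }
            best = min(dists.values())
            assert dists[owner[g]] == pytest.approx(best, abs=1e-12)

    def test_single_seed_owns_everything(self, random_net, rng):
        ba = assign_buckets(random_net, [random_net.nodes[0]], rng)
        assert len(ba.buckets[random_net.nodes[0]]) == random_net.n_nodes

    def test_tie_break_deterministic_per_seed(self, triangle):
        # all weighted degrees equal: every non-seed node is equidistant
        seeds = ["A", "B"]
        pick = lambda s: assign_buckets(
            triangle, seeds, np.random.default_rng(s)
        ).buckets
        assert pick(7) == pick(7)
        owners = {tuple(sorted(pick(s)["A"])) for s in range(30)}
        assert len(owners) > 1  # C lands in different buckets across rngs

    def test_empty_seed_set_rejected(self, random_net, rng):
        with pytest.raises(ValueError):
            assign_buckets(random_net, [], rng)


class TestSampler:
    def test_one_draw_per_bucket(self, random_net, rng):
        seeds = list(random_net.nodes[:6])
        ba = assign_buckets(random_net, seeds, rng)
        sampled = sample_degree_matched_seeds(ba, rng)
        assert set(sampled) == set(seeds)
        assert len(set(sampled.values())) <= len(seeds)
        assert all(v in ba.buckets[s] for s, v in sampled.items())

    def test_singleton_buckets_return_the_seeds(self, rng):
        net = make_random_network(30, rng)
        ba = assign_buckets(net, list(net.nodes), rng)
        sampled = sample_degree_matched_seeds(ba, rng)
        assert all(s == v for s, v in sampled.items())

    def test_mean_total_weighted_degree_matches_seeds(self, rng):
        net = make_random_network(500, rng, p=0.02)
        seeds = list(rng.choice(net.nodes, size=6, replace=False))
        ba = assign_buckets(net, seeds, rng)
        true_total = sum(net.weighted_degree(s) for s in seeds)
        totals = []
        for _ in range(1000):
            sampled = sample_degree_matched_seeds(ba, rng)
            totals.append(
                sum(net.weighted_degree(v) for v in sampled.values())
            )
        assert np.mean(totals) == pytest.approx(true_total, rel=0.05)


class TestSeedDegreeAdjustment:
    def test_z_score_matches_stored_replicates(self, rng):
        net = make_random_network(20, rng, p=0.3)
        prior = uniform_prior(net.nodes[:3])
        P = net.transition_matrix("RW")
        cfg = DiffusionConfig(r=0.3)
        scores, reps = adjust_seed_degree(
            net, prior, P, cfg, n=10,
            rng=np.random.default_rng(5), return_replicates=True,
        )
        alpha = propagate(P, build_restart_vector(prior, P.nodes), cfg)
        expected = (alpha.values - reps.mean(axis=0)) / np.maximum(
            reps.std(axis=0, ddof=1), 1e-12
        )
        np.testing.assert_array_equal(scores.values, expected)

    def test_reproducible_for_fixed_seed(self, rng):
        net = make_random_network(25, rng, p=0.25)
        prior = uniform_prior(net.nodes[:3])
        P = net.transition_matrix("RW")
        run = lambda: adjust_seed_degree(
            net, prior, P, n=5, rng=np.random.default_rng(11)
        ).values
        np.testing.assert_array_equal(run(), run())

    def test_degenerate_null_hits_sd_floor(self, rng):
        # every node a seed -> singleton buckets -> identical replicates
        net = make_random_network(15, rng, p=0.4)
        prior = uniform_prior(net.nodes)
        P = net.transition_matrix("RW")
        scores = adjust_seed_degree(net, prior, P, n=4, rng=rng)
        assert np.isfinite(scores.values).all()
        np.testing.assert_allclose(scores.values, 0.0, atol=1e-3)

    def test_needs_two_replicates(self, random_net, rng):
        prior = uniform_prior(random_net.nodes[:2])
        P = random_net.transition_matrix("RW")
        with pytest.raises(ValueError):
            adjust_seed_degree(random_net, prior, P, n=1, rng=rng)


class TestCandidateDegreeAdjustment:
    def test_matches_brute_force_peer_selection(self, rng):
        net = make_random_network(30, rng, p=0.25)
        prior = uniform_prior(net.nodes[:3])
        P = net.transition_matrix("RW")
        alpha = propagate(P, build_restart_vector(prior, P.nodes))
        out = adjust_candidate_degree(net, alpha, n=5)
        wd = {g: net.weighted_degree(g) for g in net.nodes}
        for g in net.nodes:
            peers = sorted(
                (abs(wd[g] - wd[u]), u) for u in net.nodes if u != g
            )[:5]
            sample = np.array([alpha[u] for _, u in peers])
            z = (alpha[g] - sample.mean()) / max(sample.std(ddof=1), 1e-12)
            assert out[g] == pytest.approx(z, abs=1e-12)

    def test_identical_degrees_preserve_ranking(self):
        # unit cycle: all W equal; peers = everyone else
        from netprio import load_network, rank_descending

        n = 12
        net = load_network(
            [(f"N{i:02d}", f"N{(i + 1) % n:02d}", 1.0) for i in range(n)]
        )
        prior = uniform_prior([net.nodes[0]])
        P = net.transition_matrix("RW")
        alpha = propagate(P, build_restart_vector(prior, P.nodes))
        out = adjust_candidate_degree(net, alpha, n=n - 1)
        raw_order = rank_descending(alpha, net.nodes).ordered()
        adj_order = rank_descending(out, net.nodes).ordered()
        assert raw_order == adj_order

    def test_affine_map_of_scores_is_invariant(self, rng):
        net = make_random_network(25, rng, p=0.25)
        prior = uniform_prior(net.nodes[:2])
        alpha = propagate(
            net.transition_matrix("RW"),
            build_restart_vector(prior, net.nodes),
        )
        shifted = ScoreVector(alpha.nodes, 3.0 * alpha.values + 0.7)
        a = adjust_candidate_degree(net, alpha, n=6)
        b = adjust_candidate_degree(net, shifted, n=6)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_peer_cache_matches_direct_call(self, rng):
        net = make_random_network(25, rng, p=0.25)
        prior = uniform_prior(net.nodes[:2])
        alpha = propagate(
            net.transition_matrix("RW"),
            build_restart_vector(prior, net.nodes),
        )
        peers = candidate_degree_peers(net, n=6)
        np.testing.assert_array_equal(
            adjust_candidate_degree(net, alpha, n=6).values,
            adjust_candidate_degree(net, alpha, n=6, peers=peers).values,
        )

    def test_needs_two_peers(self, random_net):
        alpha = ScoreVector(random_net.nodes, np.ones(random_net.n_nodes))
        with pytest.raises(ValueError):
            adjust_candidate_degree(random_net, alpha, n=1)


class TestCentralityAdjustment:
    def test_zero_when_score_equals_centrality(self, random_net):
        c = centrality(random_net)
        out = adjust_centrality(c, c)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_doubling_gives_log_two(self, random_net):
        c = centrality(random_net)
        doubled = ScoreVector(c.nodes, 2.0 * c.values)
        out = adjust_centrality(doubled, c, eps=0.0)
        np.testing.assert_allclose(out.values, np.log(2.0), atol=1e-12)

    def test_positive_scaling_shifts_by_log_k(self, random_net, rng):
        c = centrality(random_net)
        alpha = ScoreVector(c.nodes, rng.random(len(c.nodes)) + 0.1)
        base = adjust_centrality(alpha, c, eps=0.0)
        scaled = adjust_centrality(
            ScoreVector(c.nodes, 5.0 * alpha.values), c, eps=0.0
        )
        np.testing.assert_allclose(
            scaled.values - base.values, np.log(5.0), atol=1e-12
        )

    def test_negative_inputs_rejected(self, random_net):
        c = centrality(random_net)
        bad = ScoreVector(c.nodes, c.values - 1.0)
        with pytest.raises(ValueError):
            adjust_centrality(bad, c)
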