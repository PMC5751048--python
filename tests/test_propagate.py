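"""Propagation-engine tests against closed forms and linear-solve oracles."""

import numpy as np
import pytest

from hetprop import (
    EntitySubnetwork,
    HeterogeneousNetwork,
    PropagationConfig,
    RelationSubnetwork,
    ScoreVector,
    across_propagate,
    correlation,
    find_paths,
    generate,
    prioritize,
    target_profiles,
    within_propagate,
)
from hetprop.propagate import _arrival_for_path
from hetprop.synthetic import FixtureSpec

from conftest import random_entity


def dense_solve(net, f0, alpha):
    """Oracle: direct solution of (I - alpha*S) F = (1 - alpha) F0."""
    S = net.normalized
    return np.linalg.solve(
        np.eye(len(net)) - alpha * S, (1 - alpha) * np.asarray(f0)
    )


class TestWithinPropagate:
    def test_two_node_closed_form(self):
        net = EntitySubnetwork("A", ["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
        cfg = PropagationConfig(alpha=0.5, tol=1e-12)
        out = within_propagate(net, ScoreVector("A", [1.0, 0.0]), cfg)
        assert np.allclose(out.values, [2 / 3, 1 / 3], atol=1e-9)

    def test_isolated_seeded_node_fixed_point(self):
        # a zero-degree node has a zero row in S, so the stationary value
        # is the restart term (1 - alpha) * F0 and total mass leaks to 1-a
        net = EntitySubnetwork("A", ["a"], np.zeros((1, 1)))
        cfg = PropagationConfig(alpha=0.3, tol=1e-12)
        out = within_propagate(net, ScoreVector("A", [2.0]), cfg)
        assert np.allclose(out.values, [0.7], atol=1e-10)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_linear_solve_oracle(self, alpha, seed):
        rng = np.random.default_rng(seed)
        net = random_entity(rng.integers(3, 21), rng)
        f0 = np.zeros(len(net))
        f0[rng.integers(len(net))] = 1.0
        cfg = PropagationConfig(alpha=alpha, tol=1e-12, max_iter=20000)
        out = within_propagate(net, ScoreVector("X", f0), cfg)
        expected = dense_solve(net, f0, alpha)
        assert np.abs(out.values - expected).sum() < 1e-8

    def test_mass_bounded_by_one(self):
        rng = np.random.default_rng(11)
        net = random_entity(15, rng, density=0.3)
        seed = ScoreVector("X", rng.random(15))
        out = within_propagate(net, seed, PropagationConfig())
        assert np.all(out.values >= -1e-12)
        assert out.values.sum() <= 1 + 1e-9

    def test_all_zero_seed_rejected(self):
        net = random_entity(4, np.random.default_rng(0))
        with pytest.raises(ValueError, match="all zero"):
            within_propagate(net, ScoreVector("X", np.zeros(4)),
                             PropagationConfig())

    def test_non_convergence_warns_and_returns(self):
        net = random_entity(10, np.random.default_rng(1))
        cfg = PropagationConfig(alpha=0.9, tol=1e-14, max_iter=2)
        with pytest.warns(UserWarning, match="did not converge"):
            out = within_propagate(
                net, ScoreVector("X", np.ones(10)), cfg
            )
        assert np.all(np.isfinite(out.values))


class TestAcrossPropagate:
    def test_single_unit_edge_transfers_value(self):
        rel = RelationSubnetwork("A", "B", np.array([[1.0]]))
        out = across_propagate(rel, ScoreVector("A", [0.42]), forward=True)
        assert np.isclose(out.values[0], 0.42)
        assert out.subnet == "B"

    def test_all_zero_values_stay_zero(self):
        rel = RelationSubnetwork("A", "B", np.ones((3, 2)))
        out = across_propagate(rel, ScoreVector("A", np.zeros(3)))
        assert np.all(out.values == 0)

    def test_random_bipartite_against_sum_oracle(self):
        rng = np.random.default_rng(5)
        w = rng.random((3, 2))
        rel = RelationSubnetwork("A", "B", w)
        v = rng.random(3)
        out = across_propagate(rel, ScoreVector("A", v), forward=True)
        n = rel.normalized
        expected = [sum(n[i, j] * v[i] for i in range(3)) for j in range(2)]
        assert np.allclose(out.values, expected, atol=1e-12)
        # reverse orientation transposes the table
        u = rng.random(2)
        back = across_propagate(rel, ScoreVector("B", u), forward=False)
        expected_back = [sum(n[i, j] * u[j] for j in range(2))
                         for i in range(3)]
        assert np.allclose(back.values, expected_back, atol=1e-12)

    def test_alignment_mismatch_rejected(self):
        rel = RelationSubnetwork("A", "B", np.ones((3, 2)))
        with pytest.raises(ValueError, match="aligned"):
            across_propagate(rel, ScoreVector("B", np.zeros(2)), forward=True)


class TestCorrelation:
    @pytest.mark.parametrize(
        "u, v, kind, expected",
        [
            ([1, 2, 3], [1, 2, 3], "pearson", 1.0),
            ([1, 2, 3], [4, 2, 0], "pearson", -1.0),  # v = -2u + 6
            ([1, 2, 3, 4], [2, 1, 4, 3], "pearson", 0.6),
            ([1, 2, 3, 4], [2, 1, 4, 3], "spearman", 0.6),
            ([1, 1, 1], [1, 2, 3], "pearson", 0.0),  # zero variance
        ],
    )
    def test_known_values(self, u, v, kind, expected):
        assert correlation(np.array(u, float), np.array(v, float),
                           kind) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correlation(np.ones(3), np.ones(4))


class TestPrioritize:
    def test_planted_target_ranked_first(self):
        spec = FixtureSpec(sizes=(5, 5, 5), planted=((0, 2, 1.0),),
                           noise=0.0)
        net = generate(spec)
        target_label = net.entity("C").labels[2]
        result = prioritize(net, [net.entity("A").labels[0]], "A", "C")
        assert result.rows[0][0] == target_label
        assert result.rows[0][1] == pytest.approx(1.0, abs=1e-6)

    def test_end_to_end_against_dense_recomputation(self, planted_chain):
        """Exhaustive recomputation of the whole pipeline with dense solves."""
        net = planted_chain
        cfg = PropagationConfig(tol=1e-12, max_iter=20000)
        query = [net.entity("A").labels[0]]
        result = prioritize(net, query, "A", "C", cfg)

        # independent pipeline: linear solves instead of iteration
        def solve(entity, f0):
            return dense_solve(entity, np.asarray(f0) / np.sum(f0), cfg.alpha)

        arrivals = []
        for path in find_paths(net, "A", "C", cfg.max_path_len):
            f = np.zeros(len(net.entity("A")))
            f[0] = 1.0
            f = solve(net.entity("A"), f)
            for hop, (rel_name, forward) in enumerate(path.relation_refs):
                rel = next(r for r in net.relations if r.name == rel_name)
                table = rel.normalized.T if forward else rel.normalized
                f = table @ f
                if f.sum() == 0:
                    f = np.zeros(len(net.entity(path.entity_names[-1])))
                    break
                f = solve(net.entity(path.entity_names[hop + 1]), f)
            if f.max() > 0:
                f = f / f.max()
            arrivals.append(f)
        combined = np.mean(arrivals, axis=0)
        dst = net.entity("C")
        profiles = np.column_stack(
            [solve(dst, np.eye(len(dst))[t]) for t in range(len(dst))]
        )
        scores = [correlation(combined, profiles[:, t])
                  for t in range(len(dst))]
        expected = sorted(
            range(len(dst)), key=lambda t: (-scores[t], dst.labels[t])
        )
        assert [r[0] for r in result.rows] == [dst.labels[t]
                                               for t in expected]
        by_label = dict(result.rows)
        for t in range(len(dst)):
            assert by_label[dst.labels[t]] == pytest.approx(
                scores[t], abs=1e-6
            )

    def test_degenerate_arrival_flagged_and_tie_broken(self):
        a = EntitySubnetwork("A", ["a0", "a1"], np.zeros((2, 2)))
        c = EntitySubnetwork("C", ["c1", "c0", "c2"], np.zeros((3, 3)))
        # query node a1 has no cross edges at all: nothing arrives
        rel = RelationSubnetwork("A", "C",
                                 np.array([[0.0, 1.0, 0.0],
                                           [0.0, 0.0, 0.0]]))
        net = HeterogeneousNetwork([a, c], [rel])
        result = prioritize(net, ["a1"], "A", "C")
        assert result.degenerate
        assert [r[0] for r in result.rows] == ["c0", "c1", "c2"]
        assert all(score == 0 for _, score in result.rows)

    def test_query_set_additivity_of_arrival(self, planted_chain):
        """Seed linearity of the fixed-point operator.

        The pipeline without intermediate seed renormalization is linear,
        so the multi-query arrival equals the mean of singleton arrivals
        exactly.  The engine renormalizes arrival values to a unit-sum
        seed at each subnetwork, which rescales each path arrival by a
        scalar without changing its direction — so the engine's arrival
        must be proportional to the linear operator's.
        """
        net = planted_chain
        cfg = PropagationConfig(tol=1e-12, max_iter=20000)
        src = net.entity("A")
        labels = src.labels[:3]
        (path, *_) = find_paths(net, "A", "C", 3)

        def linear_arrival(f):
            out = dense_solve(src, np.asarray(f), cfg.alpha)
            for hop, (rel_name, forward) in enumerate(path.relation_refs):
                rel = next(r for r in net.relations if r.name == rel_name)
                table = rel.normalized.T if forward else rel.normalized
                out = table @ out
                nxt = net.entity(path.entity_names[hop + 1])
                out = np.linalg.solve(
                    np.eye(len(nxt)) - cfg.alpha * nxt.normalized,
                    (1 - cfg.alpha) * out,
                )
            return out

        def unit(v):
            return v / np.linalg.norm(v)

        seeds = [np.eye(len(src))[src.index(q)] for q in labels]
        merged_linear = linear_arrival(np.mean(seeds, axis=0))
        singles_linear = np.mean([linear_arrival(s) for s in seeds], axis=0)
        assert np.abs(merged_linear - singles_linear).max() < 1e-12

        seed = np.mean(seeds, axis=0)
        engine = _arrival_for_path(net, path, ScoreVector("A", seed), cfg)
        assert np.abs(unit(engine) - unit(merged_linear)).max() < 1e-8

    def test_automorphic_targets_score_equally(self):
        # mirror-symmetric fixture: two targets in symmetric positions
        a = EntitySubnetwork("A", ["q"], np.zeros((1, 1)))
        c = EntitySubnetwork(
            "C", ["t1", "t2", "m"],
            np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]]),
        )
        rel = RelationSubnetwork("A", "C", np.array([[1.0, 1.0, 0.0]]))
        net = HeterogeneousNetwork([a, c], [rel])
        result = prioritize(net, ["q"], "A", "C",
                            PropagationConfig(tol=1e-13, max_iter=50000))
        by_label = dict(result.rows)
        assert abs(by_label["t1"] - by_label["t2"]) < 1e-10

    def test_monotonicity_in_relation_weight(self):
        """Raising a query-target weight never lowers the target arrival.

        The query subnetwork carries no within-type edges, so the arrival
        at the target is driven solely by the query's own relation row; a
        stronger query-target cell then provably keeps or raises it.
        """
        rng = np.random.default_rng(2)
        a = EntitySubnetwork("A", [f"a{i}" for i in range(6)],
                             np.zeros((6, 6)))
        c = random_entity(6, rng, name="C")
        base = rng.random((6, 6)) * 0.3
        previous = -np.inf
        for w in [0.0, 0.2, 0.5, 0.9]:
            table = base.copy()
            table[0, 3] = w
            net = HeterogeneousNetwork(
                [a, c], [RelationSubnetwork("A", "C", table)]
            )
            (path,) = find_paths(net, "A", "C", 2)
            seed = np.zeros(6)
            seed[0] = 1.0
            arr = _arrival_for_path(
                net, path, ScoreVector("A", seed),
                PropagationConfig(tol=1e-12),
            )
            assert arr[3] >= previous - 1e-12
            previous = arr[3]

    def test_repeated_runs_bit_identical(self, planted_chain):
        r1 = prioritize(planted_chain, ["0"], "A", "C")
        r2 = prioritize(planted_chain, ["0"], "A", "C")
        assert r1.rows == r2.rows

    def test_unknown_query_label_listed(self, planted_chain):
        with pytest.raises(KeyError, match="zz"):
            prioritize(planted_chain, ["0", "zz"], "A", "C")

    def test_profiles_cached_per_config(self, planted_chain):
        dst = planted_chain.entity("C")
        cfg = PropagationConfig()
        p1 = target_profiles(dst, cfg)
        p2 = target_profiles(dst, cfg)
        assert p1 is p2
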