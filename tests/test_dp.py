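"""Dynamic program: correctness against the exhaustive oracle, pruning
soundness, timing constraints, backtracking, switch compatibility."""

import math
import time

import numpy as np
import pytest

from cophyrec import (AssociationMap, CophySystem, CostVector,
                      NoReconstructionError, TimingAnnotation, backtrack,
                      brute_force_min, check_switch_compatibility, compute_dp,
                      mirror_system, parse_newick, random_system, reconstruct,
                      timing_feasible)
from cophyrec.events import events_for_mapping

INF = math.inf


def _random_cases(n_cases, seed, max_leaves=6):
    rng = np.random.default_rng(seed)
    for i in range(n_cases):
        nh = int(rng.integers(2, max_leaves + 1))
        npar = int(rng.integers(2, max_leaves + 1))
        sys_ = random_system(nh, npar, -1.0, seed=int(rng.integers(2**31)))
        if i % 3 == 0:  # mixed-sign costs every third case
            costs = CostVector(*rng.uniform(-2, 3, 4))
        else:
            costs = CostVector(*rng.uniform(0.01, 1, 4))
        yield sys_, costs


class TestDPOptimum:
    def test_toy_minimum_matches_oracle(self, toy, default_costs):
        rec = reconstruct(toy.system, default_costs)
        oracle = brute_force_min(toy.system, default_costs)
        assert rec.total_cost == oracle.total_cost == 6
        # the depicted reconstruction is valid but costs one unit more
        _, depicted_cost = events_for_mapping(toy.system, toy.depicted_mapping,
                                              default_costs)
        assert depicted_cost == 7

    def test_leaf_base_case(self, default_costs):
        host = parse_newick("(x,y)r;")
        par = parse_newick("p;")
        sys_ = CophySystem(host, par, AssociationMap({("p", "x")}))
        table = compute_dp(sys_, default_costs)
        x = host.node_by_label("x")
        assert table.C[0][x] == 0
        assert all(c == INF for h, c in enumerate(table.C[0]) if h != x)

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_mirror_system_is_all_cospeciation(self, n):
        """Identical topologies + identity phi + cheap cospeciation:
        the optimum uses n-1 cospeciations and nothing else."""
        sys_ = mirror_system(n, seed=n)
        rec = reconstruct(sys_, CostVector(1, 10, 10, 10))
        assert rec.events.co == n - 1
        assert rec.events.total() == n - 1
        assert rec.total_cost == n - 1

    def test_oracle_equivalence_random_systems(self):
        for sys_, costs in _random_cases(60, seed=20):
            dp = reconstruct(sys_, costs)
            bf = brute_force_min(sys_, costs)
            assert dp.total_cost == pytest.approx(bf.total_cost, abs=1e-9)

    def test_pruned_and_naive_tables_identical(self):
        for sys_, costs in _random_cases(25, seed=21, max_leaves=5):
            tp = compute_dp(sys_, costs, "pruned")
            tn = compute_dp(sys_, costs, "naive")
            for p in range(sys_.parasite.n_nodes):
                for h in range(sys_.host.n_nodes):
                    assert tp.C[p][h] == pytest.approx(tn.C[p][h], abs=1e-9)

    def test_cost_scaling_invariance(self):
        """Scaling the cost vector by lambda > 0 scales every finite table
        entry by lambda and leaves the reported mapping unchanged."""
        lam = 3.5
        for sys_, costs in _random_cases(10, seed=22):
            t1 = compute_dp(sys_, costs)
            t2 = compute_dp(sys_, costs.scaled(lam))
            for p in range(sys_.parasite.n_nodes):
                for h in range(sys_.host.n_nodes):
                    a, b = t1.C[p][h], t2.C[p][h]
                    if a == INF:
                        assert b == INF
                    else:
                        assert b == pytest.approx(lam * a, abs=1e-9)
            r1 = backtrack(sys_, t1, costs)
            r2 = backtrack(sys_, t2, costs.scaled(lam))
            assert r1.mapping == r2.mapping

    def test_backtrack_deterministic_and_consistent(self, toy, default_costs):
        recs = [reconstruct(toy.system, default_costs) for _ in range(3)]
        assert recs[0].mapping == recs[1].mapping == recs[2].mapping
        events, cost = events_for_mapping(toy.system, recs[0].mapping,
                                          default_costs)
        assert events == recs[0].events
        assert cost == recs[0].total_cost

    def test_reconstruction_total_cost_is_event_sum(self):
        for sys_, costs in _random_cases(20, seed=23):
            rec = reconstruct(sys_, costs)
            assert rec.total_cost == pytest.approx(rec.events.cost(costs), abs=1e-9)


class TestTiming:
    def _timed_toy(self, toy, root_interval):
        host, par = toy.system.host, toy.system.parasite
        hz = {v: host.depth[v] for v in range(host.n_nodes)}
        pz = {v: (0, 3) for v in range(par.n_nodes)}
        pz[par.root] = root_interval
        ann = TimingAnnotation(hz, pz)
        return CophySystem(host, par, toy.system.phi, ann)

    def test_zone_containment(self, toy):
        sys_ = self._timed_toy(toy, (1, 2))
        par, host = sys_.parasite, sys_.host
        assert timing_feasible(sys_, par.root, host.node_by_label("h5")) == 0
        assert timing_feasible(sys_, par.root, host.root) == INF

    def test_unannotated_system_is_unconstrained(self, toy):
        assert timing_feasible(toy.system, 0, 0) == 0

    def test_output_respects_timing(self, toy, default_costs):
        sys_ = self._timed_toy(toy, (1, 2))  # root must sit in zone 1 or 2
        rec = reconstruct(sys_, default_costs)
        for p, h in rec.mapping.items():
            assert timing_feasible(sys_, p, h) == 0

    def test_overconstrained_timing_raises(self, toy, default_costs):
        host, par = toy.system.host, toy.system.parasite
        hz = {v: host.depth[v] for v in range(host.n_nodes)}
        pz = {v: (9, 9) for v in range(par.n_nodes)}  # no host zone reaches 9
        sys_ = CophySystem(host, par, toy.system.phi, TimingAnnotation(hz, pz))
        with pytest.raises(NoReconstructionError):
            reconstruct(sys_, default_costs)


class TestSwitchCompatibility:
    def test_switch_free_reconstruction_is_compatible(self, toy, default_costs):
        _, cost = events_for_mapping(toy.system, toy.depicted_mapping, default_costs)
        assert math.isfinite(cost)
        from cophyrec.dp import Reconstruction
        from cophyrec.events import EventCounts
        rec = Reconstruction(toy.depicted_mapping, EventCounts(2, 3, 1, 0), cost)
        assert check_switch_compatibility(toy.system, rec) is True

    def test_optimal_toy_reconstruction_is_compatible(self, toy, default_costs):
        rec = reconstruct(toy.system, default_costs)
        assert check_switch_compatibility(toy.system, rec) is True

    def test_crossing_switches_are_incompatible(self):
        """Two switches whose take-off/landing constraints order two host
        lineages both before and after one another."""
        host = parse_newick("((a11,a12)a1,(b11,b12)b1)r;")
        par = parse_newick("((x1,x2)p,(y1,y2)q)root;")
        phi = AssociationMap({("x1", "a11"), ("x2", "b11"),
                              ("y1", "b12"), ("y2", "a11")})
        sys_ = CophySystem(host, par, phi)
        lab = {"p": "a1", "q": "b1", "root": "r",
               "x1": "a11", "x2": "b11", "y1": "b12", "y2": "a11"}
        mapping = {par.node_by_label(k): host.node_by_label(v)
                   for k, v in lab.items()}
        costs = CostVector(1, 1, 1, 1)
        events, cost = events_for_mapping(sys_, mapping, costs)
        assert math.isfinite(cost) and events.hs == 2
        from cophyrec.dp import Reconstruction
        rec = Reconstruction(mapping, events, cost)
        assert check_switch_compatibility(sys_, rec) is False


def test_runtime_scales_no_worse_than_cubic():
    """Doubling smoke test: quadrupling the leaf count must not blow past
    the ~64x a cubic algorithm would cost (generous constant slack)."""
    def best_time(n):
        sys_ = random_system(n, n, -1.0, seed=1)
        costs = CostVector(1, 1, 2, 4)
        best = INF
        for _ in range(3):
            t0 = time.perf_counter()
            reconstruct(sys_, costs)
            best = min(best, time.perf_counter() - t0)
        return best

    t15, t60 = best_time(15), best_time(60)
    assert t60 / t15 < 64
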