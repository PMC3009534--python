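"""Dynamic program for cost-minimal cophylogenetic reconstruction.

``compute_dp`` fills the table C[p][h] = cheapest cost of mapping parasite
node p onto host node h, bottom-up over the parasite tree.  The pruned
method exploits dominance: for a fixed parent host h, candidate child
hosts within one of the four partitions {subtree(h.1), subtree(h.2), {h},
remaining nodes} differ only in their sorting-path cost, so only the
per-partition minimum can take part in an optimal combination.  The naive
method scans all host pairs and exists to cross-check the pruning.

``brute_force_min`` is an independent exhaustive oracle for small systems.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Optional

import networkx as nx

from .events import CostVector, EventCounts, events_for_mapping, triple_cost
from .trees import CophySystem, ValidationError

INF = math.inf

# deterministic preference when interpretations tie on cost
_RANK_CO, _RANK_DU, _RANK_HS = 0, 1, 2


class NoReconstructionError(ValueError):
    """Every root placement is infeasible (e.g. timing over-constrained)."""


def timing_feasible(sys: CophySystem, p: int, h: int) -> float:
    """0 when the association (p, h) is allowed by the timing annotation, inf otherwise.

    Systems without timing annotation are unconstrained (always 0).
    """
    if sys.timing is None:
        return 0.0
    try:
        zone = sys.timing.host_zone[h]
        lo, hi = sys.timing.parasite_interval[p]
    except KeyError as exc:
        raise ValidationError(f"missing time zone for node: {exc}") from exc
    return 0.0 if lo <= zone <= hi else INF


@dataclass
class DPTable:
    """Cost table and argmin records of the reconciliation DP."""

    C: list  # C[p][h] -> float
    choice: dict  # (p, h) -> (h1, h2) child host choices, internal p only
    method: str = "pruned"

    def root_row(self) -> list:
        return self.C[0]


@dataclass
class Reconstruction:
    """A total parasite-to-host mapping with its induced events and cost."""

    mapping: dict  # parasite node id -> host node id
    events: EventCounts
    total_cost: float

    def cospeciations(self) -> int:
        return self.events.co

    def to_json(self, sys: CophySystem, compatible: Optional[bool] = None) -> dict:
        par, host = sys.parasite, sys.host
        out = {
            "mapping": {par._name(p): host._name(h)
                        for p, h in sorted(self.mapping.items())},
            "events": self.events.as_dict(),
            "total_cost": self.total_cost,
        }
        if compatible is not None:
            out["compatible"] = compatible
        return out


def _leaf_row(sys: CophySystem, p: int) -> list:
    hosts = sys.leaf_host_ids(p)
    row = [INF] * sys.host.n_nodes
    for h in hosts:
        row[h] = 0.0 + timing_feasible(sys, p, h)
    return row


def _subtree_min(host, values) -> tuple[list, list]:
    """Per-node (min value, argmin id) over each node's subtree; ties -> smallest id."""
    best = list(values)
    arg = list(range(host.n_nodes))
    for v in host.postorder():
        for c in host.children[v]:
            if best[c] < best[v] or (best[c] == best[v] and arg[c] < arg[v]):
                best[v], arg[v] = best[c], arg[c]
    return best, arg


def _outside_min(host, values) -> tuple[list, list]:
    """Per-node min of ``values`` over hosts that are neither in the node's
    subtree nor among its ancestors (valid host-switch landing sites)."""
    sub_best, sub_arg = _subtree_min(host, values)
    best = [INF] * host.n_nodes
    arg = [-1] * host.n_nodes
    for v in host.preorder():
        if host.is_leaf(v):
            continue
        a, b = host.children[v]
        for child, sib in ((a, b), (b, a)):
            cb, ca = best[v], arg[v]
            if sub_best[sib] < cb or (sub_best[sib] == cb and sub_arg[sib] < ca):
                cb, ca = sub_best[sib], sub_arg[sib]
            best[child], arg[child] = cb, ca
    return best, arg


def _combine(host, h, cand1, cand2, costs: CostVector):
    """Best (cost, h1, h2) over candidate pairs at parent host h.

    Candidates are (kind, value, host_id) with kind one of
    'sub1'/'sub2'/'self' (in-subtree; value already includes the sorting
    path from h) or 'rest' (switch landing; no sortings).  Deterministic
    tie-break: cost, then cospeciation < duplication < switch, then ids.
    """
    best = (INF, 99, -1, -1)
    for (k1, v1, a1), (k2, v2, a2) in itertools.product(cand1, cand2):
        if v1 == INF or v2 == INF:
            continue
        base = v1 + v2
        if k1 == "rest" and k2 == "rest":
            continue
        if k1 == "rest" or k2 == "rest":
            cand = (base + costs.hs, _RANK_HS, a1, a2)
            if cand < best:
                best = cand
            continue
        # both inside subtree(h): duplication, maybe cospeciation
        cand = (base + costs.du, _RANK_DU, a1, a2)
        if cand < best:
            best = cand
        if {k1, k2} == {"sub1", "sub2"}:
            cand = (base + costs.co - 2 * costs.so, _RANK_CO, a1, a2)
            if cand < best:
                best = cand
    return best


def _candidates_pruned(sys, h, row, sub_a, arg_a, out_c, arg_c, c_so):
    host = sys.host
    depth_term = host.depth[h] * c_so
    cands = [("self", row[h], h), ("rest", out_c[h], arg_c[h])]
    if not host.is_leaf(h):
        c1, c2 = host.children[h]
        cands.append(("sub1", sub_a[c1] - depth_term, arg_a[c1]))
        cands.append(("sub2", sub_a[c2] - depth_term, arg_a[c2]))
    return cands


def compute_dp(sys: CophySystem, costs: CostVector, method: str = "pruned") -> DPTable:
    """Fill the reconciliation cost table over all (parasite, host) pairs.

    method='pruned' uses the dominance partition (linear candidate scan per
    parent host); method='naive' minimises over all host pairs directly.
    Both produce identical cost tables.
    """
    host, par = sys.host, sys.parasite
    if method not in ("pruned", "naive"):
        raise ValueError(f"unknown DP method {method!r}")
    n_h = host.n_nodes
    C: list = [None] * par.n_nodes
    choice: dict = {}
    for p in par.postorder():
        if par.is_leaf(p):
            C[p] = _leaf_row(sys, p)
            continue
        k1, k2 = par.children[p]
        row = [INF] * n_h
        if method == "pruned":
            a1 = [C[k1][h] + host.depth[h] * costs.so for h in range(n_h)]
            a2 = [C[k2][h] + host.depth[h] * costs.so for h in range(n_h)]
            sub1, sarg1 = _subtree_min(host, a1)
            sub2, sarg2 = _subtree_min(host, a2)
            out1, oarg1 = _outside_min(host, C[k1])
            out2, oarg2 = _outside_min(host, C[k2])
            for h in range(n_h):
                z = timing_feasible(sys, p, h)
                if z == INF:
                    continue
                c1 = _candidates_pruned(sys, h, C[k1], sub1, sarg1, out1, oarg1, costs.so)
                c2 = _candidates_pruned(sys, h, C[k2], sub2, sarg2, out2, oarg2, costs.so)
                cost, _, h1, h2 = _combine(host, h, c1, c2, costs)
                if cost < INF:
                    row[h] = cost + z
                    choice[(p, h)] = (h1, h2)
        else:
            for h in range(n_h):
                z = timing_feasible(sys, p, h)
                if z == INF:
                    continue
                best = (INF, 99, -1, -1)
                for h1 in range(n_h):
                    if C[k1][h1] == INF:
                        continue
                    for h2 in range(n_h):
                        if C[k2][h2] == INF:
                            continue
                        tr = triple_cost(host, h, h1, h2, costs)
                        if not tr.feasible:
                            continue
                        rank = (_RANK_CO if tr.events.co else
                                _RANK_DU if tr.events.du else _RANK_HS)
                        cand = (C[k1][h1] + C[k2][h2] + tr.cost, rank, h1, h2)
                        if cand < best:
                            best = cand
                if best[0] < INF:
                    row[h] = best[0] + z
                    choice[(p, h)] = (best[2], best[3])
        C[p] = row
    return DPTable(C, choice, method)


def backtrack(sys: CophySystem, table: DPTable, costs: CostVector) -> Reconstruction:
    """Recover one cost-minimal reconstruction from the argmin records.

    The parasite root may map to any host node; ties between root hosts are
    broken by smallest preorder id.
    """
    par = sys.parasite
    root_row = table.C[par.root]
    best_h, best_c = -1, INF
    for h, c in enumerate(root_row):
        if c < best_c:
            best_h, best_c = h, c
    if best_h < 0:
        raise NoReconstructionError(
            "no valid reconstruction exists (timing constraints too strict?)")
    mapping: dict = {}
    stack = [(par.root, best_h)]
    while stack:
        p, h = stack.pop()
        mapping[p] = h
        if not par.is_leaf(p):
            h1, h2 = table.choice[(p, h)]
            k1, k2 = par.children[p]
            stack.append((k1, h1))
            stack.append((k2, h2))
    events, cost = events_for_mapping(sys, mapping, costs)
    return Reconstruction(mapping, events, cost)


def reconstruct(sys: CophySystem, costs: CostVector,
                method: str = "pruned") -> Reconstruction:
    """Convenience: compute_dp + backtrack."""
    return backtrack(sys, compute_dp(sys, costs, method), costs)


def enumerate_optimal_mappings(sys: CophySystem, costs: CostVector,
                               limit: int = 1000) -> Iterator[dict]:
    """Yield all cost-minimal mappings (diagnostics; small systems only).

    Walks the DP table re-expanding every argmin tie; stops after ``limit``
    mappings.
    """
    host, par = sys.host, sys.parasite
    table = compute_dp(sys, costs)
    root_row = table.C[par.root]
    opt = min(root_row)
    if opt == INF:
        raise NoReconstructionError("no valid reconstruction exists")
    tol = 1e-9 * max(1.0, abs(opt))

    def expand(p: int, h: int, partial: dict) -> Iterator[dict]:
        partial = dict(partial)
        partial[p] = h
        if par.is_leaf(p):
            yield partial
            return
        k1, k2 = par.children[p]
        target = table.C[p][h] - timing_feasible(sys, p, h)
        for h1 in range(host.n_nodes):
            if table.C[k1][h1] == INF:
                continue
            for h2 in range(host.n_nodes):
                if table.C[k2][h2] == INF:
                    continue
                tr = triple_cost(host, h, h1, h2, costs)
                if not tr.feasible:
                    continue
                if abs(table.C[k1][h1] + table.C[k2][h2] + tr.cost - target) > tol:
                    continue
                for m1 in expand(k1, h1, partial):
                    for m2 in expand(k2, h2, m1):
                        yield m2

    count = 0
    for h in range(host.n_nodes):
        if abs(root_row[h] - opt) > tol:
            continue
        for m in expand(par.root, h, {}):
            yield m
            count += 1
            if count >= limit:
                return


def brute_force_min(sys: CophySystem, costs: CostVector) -> Reconstruction:
    """Exhaustive minimum over all valid mappings (independent test oracle).

    Depth-first over parasite nodes in postorder; a branch is abandoned as
    soon as a triple becomes infeasible.  Refuses parasite trees with more
    than 8 internal nodes.
    """
    host, par = sys.host, sys.parasite
    internal = [p for p in range(par.n_nodes) if not par.is_leaf(p)]
    if len(internal) > 8:
        raise ValueError("brute force limited to parasite trees with <= 8 internal nodes")
    order = list(par.postorder())
    best: list = [INF, None]

    def choices(p: int):
        if par.is_leaf(p):
            return sorted(sys.leaf_host_ids(p))
        return range(host.n_nodes)

    def rec(i: int, mapping: dict, cost: float) -> None:
        if i == len(order):
            if cost < best[0]:
                best[0], best[1] = cost, dict(mapping)
            return
        p = order[i]
        for h in choices(p):
            z = timing_feasible(sys, p, h)
            if z == INF:
                continue
            add = z
            if not par.is_leaf(p):
                k1, k2 = par.children[p]
                tr = triple_cost(host, h, mapping[k1], mapping[k2], costs)
                if not tr.feasible:
                    continue
                add += tr.cost
            mapping[p] = h
            rec(i + 1, mapping, cost + add)
            del mapping[p]

    rec(0, {}, 0.0)
    if best[1] is None:
        raise NoReconstructionError("no valid reconstruction exists")
    events, cost = events_for_mapping(sys, best[1], costs)
    return Reconstruction(best[1], events, cost)


def check_switch_compatibility(sys: CophySystem, rec: Reconstruction) -> bool:
    """Conservative consistency check on the timing relations induced by switches.

    Each host switch asserts that its take-off host lineage and the edge
    above its landing host overlap in time.  Together with the ancestry
    order of the host tree these assertions form a directed
    happens-before graph; a directed cycle means no global timing can
    realize all switches simultaneously and the reconstruction is flagged
    incompatible.  Reconstructions without switches are always compatible.
    """
    htree, ptree = sys.host, sys.parasite
    g = nx.DiGraph()
    g.add_nodes_from(range(htree.n_nodes))
    for v in range(1, htree.n_nodes):
        g.add_edge(htree.parent[v], v)
    zero = CostVector(0, 0, 0, 0)
    for p in range(ptree.n_nodes):
        if ptree.is_leaf(p):
            continue
        h = rec.mapping[p]
        k1, k2 = ptree.children[p]
        h1, h2 = rec.mapping[k1], rec.mapping[k2]
        tr = triple_cost(htree, h, h1, h2, zero)
        if tr.events.hs != 1:
            continue
        landing = h1 if not htree.is_descendant(h1, h) else h2
        take_off = h
        # landing edge (parent(landing), landing] must overlap the
        # take-off lineage at take_off: each starts before the other ends
        if htree.parent[landing] is not None:
            g.add_edge(htree.parent[landing], take_off)
        if htree.parent[take_off] is not None:
            g.add_edge(htree.parent[take_off], landing)
    return nx.is_directed_acyclic_graph(g)
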