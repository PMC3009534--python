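"""Event inference for association triples.

The unit of event bookkeeping is the *association triple*: an internal
parasite node's host mapping together with the host mappings of its two
children.  Each triple implies exactly one speciation-type event
(cospeciation, duplication, or host switch) plus a number of sorting
events, and the cheapest interpretation is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .trees import CophySystem, PhyloTree, ValidationError

INF = math.inf

EVENT_NAMES = ("cospeciation", "sorting", "duplication", "hostswitch")


@dataclass(frozen=True)
class CostVector:
    """Per-event costs c = (c_co, c_so, c_du, c_hs).

    Plain reconstruction accepts any finite reals (negative cospeciation
    costs are in common use); the parameter-adaptive search additionally
    requires all components strictly positive.
    """

    co: float
    so: float
    du: float
    hs: float

    def as_tuple(self) -> tuple:
        return (self.co, self.so, self.du, self.hs)

    def require_positive(self) -> None:
        if any(c <= 0 for c in self.as_tuple()):
            raise ValueError(
                "parameter-adaptive costs must be strictly positive; "
                f"got {self.as_tuple()}"
            )

    def scaled(self, lam: float) -> "CostVector":
        return CostVector(self.co * lam, self.so * lam, self.du * lam, self.hs * lam)


@dataclass(frozen=True)
class EventCounts:
    """Counts of cospeciation, sorting, duplication and host-switch events."""

    co: int = 0
    so: int = 0
    du: int = 0
    hs: int = 0

    def __add__(self, other: "EventCounts") -> "EventCounts":
        return EventCounts(self.co + other.co, self.so + other.so,
                           self.du + other.du, self.hs + other.hs)

    def total(self) -> int:
        return self.co + self.so + self.du + self.hs

    def as_tuple(self) -> tuple:
        return (self.co, self.so, self.du, self.hs)

    def cost(self, costs: CostVector) -> float:
        return (self.co * costs.co + self.so * costs.so
                + self.du * costs.du + self.hs * costs.hs)

    def as_dict(self) -> dict:
        return dict(zip(EVENT_NAMES, self.as_tuple()))


@dataclass(frozen=True)
class TripleResult:
    cost: float
    events: EventCounts

    @property
    def feasible(self) -> bool:
        return math.isfinite(self.cost)


def triple_cost(host: PhyloTree, h: int, h1: int, h2: int,
                costs: CostVector) -> TripleResult:
    """Cheapest event set explaining (p -> h) with children at h1 and h2.

    Cases, in the order tested:

    * h a proper descendant of h1 or h2 -> infeasible (a child may never
      sit on a strict ancestor of its parent's host).
    * both children inside the subtree of h -> duplication plus one
      sorting per skipped host edge; when the children sit in *different*
      child subtrees of h the cospeciation reading (two of those edges
      absorbed by the joint speciation) is also available and the cheaper
      of the two is kept, cospeciation winning ties.
    * exactly one child inside -> host switch; the out-of-subtree child
      lands exactly at its mapped node and contributes no sortings.
    * neither child inside -> infeasible (untraceable double switch).
    """
    if host.is_proper_descendant(h, h1) or host.is_proper_descendant(h, h2):
        return TripleResult(INF, EventCounts())
    in1 = host.is_descendant(h1, h)
    in2 = host.is_descendant(h2, h)
    s1 = host.depth[h1] - host.depth[h] if in1 else 0
    s2 = host.depth[h2] - host.depth[h] if in2 else 0
    s = s1 + s2
    if in1 and in2:
        du_cost = costs.du + s * costs.so
        best = TripleResult(du_cost, EventCounts(so=s, du=1))
        if h1 != h and h2 != h:
            ch_a, ch_b = host.children[h]
            split = ((host.is_descendant(h1, ch_a) and host.is_descendant(h2, ch_b))
                     or (host.is_descendant(h1, ch_b) and host.is_descendant(h2, ch_a)))
            if split:
                co_cost = costs.co + (s - 2) * costs.so
                if co_cost <= du_cost:  # tie -> cospeciation
                    best = TripleResult(co_cost, EventCounts(co=1, so=s - 2))
        return best
    if in1 != in2:
        return TripleResult(costs.hs + s * costs.so, EventCounts(so=s, hs=1))
    return TripleResult(INF, EventCounts())


def events_for_mapping(sys: CophySystem, mapping: Mapping[int, int],
                       costs: CostVector) -> tuple[EventCounts, float]:
    """Aggregate events and total cost of a full parasite-to-host mapping.

    ``mapping`` must assign a host node id to every parasite node id.
    Returns (EventCounts(), inf) when any leaf violates phi or any triple
    is infeasible.
    """
    par = sys.parasite
    for v in range(par.n_nodes):
        if v not in mapping:
            raise ValidationError(
                f"mapping is partial: parasite node {par._name(v)} unmapped")
    total = EventCounts()
    cost = 0.0
    for v in range(par.n_nodes):
        if par.is_leaf(v):
            if mapping[v] not in sys.leaf_host_ids(v):
                return EventCounts(), INF
    for v in range(par.n_nodes):
        if par.is_leaf(v):
            continue
        c1, c2 = par.children[v]
        res = triple_cost(sys.host, mapping[v], mapping[c1], mapping[c2], costs)
        if not res.feasible:
            return EventCounts(), INF
        total = total + res.events
        cost += res.cost
    return total, cost
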