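"""Worked-example fixture and random system generator.

``toy_system`` is a four-host / four-parasite tanglegram small enough to
check every event count by hand: the parasite root duplicates on the host
root (two sortings down to its children's hosts), one parasite clade
cospeciates at the host root (one sorting), and the other tracks the
(hA, hB) host cherry exactly.  Its optimal reconstruction under costs
(1, 1, 2, 4) needs two cospeciations, one duplication and three sortings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import CostVector, EventCounts, events_for_mapping
from .randomize import beta_splitting_tree
from .trees import AssociationMap, CophySystem, PhyloTree, parse_newick

TOY_HOST_NEWICK = "(h2,(h3,(hA,hB)h4)h5)h1;"
TOY_PARASITE_NEWICK = "((p3,p4)p2,(pA,pB)p5)p1;"
TOY_ASSOCIATIONS = (("p3", "h2"), ("p4", "h3"), ("pA", "hA"), ("pB", "hB"))
#: host assignment of the internal parasite nodes in the depicted reconstruction
TOY_INTERNAL_MAPPING = (("p1", "h1"), ("p2", "h1"), ("p5", "h4"))
TOY_EVENT_COUNTS = EventCounts(co=2, so=3, du=1, hs=0)


@dataclass
class ToyExample:
    system: CophySystem
    depicted_mapping: dict  # parasite node id -> host node id

    def mapping_by_label(self) -> dict:
        par, host = self.system.parasite, self.system.host
        return {par._name(p): host._name(h)
                for p, h in sorted(self.depicted_mapping.items())}


def toy_system() -> ToyExample:
    """The worked four-taxon example with its depicted reconstruction."""
    host = parse_newick(TOY_HOST_NEWICK)
    parasite = parse_newick(TOY_PARASITE_NEWICK)
    phi = AssociationMap(frozenset(TOY_ASSOCIATIONS))
    sys = CophySystem(host, parasite, phi)
    mapping = {}
    for p_lab, h_lab in TOY_INTERNAL_MAPPING + TOY_ASSOCIATIONS:
        mapping[parasite.node_by_label(p_lab)] = host.node_by_label(h_lab)
    return ToyExample(sys, mapping)


def validate_toy() -> None:
    """Self-check: the depicted mapping induces exactly (2 co, 3 so, 1 du, 0 hs)."""
    toy = toy_system()
    events, _ = events_for_mapping(toy.system, toy.depicted_mapping,
                                   CostVector(1, 1, 2, 4))
    if events != TOY_EVENT_COUNTS:
        raise AssertionError(
            f"toy fixture is inconsistent: expected {TOY_EVENT_COUNTS}, got {events}")


def random_system(n_host_leaves: int, n_parasite_leaves: int,
                  beta: float = -1.0, seed: int = 0) -> CophySystem:
    """Random tanglegram: two beta-splitting trees plus uniform associations.

    Each parasite leaf is associated with exactly one uniformly chosen host
    leaf (multiple parasites may share a host).  Deterministic under seed.
    """
    if n_host_leaves < 1 or n_parasite_leaves < 1:
        raise ValueError("leaf counts must be >= 1")
    rng = np.random.default_rng(seed)
    host = beta_splitting_tree(
        n_host_leaves, beta, labels=[f"H{i + 1}" for i in range(n_host_leaves)],
        rng=rng)
    parasite = beta_splitting_tree(
        n_parasite_leaves, beta,
        labels=[f"P{i + 1}" for i in range(n_parasite_leaves)], rng=rng)
    hleaves = host.leaf_labels()
    pairs = frozenset(
        (p, hleaves[int(rng.integers(len(hleaves)))])
        for p in parasite.leaf_labels())
    return CophySystem(host, parasite, AssociationMap(pairs))


def mirror_system(n_leaves: int, beta: float = -1.0, seed: int = 0) -> CophySystem:
    """Perfectly cospeciating system: identical topologies, identity phi.

    The parasite tree is a label-for-label copy of the host tree, so the
    all-cospeciation reconstruction (n_leaves - 1 cospeciations, nothing
    else) is available and maximal.
    """
    rng = np.random.default_rng(seed)
    host = beta_splitting_tree(
        n_leaves, beta, labels=[f"H{i + 1}" for i in range(n_leaves)], rng=rng)
    parasite = PhyloTree(
        host.parent, host.children,
        [None if lab is None else lab.replace("H", "P") for lab in host.label])
    pairs = frozenset((f"P{i + 1}", f"H{i + 1}") for i in range(n_leaves))
    return CophySystem(host, parasite, AssociationMap(pairs))
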