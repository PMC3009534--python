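"""Rooted binary tree model, ancestry queries, and input parsing.

Trees are stored in flat arrays indexed by preorder id (root = 0), which
makes the ancestry and path-length queries used by the reconciliation
dynamic program O(1) after construction.  Newick parsing is delegated to
dendropy; branch lengths are read but carry no meaning here.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import dendropy

INF = math.inf


class TreeError(ValueError):
    """Structural problem with a tree (multifurcation, duplicate labels, ...)."""


class NewickParseError(ValueError):
    """Malformed Newick input; message carries the reader's position info."""


class ValidationError(ValueError):
    """Inconsistent association / timing input."""


class PhyloTree:
    """Rooted binary phylogenetic tree with preorder node ids.

    Every non-leaf node has exactly two children; multifurcating input is
    rejected at construction.  Leaf labels must be unique.  Interior labels
    are optional and preserved when present.
    """

    __slots__ = (
        "n_nodes", "parent", "children", "label", "depth",
        "_tin", "_tout", "_label_to_id",
    )

    def __init__(self, parent: Sequence[Optional[int]],
                 children: Sequence[tuple], label: Sequence[Optional[str]]):
        self.n_nodes = len(parent)
        self.parent = list(parent)
        self.children = [tuple(c) for c in children]
        self.label = list(label)
        if self.n_nodes == 0:
            raise TreeError("empty tree")
        if self.parent[0] is not None:
            raise TreeError("node 0 must be the root")
        for v in range(self.n_nodes):
            deg = len(self.children[v])
            if deg not in (0, 2):
                raise TreeError(
                    f"node {self._name(v)} has out-degree {deg}; "
                    "only rooted binary trees are supported"
                )
        # depth + Euler intervals for O(1) subtree tests
        self.depth = [0] * self.n_nodes
        self._tin = [0] * self.n_nodes
        self._tout = [0] * self.n_nodes
        timer = 0
        stack: list[tuple[int, bool]] = [(0, False)]
        seen = 0
        while stack:
            v, done = stack.pop()
            if done:
                self._tout[v] = timer
                timer += 1
                continue
            seen += 1
            self._tin[v] = timer
            timer += 1
            stack.append((v, True))
            for c in reversed(self.children[v]):
                if self.parent[c] != v:
                    raise TreeError("parent/child arrays inconsistent")
                self.depth[c] = self.depth[v] + 1
                stack.append((c, False))
        if seen != self.n_nodes:
            raise TreeError("tree is not connected")
        self._label_to_id: dict[str, int] = {}
        for v in range(self.n_nodes):
            lab = self.label[v]
            if self.is_leaf(v) and lab is None:
                raise TreeError(f"leaf node {v} has no label")
            if lab is not None:
                if lab in self._label_to_id:
                    raise TreeError(f"duplicate label {lab!r}")
                self._label_to_id[lab] = v

    # -- basic queries -------------------------------------------------

    @property
    def root(self) -> int:
        return 0

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def leaves(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.is_leaf(v)]

    def leaf_labels(self) -> list[str]:
        return [self.label[v] for v in self.leaves()]

    def node_by_label(self, lab: str) -> int:
        try:
            return self._label_to_id[lab]
        except KeyError:
            raise KeyError(f"no node labeled {lab!r}") from None

    def preorder(self) -> Iterator[int]:
        return iter(range(self.n_nodes))

    def postorder(self) -> Iterator[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return reversed(order)

    def _name(self, v: int) -> str:
        return self.label[v] if self.label[v] is not None else f"#{v}"

    def _check_id(self, v: int) -> None:
        if not (0 <= v < self.n_nodes):
            raise KeyError(f"node id {v} out of range")

    # -- ancestry ------------------------------------------------------

    def is_descendant(self, a: int, b: int) -> bool:
        """True iff ``a`` lies in the subtree rooted at ``b`` (descendant-or-self)."""
        self._check_id(a)
        self._check_id(b)
        return self._tin[b] <= self._tin[a] and self._tout[a] <= self._tout[b]

    def is_proper_descendant(self, a: int, b: int) -> bool:
        return a != b and self.is_descendant(a, b)

    def path_edge_count(self, anc: int, desc: int) -> float:
        """Edges on the anc-to-desc path; ``inf`` if desc is not under anc."""
        if not self.is_descendant(desc, anc):
            return INF
        return self.depth[desc] - self.depth[anc]

    def subtree(self, v: int) -> list[int]:
        """Node ids in the subtree rooted at v (preorder-contiguous)."""
        self._check_id(v)
        return [u for u in range(self.n_nodes)
                if self._tin[v] <= self._tin[u] and self._tout[u] <= self._tout[v]]

    # -- I/O -----------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            lab = self.label[v] or ""
            if self.is_leaf(v):
                return lab
            return "(" + ",".join(fmt(c) for c in self.children[v]) + ")" + lab

        return fmt(0) + ";"

    def __repr__(self) -> str:
        return f"PhyloTree({self.n_nodes} nodes, {len(self.leaves())} leaves)"


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick string into a :class:`PhyloTree`.

    A unary chain at the top (an outer pair of parentheses around a single
    named clade) is collapsed so that the named clade becomes the root.
    """
    if ";" not in text:
        raise NewickParseError("Newick string must be terminated by ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    node = dtree.seed_node
    # collapse a top-level unary chain (e.g. "((a,b)x);" -> root x)
    while len(node.child_nodes()) == 1:
        node = node.child_nodes()[0]
    return _from_dendropy(node)


def _from_dendropy(seed) -> PhyloTree:
    parent: list[Optional[int]] = []
    children: list[list[int]] = []
    label: list[Optional[str]] = []

    def visit(dnode, par: Optional[int]) -> int:
        my_id = len(parent)
        parent.append(par)
        children.append([])
        if dnode.taxon is not None:
            lab = dnode.taxon.label
        else:
            lab = dnode.label
        label.append(lab)
        for c in dnode.child_nodes():
            cid = visit(c, my_id)
            children[my_id].append(cid)
        return my_id

    visit(seed, None)
    return PhyloTree(parent, children, label)


@dataclass(frozen=True)
class AssociationMap:
    """Leaf-to-leaf host associations: set of (parasite label, host label)."""

    pairs: frozenset

    def __post_init__(self):
        object.__setattr__(self, "pairs", frozenset(self.pairs))

    def hosts_of(self, parasite_label: str) -> list[str]:
        return sorted(h for p, h in self.pairs if p == parasite_label)

    def host_degree_histogram(self, host: PhyloTree) -> dict[int, int]:
        """Number of host leaves carrying exactly k parasites, for every k."""
        deg = {lab: 0 for lab in host.leaf_labels()}
        for _, h in self.pairs:
            deg[h] += 1
        hist: dict[int, int] = {}
        for d in deg.values():
            hist[d] = hist.get(d, 0) + 1
        return hist

    def validate(self, host: PhyloTree, parasite: PhyloTree) -> None:
        hleaves = set(host.leaf_labels())
        pleaves = set(parasite.leaf_labels())
        for p, h in self.pairs:
            if p not in pleaves:
                raise ValidationError(f"unknown parasite leaf {p!r} in association")
            if h not in hleaves:
                raise ValidationError(f"unknown host leaf {h!r} in association")
        uncovered = pleaves - {p for p, _ in self.pairs}
        if uncovered:
            raise ValidationError(
                f"parasite leaves without any host association: {sorted(uncovered)}"
            )

    def __len__(self) -> int:
        return len(self.pairs)


def read_association_table(text: str, host: PhyloTree,
                           parasite: PhyloTree) -> AssociationMap:
    """Read a 2-column TSV ``parasite_leaf<TAB>host_leaf`` association table.

    Multiple lines per parasite leaf encode a multi-host parasite.
    """
    hleaves = set(host.leaf_labels())
    pleaves = set(parasite.leaf_labels())
    pairs = set()
    for lineno, raw in enumerate(_io.StringIO(text), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"line {lineno}: expected 2 tab-separated fields")
        p, h = parts[0].strip(), parts[1].strip()
        if p not in pleaves:
            raise ValidationError(f"line {lineno}: unknown parasite leaf {p!r}")
        if h not in hleaves:
            raise ValidationError(f"line {lineno}: unknown host leaf {h!r}")
        pairs.add((p, h))
    amap = AssociationMap(frozenset(pairs))
    amap.validate(host, parasite)
    return amap


@dataclass
class TimingAnnotation:
    """Divergence-timing constraints.

    Host nodes sit in a single integer time zone; parasite nodes carry an
    integer zone interval [lo, hi].  A parasite-host association is allowed
    only when the host's zone falls inside the parasite's interval.  Zones
    must be non-decreasing along every root-to-leaf host path.
    """

    host_zone: dict  # host node id -> int
    parasite_interval: dict  # parasite node id -> (lo, hi)

    def validate(self, host: PhyloTree, parasite: PhyloTree) -> None:
        for v in range(host.n_nodes):
            if v not in self.host_zone:
                raise ValidationError(f"host node {host._name(v)} has no time zone")
        for v in range(parasite.n_nodes):
            if v not in self.parasite_interval:
                raise ValidationError(
                    f"parasite node {parasite._name(v)} has no zone interval")
            lo, hi = self.parasite_interval[v]
            if lo > hi:
                raise ValidationError(
                    f"parasite node {parasite._name(v)}: interval [{lo}, {hi}] empty")
        for v in range(1, host.n_nodes):
            if self.host_zone[v] < self.host_zone[host.parent[v]]:
                raise ValidationError(
                    "host time zones must be non-decreasing from the root")

    @classmethod
    def from_tables(cls, host_text: str, parasite_text: str,
                    host: PhyloTree, parasite: PhyloTree) -> "TimingAnnotation":
        """Read zones from 2-column TSVs: ``label<TAB>zone`` / ``label<TAB>lo-hi``."""
        hz = {}
        for lineno, raw in enumerate(_io.StringIO(host_text), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            lab, zone = line.split("\t")
            try:
                hz[host.node_by_label(lab.strip())] = int(zone)
            except KeyError:
                raise ValidationError(f"host timing line {lineno}: unknown label {lab!r}")
        pz = {}
        for lineno, raw in enumerate(_io.StringIO(parasite_text), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            lab, iv = line.split("\t")
            lo, _, hi = iv.partition("-")
            lo = int(lo)
            hi = int(hi) if hi else lo
            try:
                pz[parasite.node_by_label(lab.strip())] = (lo, hi)
            except KeyError:
                raise ValidationError(
                    f"parasite timing line {lineno}: unknown label {lab!r}")
        ann = cls(hz, pz)
        ann.validate(host, parasite)
        return ann


@dataclass
class CophySystem:
    """A host tree, a parasite tree, their leaf associations, optional timing."""

    host: PhyloTree
    parasite: PhyloTree
    phi: AssociationMap
    timing: Optional[TimingAnnotation] = None
    # leaf-level association by node id, derived once
    _leaf_hosts: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.phi.validate(self.host, self.parasite)
        if self.timing is not None:
            self.timing.validate(self.host, self.parasite)
        self._leaf_hosts = {}
        for p, h in self.phi.pairs:
            pid = self.parasite.node_by_label(p)
            hid = self.host.node_by_label(h)
            self._leaf_hosts.setdefault(pid, set()).add(hid)

    def leaf_host_ids(self, parasite_leaf_id: int) -> set:
        """Host node ids a parasite leaf may map to under phi."""
        return self._leaf_hosts.get(parasite_leaf_id, set())
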