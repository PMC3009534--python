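"""Null models and significance statistics for coevolutionary signal.

Four randomization schemes are supported: regrowing the host tree, the
parasite tree, or both under the Aldous beta-splitting model, and
shuffling the associations while preserving, for every k, the number of
host leaves that carry exactly k parasites (the character-preserving
association shuffle).  Significance of the observed reconstruction is
quantified by comparing its cospeciation count and quality q against the
null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import gammaln

from .search import UndefinedQualityError, random_search
from .trees import AssociationMap, CophySystem, PhyloTree

NULL_METHODS = ("rnd_host", "rnd_parasite", "rnd_both", "rnd_assoc")


def beta_split_weights(n: int, beta: float) -> np.ndarray:
    """Unnormalized probabilities of splitting an n-clade into (i, n-i).

    w_i proportional to Gamma(beta+1+i) * Gamma(beta+1+n-i) /
    (Gamma(i+1) * Gamma(n-i+1)) for i = 1..n-1.  beta = 0 recovers the
    Markov (Yule) model, where every split size is equally likely;
    beta = -3/2 recovers the PDA (uniform-topology) model.
    """
    if beta <= -2:
        raise ValueError("beta must be > -2")
    i = np.arange(1, n)
    logw = (gammaln(beta + 1 + i) + gammaln(beta + 1 + (n - i))
            - gammaln(i + 1) - gammaln(n - i + 1))
    w = np.exp(logw - logw.max())
    return w / w.sum()


def beta_splitting_tree(n_leaves: int, beta: float = -1.0,
                        seed: Optional[int] = None,
                        labels: Optional[list] = None,
                        rng: Optional[np.random.Generator] = None) -> PhyloTree:
    """Random binary tree shape under the beta-splitting model.

    Leaf labels default to L1..Ln, assigned left-to-right; pass ``labels``
    to override.  The default beta = -1 gives a tree-shape distribution
    intermediate between Yule (beta=0) and PDA (beta=-3/2).
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"L{i + 1}" for i in range(n_leaves)]
    if len(labels) != n_leaves:
        raise ValueError("need exactly one label per leaf")

    parent: list = []
    children: list = []
    label: list = []

    def build(lo: int, hi: int, par: Optional[int]) -> int:
        n = hi - lo
        my_id = len(parent)
        parent.append(par)
        children.append([])
        if n == 1:
            label.append(labels[lo])
            return my_id
        label.append(None)
        i = int(rng.choice(np.arange(1, n), p=beta_split_weights(n, beta)))
        left = build(lo, lo + i, my_id)
        right = build(lo + i, hi, my_id)
        children[my_id] = [left, right]
        return my_id

    build(0, n_leaves, None)
    return PhyloTree(parent, children, label)


def randomize_assoc(phi: AssociationMap, host: PhyloTree, parasite: PhyloTree,
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None) -> AssociationMap:
    """Character-preserving association shuffle.

    The multiset of per-host-leaf parasite counts (including zero-parasite
    hosts) is preserved exactly, and every parasite leaf keeps its number
    of hosts: host leaves swap their association-count labels uniformly at
    random, then parasite association stubs are matched to host slots by a
    uniform random permutation.  Draws are rejected (rare, multi-host
    parasites only) when the same pair would appear twice.
    """
    if not phi.pairs:
        raise ValueError("empty association map")
    if rng is None:
        rng = np.random.default_rng(seed)
    hosts = host.leaf_labels()
    deg = {h: 0 for h in hosts}
    for _, h in phi.pairs:
        deg[h] += 1
    degrees = [deg[h] for h in hosts]
    stubs = [p for p, _ in sorted(phi.pairs)]
    for _ in range(1000):
        perm = rng.permutation(len(hosts))
        slots: list = []
        for j, hi in enumerate(perm):
            slots.extend([hosts[hi]] * degrees[j])
        order = rng.permutation(len(slots))
        pairs = {(stubs[k], slots[order[k]]) for k in range(len(slots))}
        if len(pairs) == len(slots):
            return AssociationMap(frozenset(pairs))
    raise RuntimeError("could not draw a duplicate-free association shuffle")


def make_null_instance(sys: CophySystem, method: str,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None,
                       beta: float = -1.0) -> CophySystem:
    """One randomized instance under the given null model.

    Tree-randomizing methods regrow the named tree(s) with the
    beta-splitting model at equal leaf count and reassign the original
    leaf labels in uniform random order, so phi stays well defined.
    Timing annotations are dropped in null instances.
    """
    if method not in NULL_METHODS:
        raise ValueError(f"unknown null method {method!r}; choose from {NULL_METHODS}")
    if rng is None:
        rng = np.random.default_rng(seed)
    host, par, phi = sys.host, sys.parasite, sys.phi

    def regrow(tree: PhyloTree) -> PhyloTree:
        labels = list(tree.leaf_labels())
        shuffled = [labels[i] for i in rng.permutation(len(labels))]
        return beta_splitting_tree(len(labels), beta, labels=shuffled, rng=rng)

    if method == "rnd_host":
        host = regrow(host)
    elif method == "rnd_parasite":
        par = regrow(par)
    elif method == "rnd_both":
        host = regrow(host)
        par = regrow(par)
    else:  # rnd_assoc
        phi = randomize_assoc(phi, host, par, rng=rng)
    return CophySystem(host, par, phi, timing=None)


@dataclass
class SignificanceReport:
    """Null-distribution comparison of the observed reconstruction.

    p_co_gt / p_co_ge: fraction of null instances whose best reconstruction
    has strictly more / at least as many cospeciations as the original's.
    p_qu: fraction with strictly smaller quality q (a smaller null q
    undermines the original's support).
    """

    p_co_gt: float
    p_co_ge: float
    p_qu: float
    n_instances: int
    original_cospeciations: int
    original_q: float
    records: list = field(default_factory=list)  # per-instance (cospeciations, q)
    n_excluded: int = 0
    method: str = ""

    def to_json(self) -> dict:
        return {
            "method": self.method,
            "p_co_gt": self.p_co_gt,
            "p_co_ge": self.p_co_ge,
            "p_qu": self.p_qu,
            "n_instances": self.n_instances,
            "n_excluded": self.n_excluded,
            "original": {"cospeciations": self.original_cospeciations,
                         "q": self.original_q},
            "instances": [{"cospeciations": c, "q": q} for c, q in self.records],
        }


def significance_test(sys: CophySystem, method: str, n_instances: int = 100,
                      n_samples: int = 100_000, seed: int = 0,
                      null_samples: Optional[int] = None,
                      beta: float = -1.0,
                      progress: Optional[Callable] = None) -> SignificanceReport:
    """Randomization test of coevolutionary signal.

    Runs the parameter-adaptive random search on the original system and on
    ``n_instances`` null instances (``null_samples`` cost vectors each,
    defaulting to ``n_samples``), then reports the tail fractions.
    Instance seeds are derived deterministically from the master seed.
    Null instances whose q is undefined are excluded and counted.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if null_samples is None:
        null_samples = n_samples
    states = np.random.SeedSequence(seed).generate_state(2 * n_instances + 1)
    seeds = [int(s) & 0x7FFFFFFF for s in states]
    original = random_search(sys, n_samples, seeds[0])
    orig_co = original.best_reconstruction.cospeciations()
    orig_q = original.q_best
    records: list = []
    excluded = 0
    for i in range(n_instances):
        inst = make_null_instance(sys, method, seed=seeds[1 + 2 * i], beta=beta)
        try:
            res = random_search(inst, null_samples, seeds[2 + 2 * i])
        except UndefinedQualityError:
            excluded += 1
            continue
        records.append((res.best_reconstruction.cospeciations(), res.q_best))
        if progress is not None:
            progress(i + 1, n_instances)
    n_ok = len(records)
    if n_ok == 0:
        raise RuntimeError("every null instance had undefined quality")
    p_gt = sum(1 for c, _ in records if c > orig_co) / n_ok
    p_ge = sum(1 for c, _ in records if c >= orig_co) / n_ok
    p_qu = sum(1 for _, q in records if q < orig_q) / n_ok
    return SignificanceReport(p_gt, p_ge, p_qu, n_ok, orig_co, orig_q,
                              records, excluded, method)
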