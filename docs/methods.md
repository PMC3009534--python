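# Methods

## Model

Both phylogenies are rooted and strictly binary; multifurcating input is
rejected at parse time (composite multifurcation events are out of
scope).  A *reconstruction* maps every parasite node to a host node.  It
is valid when (i) each parasite leaf maps to a host leaf it is
associated with under φ, (ii) no parasite node maps to a strict ancestor
of a host that one of its descendants maps to, and (iii) every internal
parasite node has at least one child mapped inside the subtree of its
own host (a speciation in which *both* daughters leave the subtree
cannot be traced and is disallowed).

Events are inferred per *association triple* — an internal parasite node
p with host h and its two children with hosts h1, h2:

- both children inside subtree(h): **duplication** plus one **sorting**
  per edge on the descent paths (S = total skipped edges); if the
  children lie in *different* child subtrees of h, the **cospeciation**
  reading costs c_co + (S − 2)·c_so and the cheaper of the two is kept;
- exactly one child inside: **host switch**; the out-of-subtree child
  lands exactly at its mapped node and contributes no sortings (the
  descent-path notion is only defined inside the subtree, and this
  convention reproduces the worked example's counts);
- h a strict ancestor-violating placement or both children outside:
  infeasible (cost ∞).

Conventions that matter for corner cases: "descendant" is reflexive, so
a child mapped to h itself is a duplication candidate with zero sortings
and never a cospeciation; cospeciation wins cost ties against
duplication (it is the statistic the significance tests count, and the
tie-break makes output deterministic).

## Dynamic program

C(p, h) is filled bottom-up over the parasite tree; leaves cost 0 at
associated hosts and ∞ elsewhere.  With timing annotations, an
infeasible zone combination adds ∞ at every association, leaves
included.  The production path prunes by dominance: for fixed parent
host h, two candidate placements of the same child inside the same
partition of the host set — subtree(h.1), subtree(h.2), {h}, or the
remaining nodes — differ only by their sorting-path cost, so only the
per-partition minimum can appear in an optimum.  The implementation
computes, per child, running subtree minima of C(child, ·) +
depth·c_so and, top-down, the best value outside each node's subtree
*excluding its ancestors* (an ancestor is never a legal switch landing;
including it would let the partition minimum pick an infeasible
candidate), then combines the ≤ 4 × 4 candidates per (p, h) in O(1).
Total cost O(n·m) per internal parasite node, O(n³) overall in the
worst case.  A naive variant that scans all host pairs is retained and
the tests assert both produce identical tables; an exhaustive
enumeration over all valid mappings (≤ 8 internal parasite nodes) is
the independent oracle.

The parasite root may map to any host node; the reported optimum is the
minimum over the root row, ties broken by smallest preorder id.  One
optimal reconstruction is reported per cost vector;
`enumerate_optimal_mappings` exposes all co-optima for diagnostics.
Multi-host parasites are supported at the leaf level (cost 0 at every
associated host).

Host switches induce timing relations between take-off and landing
lineages.  `check_switch_compatibility` encodes, conservatively, host
ancestry as a happens-before order plus, per switch, "the landing edge
begins before the take-off host ends" in both directions
(parent(landing) ≺ take-off, parent(take-off) ≺ landing); a directed
cycle marks the reconstruction incompatible.  This is a necessary
condition only — a finer interval analysis could reject more — and it is
reported as a flag, not used to constrain the optimization.

## Parameter-adaptive criterion

q(c) = Σ_i |p_i − r_i| with p_i the normalized reciprocal costs and r_i
the relative event frequencies of the reconstruction computed under c.
The L1 form is the package's convention for "sum of the differences";
it is bounded by [0, 2], scale-invariant in c (only cost ratios affect
both the reconstruction and p), and zero exactly at self-consistency.
r_i is computed from the single reported optimal reconstruction, not
averaged over co-optima.  Negative costs are accepted for plain
reconstruction but refused here (reciprocal-cost probabilities are
meaningless for c_i ≤ 0).

The search draws cost vectors uniformly from (0, 1]⁴ — 100 000 samples
by default, configurable because the randomization tests multiply this
cost — and keeps the running minimum of q, which is therefore
non-increasing in the sample count and reproducible under a fixed seed.
The objective is piecewise constant between reconstruction changes, so
the optional Nelder–Mead refinement (coordinates clipped to
[10⁻⁶, 1]) tracks the best *visited* point and usually terminates on its
iteration budget; it can never return a worse point than its start.

**Known limitation — corner degeneracy.**  If the system admits a valid
reconstruction composed of a single event type with no sortings (an
all-switch reconstruction exists whenever all associated hosts are
distinct; an all-cospeciation one exists for perfectly mirrored
tanglegrams), then q → 0 as the corresponding cost coordinate → 0:
the criterion rewards any *pure* event profile matched by an extreme
cost vector.  On small or perfectly cospeciating systems several such
corners coexist with essentially equal q, and which one the search
reports depends on which sampled vector lies closest to a corner.
Realistic tanglegrams force mixed event profiles, which is where the
criterion is informative; interpret q_best near machine zero on a tiny
system as a degeneracy flag rather than as strong support.

## Null models and significance

- **rnd_host / rnd_parasite / rnd_both** regrow the named tree(s) under
  the Aldous β-splitting model at equal leaf count: a clade of n leaves
  splits into (i, n − i) with probability ∝
  Γ(β+1+i)·Γ(β+1+n−i) / (Γ(i+1)·Γ(n−i+1)).  β = 0 is the Markov/Yule
  model (uniform split sizes — the closed form the tests check), β = −3/2
  the PDA model (supported, structurally tested only), and β = −1 the
  default.  Original leaf labels are reassigned in uniform random order,
  which keeps φ well defined; the choice is arbitrary and harmless
  because the regrown shape is exchangeable over leaves.
- **rnd_assoc** keeps both trees and shuffles φ preserving the
  hosts-with-k-parasites histogram exactly (host leaves permute their
  association counts; parasite stubs are matched to host slots by a
  uniform permutation, rejecting the rare duplicate pair for multi-host
  parasites).  Every parasite also keeps its number of hosts.

Timing annotations are dropped in null instances: a regrown tree has no
meaningful zones, and keeping zones while shuffling φ would conflate
timing infeasibility with association signal.

`significance_test` runs the adaptive search on the original system and
on each null instance (per-instance seeds derived from the master seed
via a seed sequence, so reports are reproducible), then reports
p_co,> (strict), p_co,≥ (non-strict) and p_qu (strictly smaller q) with
the per-instance records retained for plotting.  Null instances with
undefined q (no events) are excluded and counted.

## Problem sizes and numerical choices

The test suite and the acceptance script run the oracle comparison on
200 random systems of ≤ 6 leaves per tree (the exhaustive oracle is
exponential), the size-trend experiment on 20 random tanglegrams per
size in {5, 10, 20, 30, 40, 50, 60} under fixed costs (−2, 1, 2, 4)
(a qualitative rank-correlation check: switch frequency rises,
cospeciation frequency falls with size), short-run search convergence at
tens of samples per seed, and the mirror-tree significance test at 20
null instances × 2000 samples — sizes chosen so each check finishes in
seconds while leaving the measured effects far from their decision
thresholds.  Cost comparisons between the DP and the oracle use an
absolute tolerance of 10⁻⁹ (all arithmetic is plain float addition);
co-optimum enumeration uses a relative 10⁻⁹ band.  Infeasibility is the
IEEE infinity throughout, which propagates correctly through the
minimizations.

## What the generators do and do not emulate

`random_system` draws independent β-splitting shapes and associates each
parasite leaf with one uniform host leaf.  This produces no built-in
coevolutionary signal, no multi-host parasites, no timing annotations,
and no phylogenetic autocorrelation in the associations; passing tests
on it demonstrate algorithmic correctness (DP = oracle, contract
invariants), not biological realism.  `mirror_system` is the opposite
extreme — a perfectly cospeciating tanglegram — used to check that the
significance machinery recovers an obvious signal.  Conclusions about
real data sets require real trees and associations supplied through the
standard input formats.
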