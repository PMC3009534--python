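"""Parameter-adaptive cost estimation.

Instead of fixing event costs a priori, costs are treated as free
parameters: a cost vector c implies event probabilities p_i proportional
to the reciprocal costs 1/c_i, and a candidate reconstruction realizes
event frequencies r_i.  The quality

    q(c) = sum_i | p_i - r_i |

measures how far the reconstruction implied by c is from self-consistency
(cheap events should be frequent).  The search samples cost vectors
uniformly from (0, 1]^4, reconstructs under each, and keeps the smallest
q; an optional Nelder-Mead refinement polishes the best vector.  Only the
ratios between costs matter, so no normalization of the samples is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .dp import Reconstruction, reconstruct
from .events import CostVector, EventCounts
from .trees import CophySystem


class UndefinedQualityError(ValueError):
    """No events occurred (single-leaf parasite tree): q is not defined."""


def event_probabilities(costs: CostVector) -> tuple:
    """(p_co, p_so, p_du, p_hs): normalized reciprocal costs.

    p_i = (1/c_i) / sum_j (1/c_j), so p_i / p_j = c_j / c_i.  Requires all
    costs strictly positive; negative costs have no probability reading.
    """
    costs.require_positive()
    recip = [1.0 / c for c in costs.as_tuple()]
    s = sum(recip)
    return tuple(r / s for r in recip)


def relative_frequencies(events: EventCounts) -> tuple:
    """r_i = n_i / total event count."""
    n = events.total()
    if n == 0:
        raise UndefinedQualityError(
            "no events occurred; relative frequencies are undefined")
    return tuple(x / n for x in events.as_tuple())


def quality(costs: CostVector, events: EventCounts) -> float:
    """L1 distance between implied probabilities and realized frequencies.

    Lies in [0, 2]; 0 means the cost vector exactly predicts the event
    frequencies of its own optimal reconstruction.  Invariant under
    rescaling of the cost vector.
    """
    p = event_probabilities(costs)
    r = relative_frequencies(events)
    return sum(abs(pi - ri) for pi, ri in zip(p, r))


@dataclass
class SearchResult:
    best_costs: CostVector
    best_reconstruction: Reconstruction
    q_best: float
    n_sampled: int
    seed: Optional[int] = None

    def to_json(self, sys: CophySystem) -> dict:
        return {
            "best_costs": dict(zip(("cospeciation", "sorting", "duplication",
                                    "hostswitch"), self.best_costs.as_tuple())),
            "q_best": self.q_best,
            "n_sampled": self.n_sampled,
            "seed": self.seed,
            "reconstruction": self.best_reconstruction.to_json(sys),
        }


def _draw_costs(rng: np.random.Generator) -> CostVector:
    # 1 - U[0,1) lies in (0, 1]: exact zeros are impossible
    u = 1.0 - rng.random(4)
    return CostVector(*u)


def evaluate_costs(sys: CophySystem, costs: CostVector) -> tuple[Reconstruction, float]:
    """Reconstruct under ``costs`` and score with q."""
    rec = reconstruct(sys, costs)
    return rec, quality(costs, rec.events)


def random_search(sys: CophySystem, n_samples: int = 100_000,
                  seed: int = 0, log_progress=None) -> SearchResult:
    """Uniform random search over cost vectors; returns the smallest-q result.

    Deterministic for a given seed.  ``log_progress``, if given, is called
    with (i, q_best) at powers of ten.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    best: Optional[SearchResult] = None
    next_log = 10
    for i in range(1, n_samples + 1):
        costs = _draw_costs(rng)
        rec, q = evaluate_costs(sys, costs)
        if best is None or q < best.q_best:
            best = SearchResult(costs, rec, q, i, seed)
        if log_progress is not None and i >= next_log:
            log_progress(i, best.q_best)
            next_log *= 10
    assert best is not None
    return SearchResult(best.best_costs, best.best_reconstruction,
                        best.q_best, n_samples, seed)


def simplex_search(sys: CophySystem, start: CostVector,
                   max_iter: int = 200) -> SearchResult:
    """Nelder-Mead refinement of q around ``start``.

    The objective is piecewise constant between reconstruction switches,
    so the simplex frequently terminates on max_iter; the best *visited*
    point is returned, which can never be worse than the start.
    Coordinates are clipped to [1e-6, 1].
    """
    start.require_positive()
    lo, hi = 1e-6, 1.0
    tracker: dict = {}

    def objective(x) -> float:
        cv = CostVector(*np.clip(x, lo, hi))
        try:
            rec, q = evaluate_costs(sys, cv)
        except UndefinedQualityError:
            return math.inf
        if "best" not in tracker or q < tracker["best"][2]:
            tracker["best"] = (cv, rec, q)
        tracker["n"] = tracker.get("n", 0) + 1
        return q

    x0 = np.clip(np.asarray(start.as_tuple(), dtype=float), lo, hi)
    try:
        minimize(objective, x0, method="Nelder-Mead",
                 options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-9})
    except Exception:
        # degenerate simplex: one restart from a perturbed start
        if "best" not in tracker:
            raise
        x1 = np.clip(x0 * 0.9 + 0.05, lo, hi)
        try:
            minimize(objective, x1, method="Nelder-Mead",
                     options={"maxiter": max_iter})
        except Exception:
            pass
    cv, rec, q = tracker["best"]
    return SearchResult(cv, rec, q, tracker.get("n", 0))


def adaptive_search(sys: CophySystem, n_samples: int = 100_000, seed: int = 0,
                    refine: bool = True, max_iter: int = 200,
                    log_progress=None) -> SearchResult:
    """Random search followed by optional Nelder-Mead refinement."""
    result = random_search(sys, n_samples, seed, log_progress)
    if refine:
        refined = simplex_search(sys, result.best_costs, max_iter)
        if refined.q_best < result.q_best:
            return SearchResult(refined.best_costs, refined.best_reconstruction,
                                refined.q_best,
                                result.n_sampled + refined.n_sampled, seed)
        result.n_sampled += refined.n_sampled
    return result
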