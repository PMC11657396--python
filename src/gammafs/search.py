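"""Greedy subset search: forward, backward and best-first.

All three searches maximize an arbitrary evaluation function over feature
subsets under a *strict*-improvement stopping rule: a candidate is accepted
only if its score is strictly greater (exact float ``>``) than the
incumbent's.  Ties among equal-scored candidates are broken toward the
candidate whose added (or removed) feature has the lowest index, so results
are fully deterministic.

Best-first search keeps a priority queue of every evaluated-but-unexpanded
subset; when the greedy expansion dead-ends it backs up to the best queued
subset and continues, up to ``max_backtracks`` times, returning the best
subset found overall.  With ``max_backtracks = 0`` it coincides with the
forward search.
"""

from __future__ import annotations

import heapq
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = ["SelectionResult", "SearchConfig", "forward_search",
           "backward_search", "best_first_search", "run_search", "SearchError"]


class SearchError(RuntimeError):
    """Raised when the evaluation function fails; carries the subset."""

    def __init__(self, subset, cause):
        super().__init__(f"evaluation failed on subset {sorted(subset)}: {cause}")
        self.subset = tuple(sorted(subset))


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one search run."""

    selected: tuple[int, ...]       # sorted feature indices
    score: float
    trace: tuple                    # ((subset, score), ...) accepted, scores strictly increasing
    n_evaluations: int
    runtime_s: float


@dataclass(frozen=True)
class SearchConfig:
    direction: str = "forward"      # forward | backward | best_first
    max_backtracks: int = 5         # best-first only
    tie_break: str = "lowest_index"

    def __post_init__(self):
        if self.direction not in ("forward", "backward", "best_first"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.max_backtracks < 0:
            raise ValueError("max_backtracks must be >= 0")
        if self.tie_break != "lowest_index":
            raise ValueError("only lowest_index tie-breaking is implemented")


class _CountingEval:
    def __init__(self, evaluate: Callable):
        self._fn = evaluate
        self.count = 0

    def __call__(self, subset):
        self.count += 1
        try:
            return float(self._fn(sorted(subset)))
        except SearchError:
            raise
        except Exception as exc:
            raise SearchError(subset, exc) from exc


def _best_singleton(p: int, ev: _CountingEval) -> tuple[frozenset, float]:
    best, best_score = None, None
    for j in range(p):
        s = ev([j])
        if best_score is None or s > best_score:
            best, best_score = frozenset([j]), s
    return best, best_score


def forward_search(p: int, evaluate: Callable[[Sequence[int]], float],
                   config: SearchConfig | None = None) -> SelectionResult:
    """Grow from the best singleton, adding one feature per step."""
    if p < 1:
        raise ValueError("p must be >= 1")
    t0 = time.perf_counter()
    ev = _CountingEval(evaluate)
    current, score = _best_singleton(p, ev)
    trace = [(tuple(sorted(current)), score)]
    while len(current) < p:
        best_child, best_score = None, None
        for j in range(p):
            if j in current:
                continue
            s = ev(current | {j})
            if best_score is None or s > best_score:
                best_child, best_score = current | {j}, s
        if best_score > score:
            current, score = best_child, best_score
            trace.append((tuple(sorted(current)), score))
        else:
            break
    return SelectionResult(tuple(sorted(current)), score, tuple(trace),
                           ev.count, time.perf_counter() - t0)


def backward_search(p: int, evaluate: Callable[[Sequence[int]], float],
                    config: SearchConfig | None = None) -> SelectionResult:
    """Shrink from the full set, removing one feature per step.

    Never evaluates the empty subset: the search stops once a single
    feature remains.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    t0 = time.perf_counter()
    ev = _CountingEval(evaluate)
    current = frozenset(range(p))
    score = ev(current)
    trace = [(tuple(sorted(current)), score)]
    while len(current) > 1:
        best_child, best_score = None, None
        for j in sorted(current):
            s = ev(current - {j})
            if best_score is None or s > best_score:
                best_child, best_score = current - {j}, s
        if best_score > score:
            current, score = best_child, best_score
            trace.append((tuple(sorted(current)), score))
        else:
            break
    return SelectionResult(tuple(sorted(current)), score, tuple(trace),
                           ev.count, time.perf_counter() - t0)


def best_first_search(p: int, evaluate: Callable[[Sequence[int]], float],
                      config: SearchConfig | None = None,
                      max_backtracks: int | None = None) -> SelectionResult:
    """Forward expansion with backtracking to the best unexpanded subset."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if max_backtracks is None:
        max_backtracks = (config.max_backtracks if config is not None else 5)
    if max_backtracks < 0:
        raise ValueError("max_backtracks must be >= 0")
    t0 = time.perf_counter()
    ev = _CountingEval(evaluate)

    visited: set[frozenset] = set()
    frontier: list = []   # heap of (-score, subset_tuple); tuple order breaks ties

    best, best_score = None, None
    for j in range(p):
        sub = frozenset([j])
        s = ev(sub)
        visited.add(sub)
        if best_score is None or s > best_score:
            if best is not None:
                heapq.heappush(frontier, (-best_score, tuple(sorted(best))))
            best, best_score = sub, s
        else:
            heapq.heappush(frontier, (-s, tuple(sorted(sub))))

    current, cur_score = best, best_score
    trace = [(tuple(sorted(best)), best_score)]
    backtracks = 0
    while True:
        best_child, child_score = None, None
        for j in range(p):
            if j in current:
                continue
            sub = current | {j}
            if sub in visited:
                continue
            s = ev(sub)
            visited.add(sub)
            if child_score is None or s > child_score:
                if best_child is not None:
                    heapq.heappush(frontier, (-child_score, tuple(sorted(best_child))))
                best_child, child_score = sub, s
            else:
                heapq.heappush(frontier, (-s, tuple(sorted(sub))))
        if best_child is not None and child_score > cur_score:
            current, cur_score = best_child, child_score
            if cur_score > best_score:
                best, best_score = current, cur_score
                trace.append((tuple(sorted(best)), best_score))
        else:
            if best_child is not None:
                heapq.heappush(frontier, (-child_score, tuple(sorted(best_child))))
            if backtracks >= max_backtracks or not frontier:
                break
            backtracks += 1
            neg, sub = heapq.heappop(frontier)
            current, cur_score = frozenset(sub), -neg
    return SelectionResult(tuple(sorted(best)), best_score, tuple(trace),
                           ev.count, time.perf_counter() - t0)


def run_search(p: int, evaluate: Callable, config: SearchConfig) -> SelectionResult:
    """Dispatch on ``config.direction``."""
    if config.direction == "forward":
        return forward_search(p, evaluate, config)
    if config.direction == "backward":
        return backward_search(p, evaluate, config)
    return best_first_search(p, evaluate, config)
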