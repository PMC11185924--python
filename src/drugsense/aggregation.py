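"""Consensus drug ranking across patients.

Per-patient ranked drug lists are aggregated into one top-k (or bottom-k)
consensus list by Cross-Entropy Monte Carlo optimization of the mean Spearman
footrule distance, in the style of the RankAggreg formulation: candidate
ordered k-lists are sampled from a column-stochastic position-probability
matrix, the elite fraction re-estimates the matrix, and the best-ever
candidate is returned. Items absent from a top-k list count as sitting at
position k+1.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np

from .types import CEParams, ConsensusList

__all__ = [
    "footrule_objective",
    "ce_aggregate",
    "exhaustive_aggregate",
    "aggregate_bottom",
    "subtype_specific",
]

_ENUMERATION_GUARD = 1_000_000


def _universe(input_lists: Sequence[Sequence[str]]) -> list[str]:
    if not input_lists:
        raise ValueError("need at least one input ranked list")
    uni: set[str] = set()
    for lst in input_lists:
        if len(set(lst)) != len(lst):
            raise ValueError("input ranked lists must not contain duplicates")
        uni.update(lst)
    # sorted so aggregation is invariant to the order input lists arrive in
    return sorted(uni)


def footrule_objective(
    candidate: Sequence[str],
    input_lists: Sequence[Sequence[str]],
    k: int | None = None,
) -> float:
    """Mean Spearman footrule distance of a candidate k-list to the inputs.

    For each input list, the distance sums |position in candidate - position
    in the input's top-k| over the union of both k-lists, with absent items
    at position k+1; the objective is the mean across input lists.
    """
    candidate = list(candidate)
    k = k if k is not None else len(candidate)
    if len(candidate) != k or len(set(candidate)) != k:
        raise ValueError("candidate must hold k distinct items")
    cand_pos = {item: i + 1 for i, item in enumerate(candidate)}
    total = 0.0
    for lst in input_lists:
        top = list(lst)[:k]
        in_pos = {item: i + 1 for i, item in enumerate(top)}
        dist = 0
        for item in set(candidate) | set(top):
            dist += abs(cand_pos.get(item, k + 1) - in_pos.get(item, k + 1))
        total += dist
    return total / len(input_lists)


def _objective_matrix(input_lists: Sequence[Sequence[str]], universe: list[str], k: int):
    """Precompute per-list position arrays for vectorized candidate scoring."""
    index = {item: i for i, item in enumerate(universe)}
    pos = np.full((len(input_lists), len(universe)), k + 1, dtype=np.int64)
    base = np.zeros(len(input_lists))
    for li, lst in enumerate(input_lists):
        for j, item in enumerate(list(lst)[:k]):
            pos[li, index[item]] = j + 1
        # contribution of the list's own top-k items if absent from the candidate
        base[li] = float(np.sum((k + 1) - pos[li][pos[li] <= k]))
    return pos, base


def _score_candidates(C: np.ndarray, pos: np.ndarray, base: np.ndarray, k: int) -> np.ndarray:
    """Objective for each candidate row of item indices C (n_cand, k)."""
    cand_positions = np.arange(1, k + 1)[None, None, :]  # (1, 1, k)
    gathered = pos[:, C]  # (L, n_cand, k): input position of each candidate item
    part1 = np.abs(cand_positions - gathered.transpose(1, 0, 2)).sum(axis=2)  # (n_cand, L)
    in_top = gathered.transpose(1, 0, 2) <= k
    part2 = base[None, :] - (((k + 1) - gathered.transpose(1, 0, 2)) * in_top).sum(axis=2)
    return (part1 + part2).mean(axis=1)


def exhaustive_aggregate(input_lists: Sequence[Sequence[str]], k: int) -> ConsensusList:
    """Global optimum of the footrule objective by enumerating ordered k-lists.

    Feasible only for small universes (guarded at 10^6 candidates); ties are
    broken lexicographically. Serves as the exact oracle for ce_aggregate.
    """
    universe = _universe(input_lists)
    U = len(universe)
    if k > U:
        raise ValueError(f"k={k} exceeds universe size {U}")
    n_cand = math.perm(U, k)
    if n_cand > _ENUMERATION_GUARD:
        raise ValueError(
            f"{n_cand} candidate lists exceed the enumeration guard; use ce_aggregate"
        )
    pos, base = _objective_matrix(input_lists, universe, k)
    best: tuple[float, tuple[str, ...]] | None = None
    perms = itertools.permutations(range(U), k)
    while True:
        chunk = list(itertools.islice(perms, 20_000))
        if not chunk:
            break
        C = np.array(chunk, dtype=np.int64)
        obj = _score_candidates(C, pos, base, k)
        # lexicographic tie-break on item names within the chunk
        for i in np.flatnonzero(obj <= obj.min() + 1e-12):
            names = tuple(universe[j] for j in chunk[i])
            key = (float(obj[i]), names)
            if best is None or key < best:
                best = key
    assert best is not None
    return ConsensusList(list(best[1]), best[0], k, converged=True, n_iterations=0)


def ce_aggregate(
    input_lists: Sequence[Sequence[str]],
    params: CEParams | None = None,
    rng: int | np.random.Generator = 0,
) -> ConsensusList:
    """Cross-Entropy Monte Carlo minimization of the mean footrule distance.

    Maintains a (universe x k) column-stochastic probability matrix, samples
    candidate k-lists without replacement, re-estimates the matrix from the
    elite fraction with smoothing, and stops after ``tolerance`` iterations
    without improvement (or ``max_iterations``). Deterministic given the rng.
    """
    params = params or CEParams()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    universe = _universe(input_lists)
    U = len(universe)
    k = params.k
    if k > U:
        raise ValueError(f"k={k} exceeds universe size {U}")
    pos, base = _objective_matrix(input_lists, universe, k)
    n_samples = params.n_samples or 10 * U
    n_elite = max(1, int(math.ceil(params.elite_fraction * n_samples)))
    P = np.full((U, k), 1.0 / U)
    best_obj = np.inf
    best_items: np.ndarray | None = None
    stall = 0
    iteration = 0
    for iteration in range(1, params.max_iterations + 1):
        C = np.empty((n_samples, k), dtype=np.int64)
        available = np.ones((n_samples, U), dtype=bool)
        for j in range(k):
            probs = P[:, j][None, :] * available
            norm = probs.sum(axis=1, keepdims=True)
            uniform = available / available.sum(axis=1, keepdims=True)
            probs = np.where(norm > 0, probs / np.where(norm == 0, 1, norm), uniform)
            u = rng.random(n_samples)
            idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            idx = np.minimum(idx, U - 1)
            C[:, j] = idx
            available[np.arange(n_samples), idx] = False
        obj = _score_candidates(C, pos, base, k)
        order = np.argsort(obj, kind="stable")
        elite = C[order[:n_elite]]
        if obj[order[0]] < best_obj - 1e-12:
            best_obj = float(obj[order[0]])
            best_items = C[order[0]].copy()
            stall = 0
        else:
            stall += 1
        P_elite = np.zeros_like(P)
        for j in range(k):
            counts = np.bincount(elite[:, j], minlength=U)
            P_elite[:, j] = counts / n_elite
        P = params.smoothing * P_elite + (1.0 - params.smoothing) * P
        if stall >= params.tolerance or best_obj == 0.0:
            break
    assert best_items is not None
    return ConsensusList(
        [universe[i] for i in best_items],
        best_obj,
        k,
        converged=stall >= params.tolerance or best_obj == 0.0,
        n_iterations=iteration,
    )


def aggregate_bottom(
    input_lists: Sequence[Sequence[str]],
    params: CEParams | None = None,
    rng: int | np.random.Generator = 0,
) -> ConsensusList:
    """Consensus of the *worst* drugs: aggregate the reversed rankings."""
    params = params or CEParams(k=50)
    reversed_lists = [list(reversed(list(lst))) for lst in input_lists]
    return ce_aggregate(reversed_lists, params, rng)


def subtype_specific(
    consensus_a: ConsensusList,
    consensus_b: ConsensusList,
) -> tuple[list[str], list[str], list[str]]:
    """Split two consensus lists into (only_a, only_b, shared), order-preserving.

    ``shared`` follows consensus_a's order.
    """
    set_a, set_b = set(consensus_a.items), set(consensus_b.items)
    only_a = [d for d in consensus_a.items if d not in set_b]
    only_b = [d for d in consensus_b.items if d not in set_a]
    shared = [d for d in consensus_a.items if d in set_b]
    return only_a, only_b, shared
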