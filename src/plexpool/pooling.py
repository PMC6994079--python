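"""Partition primer pairs into subpools by randomized hill climbing.

The objective is a four-dimensional "pool score" over the interaction
*ranges* present among co-pooled primer pairs:

* d1 — the worst (maximum) interaction range,
* d2 — how many interactions sit at that range,
* d3 — how many sit one range below,
* d4 — how many sit two ranges below,

compared lexicographically (d1 first).  Match scores are their own range;
ΔG values are mapped to half-kcal ranges via ``range = int(−2 × ΔG)``.
Counters saturate at 65535 instead of wrapping.

Each primer pair contributes four cross-interactions (F×F, F×R, R×F, R×R)
against every other pair in its pool; a pair's own forward–reverse and
self-dimer interactions are pool-invariant and excluded from the objective.

The search starts from a uniform-random assignment, repeatedly applies the
best positive-benefit single-pair move until a local optimum, saves the best
state seen, then either perturbs with random "bad moves" (when the climb
matched the saved best) or re-randomizes entirely (when it converged on a
worse state), stopping after a fixed number of cycles without improvement.
"""

from __future__ import annotations

import logging
import random
import time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .primer_io import PrimerSet

logger = logging.getLogger(__name__)

RANGE_SATURATION = 0xFFFF  # 16-bit fields: ranges and counters cap here


def range_of(value: float, mode: str) -> int:
    """Interaction range: identity for scores, int(−2×ΔG) for ΔG values.

    Truncates toward zero (−1.25 kcal/mol falls in range 2); never negative.
    """
    if mode == "score":
        rng = int(value)
    elif mode == "dG":
        rng = int(-2.0 * value)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return max(0, min(rng, RANGE_SATURATION))


def search_space_size(n_pairs: int, k: int) -> int:
    """Exact number of pool assignments (k ** n_pairs)."""
    return k ** n_pairs


@dataclass(frozen=True, order=True)
class PoolScore:
    """Lexicographic 4-tuple (worst range, count there, count −1, count −2)."""

    d1: int = 0
    d2: int = 0
    d3: int = 0
    d4: int = 0

    @classmethod
    def from_ranges(cls, ranges: Iterable[int]) -> "PoolScore":
        """Aggregate a multiset of interaction ranges.

        Range 0 means "no interaction" and is ignored; counters saturate
        at 65535.
        """
        counts: dict[int, int] = {}
        for r in ranges:
            if r > 0:
                counts[r] = counts.get(r, 0) + 1
        if not counts:
            return cls()
        d1 = max(counts)
        sat = lambda x: min(x, RANGE_SATURATION)
        return cls(sat(d1), sat(counts[d1]),
                   sat(counts.get(d1 - 1, 0)), sat(counts.get(d1 - 2, 0)))

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.d1, self.d2, self.d3, self.d4)


class PairMatrix:
    """Cross-interaction ranges between primer pairs, the partitioner's view.

    ``ranges(i, j)`` is the tuple of interaction ranges between the primers
    of pair i and the primers of pair j (four entries for full F/R pairs).
    """

    def __init__(self, n_pairs: int,
                 cross: dict[tuple[int, int], tuple[int, ...]]):
        self.n_pairs = n_pairs
        self._cross = cross

    @classmethod
    def from_table(cls, table, pset: PrimerSet) -> "PairMatrix":
        pairs = pset.pairs
        cross: dict[tuple[int, int], tuple[int, ...]] = {}
        for a in pairs:
            for b in pairs:
                if a.index >= b.index:
                    continue
                names_a = (a.forward.name, a.reverse.name)
                names_b = (b.forward.name, b.reverse.name)
                cross[(a.index, b.index)] = tuple(
                    range_of(table.value(x, y), table.mode)
                    for x in names_a for y in names_b
                )
        return cls(len(pairs), cross)

    def ranges(self, i: int, j: int) -> tuple[int, ...]:
        if i > j:
            i, j = j, i
        return self._cross.get((i, j), ())


@dataclass
class PoolAssignment:
    """pair index -> pool index in [1..k]."""

    pool_of: dict[int, int]
    k: int
    size_cap: int | None = None

    def pools(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.k)]
        for pair, pool in sorted(self.pool_of.items()):
            out[pool - 1].append(pair)
        return out

    def copy(self) -> "PoolAssignment":
        return PoolAssignment(dict(self.pool_of), self.k, self.size_cap)


@dataclass(frozen=True)
class Move:
    pair_id: int
    from_pool: int
    to_pool: int
    benefit: tuple[int, int, int, int]


def pool_score(pair: int, pool: int, assignment: PoolAssignment,
               matrix: PairMatrix) -> PoolScore:
    """Pool score of ``pair`` if it sat in ``pool`` (cross-pair interactions
    with the pool's other members only)."""
    ranges: list[int] = []
    for other, p in assignment.pool_of.items():
        if p == pool and other != pair:
            ranges.extend(matrix.ranges(pair, other))
    return PoolScore.from_ranges(ranges)


def global_score(assignment: PoolAssignment, matrix: PairMatrix) -> PoolScore:
    """Objective over the whole assignment: 4-tuple of the multiset of all
    co-pooled cross-pair interaction ranges."""
    ranges: list[int] = []
    items = sorted(assignment.pool_of.items())
    for ai, (a, pa) in enumerate(items):
        for b, pb in items[ai + 1:]:
            if pa == pb:
                ranges.extend(matrix.ranges(a, b))
    return PoolScore.from_ranges(ranges)


def per_pool_summary(assignment: PoolAssignment, matrix: PairMatrix
                     ) -> list[dict[str, object]]:
    """Per-pool size and interaction-range counts (the swap-epoch log line)."""
    out = []
    for pool_members in assignment.pools():
        counts: dict[int, int] = {}
        for ai, a in enumerate(pool_members):
            for b in pool_members[ai + 1:]:
                for r in matrix.ranges(a, b):
                    counts[r] = counts.get(r, 0) + 1
        out.append({"size": len(pool_members),
                    "range_counts": dict(sorted(counts.items(), reverse=True))})
    return out


def _benefit(cur: PoolScore, new: PoolScore) -> tuple[int, int, int, int]:
    return (cur.d1 - new.d1, cur.d2 - new.d2, cur.d3 - new.d3, cur.d4 - new.d4)


def best_move(assignment: PoolAssignment, matrix: PairMatrix) -> Move | None:
    """Lexicographically best positive-benefit move, or None at a local
    optimum.  Ties: lowest pair index, then lowest target pool index."""
    sizes = [0] * (assignment.k + 1)
    for pool in assignment.pool_of.values():
        sizes[pool] += 1
    best: Move | None = None
    for pair in sorted(assignment.pool_of):
        cur_pool = assignment.pool_of[pair]
        cur = pool_score(pair, cur_pool, assignment, matrix)
        for pool in range(1, assignment.k + 1):
            if pool == cur_pool:
                continue
            if assignment.size_cap is not None and sizes[pool] >= assignment.size_cap:
                continue
            new = pool_score(pair, pool, assignment, matrix)
            ben = _benefit(cur, new)
            if ben <= (0, 0, 0, 0):
                continue
            if best is None or ben > best.benefit:
                best = Move(pair, cur_pool, pool, ben)
    return best


def hill_climb(assignment: PoolAssignment, matrix: PairMatrix,
               max_moves: int | None = None) -> int:
    """Apply best moves until a local optimum; returns the move count.

    ``max_moves`` (default 50·n) guards against rare benefit cycles: the
    per-pair benefit ranking does not strictly guarantee descent of the
    global lexicographic objective.
    """
    if max_moves is None:
        max_moves = 50 * max(1, matrix.n_pairs)
    moves = 0
    while moves < max_moves:
        mv = best_move(assignment, matrix)
        if mv is None:
            break
        assignment.pool_of[mv.pair_id] = mv.to_pool
        moves += 1
    return moves


def perturb(assignment: PoolAssignment, rng: random.Random,
            max_bad_moves: int | None = None) -> int:
    """Random 'bad moves': reassign 1..max random pairs to random other pools
    (respecting the size cap).  Returns how many moves were made."""
    n = len(assignment.pool_of)
    if n == 0 or assignment.k < 2:
        return 0
    if max_bad_moves is None:
        max_bad_moves = max(2, n // 10)
    n_moves = rng.randint(1, max_bad_moves)
    made = 0
    pairs = sorted(assignment.pool_of)
    for _ in range(n_moves):
        pair = rng.choice(pairs)
        cur = assignment.pool_of[pair]
        choices = [p for p in range(1, assignment.k + 1) if p != cur]
        if assignment.size_cap is not None:
            sizes = [0] * (assignment.k + 1)
            for pool in assignment.pool_of.values():
                sizes[pool] += 1
            choices = [p for p in choices if sizes[p] < assignment.size_cap]
        if not choices:
            continue
        assignment.pool_of[pair] = rng.choice(choices)
        made += 1
    return made


def random_assignment(n_pairs: int, k: int, rng: random.Random,
                      size_cap: int | None = None) -> PoolAssignment:
    """Uniform-random pools; randomized round-robin when a size cap is set."""
    if size_cap is None:
        pool_of = {i: rng.randint(1, k) for i in range(n_pairs)}
    else:
        order = list(range(n_pairs))
        rng.shuffle(order)
        pool_of = {}
        sizes = [0] * (k + 1)
        for pos, pair in enumerate(order):
            candidates = [p for p in range(1, k + 1) if sizes[p] < size_cap]
            pool = candidates[pos % len(candidates)]
            pool_of[pair] = pool
            sizes[pool] += 1
        pool_of = {i: pool_of[i] for i in range(n_pairs)}
    return PoolAssignment(pool_of, k, size_cap)


@dataclass
class PartitionResult:
    assignment: PoolAssignment
    score: PoolScore
    best_history: list[PoolScore] = field(default_factory=list)
    cycles: int = 0


def partition(matrix: PairMatrix, k: int, size_cap: int | None = None,
              seed: int = 0, patience: int = 200,
              max_cycles: int | None = None,
              time_limit: float | None = None) -> PartitionResult:
    """Hill climbing with bad-move perturbation and full restarts.

    Stops after ``patience`` consecutive cycles without improving the saved
    best (or on ``max_cycles``/``time_limit``), returning the best state.
    Reproducible for fixed (matrix, k, size_cap, seed, budgets).
    """
    n = matrix.n_pairs
    if k < 1:
        raise ValueError("k must be >= 1")
    if n and k > n:
        raise ValueError(f"more pools ({k}) than primer pairs ({n})")
    if size_cap is not None and size_cap * k < n:
        raise ValueError(
            f"infeasible: size_cap {size_cap} x {k} pools < {n} pairs")
    rng = random.Random(seed)
    state = random_assignment(n, k, rng, size_cap)
    best: PoolAssignment | None = None
    best_score: PoolScore | None = None
    history: list[PoolScore] = []
    cycles = 0
    no_improve = 0
    t0 = time.monotonic()
    while True:
        hill_climb(state, matrix)
        score = global_score(state, matrix)
        cycles += 1
        if best_score is None or score < best_score:
            best, best_score = state.copy(), score
            history.append(score)
            no_improve = 0
            logger.info("cycle %d: new best %s; pools %s", cycles,
                        score.as_tuple(),
                        [len(p) for p in state.pools()])
        else:
            no_improve += 1
        if (no_improve >= patience
                or (max_cycles is not None and cycles >= max_cycles)
                or (time_limit is not None
                    and time.monotonic() - t0 > time_limit)):
            break
        if score <= best_score:
            perturb(state, rng)
        else:
            state = random_assignment(n, k, rng, size_cap)
    assert best is not None and best_score is not None
    return PartitionResult(best, best_score, history, cycles)


def suggest_pool_count(matrix: PairMatrix, threshold_range: int = 14) -> int:
    """Single-pass first-fit packing under a ΔG −7 threshold (range 14).

    Pairs are taken in input order; each goes into the first pool where its
    worst cross-interaction stays below the threshold (overlap-saturated
    entries can never pass), opening a new pool when none fits.
    """
    pools: list[list[int]] = []
    for pair in range(matrix.n_pairs):
        placed = False
        for members in pools:
            worst = max((r for m in members for r in matrix.ranges(pair, m)),
                        default=0)
            if worst < threshold_range:
                members.append(pair)
                placed = True
                break
        if not placed:
            pools.append([pair])
    return max(1, len(pools))


def brute_force_optimum(matrix: PairMatrix, k: int) -> tuple[PoolScore, tuple[int, ...]]:
    """Exhaustive search over k**n assignments (small n only); the oracle the
    hill climber is checked against."""
    n = matrix.n_pairs
    best_score: PoolScore | None = None
    best_assign: tuple[int, ...] = ()
    assign = [1] * n
    pair_ranges = {
        (i, j): matrix.ranges(i, j) for i in range(n) for j in range(i + 1, n)
    }

    def rec(idx: int) -> None:
        nonlocal best_score, best_assign
        if idx == n:
            ranges = [r for (i, j), rs in pair_ranges.items()
                      if assign[i] == assign[j] for r in rs]
            s = PoolScore.from_ranges(ranges)
            if best_score is None or s < best_score:
                best_score, best_assign = s, tuple(assign)
            return
        # fix pair 0 in pool 1 (pool labels are symmetric)
        top = 1 if idx == 0 else k
        for p in range(1, top + 1):
            assign[idx] = p
            rec(idx + 1)

    rec(0)
    assert best_score is not None
    return best_score, best_assign
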