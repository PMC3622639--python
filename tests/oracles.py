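"""Independent brute-force oracles used to cross-check the implementation.

Each oracle solves the same mathematical problem as a production routine
by a different method (vertex enumeration, exhaustive subset search,
recursive path enumeration), so agreement is evidence of correctness
rather than a tautology.
"""

from __future__ import annotations

import itertools
from math import isclose
from typing import Optional, Sequence

import numpy as np


def lp_objective_oracle(
    member_ranges: Sequence[tuple[int, int]],
    interval_lengths: Sequence[float],
    mean_coverages: Sequence[float],
    lower_bound: float = 0.0,
) -> Optional[float]:
    """Minimum total slack by vertex enumeration of the reduced problem.

    With the slack variables eliminated (at the optimum each slack equals
    its constraint's absolute residual), the objective is the convex
    piecewise-linear function

        g(c) = sum_j |sum_i c_ij - Cbar_j| + sum_adj |c_ij - c_i,j+1|

    over the polytope {conservation equality, c >= lower_bound}.  The
    optimum lies at a vertex of the kink-hyperplane arrangement restricted
    to the polytope; all candidate vertices are enumerated by solving every
    full-rank system of active constraints.
    """
    c_vars = [
        (i, j)
        for i, (a, b) in enumerate(member_ranges)
        for j in range(a, b + 1)
    ]
    d = len(c_vars)
    col = {v: k for k, v in enumerate(c_vars)}
    n_iv = len(interval_lengths)
    total = float(np.dot(mean_coverages, interval_lengths))

    def g(c: np.ndarray) -> float:
        val = 0.0
        for j in range(n_iv):
            s = sum(c[col[(i, jj)]] for (i, jj) in c_vars if jj == j)
            val += abs(s - mean_coverages[j])
        for i, (a, b) in enumerate(member_ranges):
            for j in range(a, b):
                val += abs(c[col[(i, j)]] - c[col[(i, j + 1)]])
        return val

    # candidate active hyperplanes: conservation (always), additivity kinks,
    # continuity kinks, lower bounds
    planes: list[tuple[np.ndarray, float]] = []
    conserve = np.array([interval_lengths[j] for (_, j) in c_vars], dtype=float)
    for j in range(n_iv):
        row = np.zeros(d)
        for (i, jj) in c_vars:
            if jj == j:
                row[col[(i, jj)]] = 1.0
        planes.append((row, float(mean_coverages[j])))
    for i, (a, b) in enumerate(member_ranges):
        for j in range(a, b):
            row = np.zeros(d)
            row[col[(i, j)]] = 1.0
            row[col[(i, j + 1)]] = -1.0
            planes.append((row, 0.0))
    for k in range(d):
        row = np.zeros(d)
        row[k] = 1.0
        planes.append((row, lower_bound))

    best = None
    for combo in itertools.combinations(range(len(planes)), d - 1):
        a_rows = [conserve] + [planes[k][0] for k in combo]
        b_vals = [total] + [planes[k][1] for k in combo]
        a = np.array(a_rows)
        if np.linalg.matrix_rank(a) < d:
            continue
        try:
            c = np.linalg.solve(a, np.array(b_vals))
        except np.linalg.LinAlgError:
            continue
        if np.any(c < lower_bound - 1e-9):
            continue
        if not isclose(float(conserve @ c), total, abs_tol=1e-6):
            continue
        val = g(c)
        if best is None or val < best:
            best = val
    if d == 1:
        # single variable: conservation fixes it outright
        c = np.array([total / conserve[0]])
        if c[0] >= lower_bound - 1e-9:
            v = g(c)
            best = v if best is None else min(best, v)
    return best


def min_set_cover(sat: Sequence[set[int]], universe: set[int]) -> Optional[int]:
    """Exhaustive minimum number of sets covering the universe."""
    n = len(sat)
    best = None
    for size in range(0, n + 1):
        for combo in itertools.combinations(range(n), size):
            covered = set()
            for t in combo:
                covered |= sat[t]
            if universe <= covered:
                return size
    return best


def min_weighted_cover_cost(
    sat: Sequence[set[int]], universe: set[int], weights: Sequence[float]
) -> Optional[float]:
    """Exhaustive minimum total weight of a cover."""
    n = len(sat)
    best = None
    for mask in range(1 << n):
        covered = set()
        cost = 0.0
        for t in range(n):
            if mask & (1 << t):
                covered |= sat[t]
                cost += weights[t]
        if universe <= covered and (best is None or cost < best):
            best = cost
    return best


def harmonic(d: int) -> float:
    return sum(1.0 / i for i in range(1, d + 1)) if d >= 1 else 1.0


def count_maximal_paths(adj: dict[int, list[int]], n_nodes: int) -> int:
    """Source-to-sink path count by plain recursive enumeration."""
    indeg = {v: 0 for v in range(n_nodes)}
    for u, vs in adj.items():
        for v in vs:
            indeg[v] += 1
    sources = [v for v in range(n_nodes) if indeg[v] == 0]

    def walk(u: int) -> int:
        succ = adj.get(u, [])
        if not succ:
            return 1
        return sum(walk(v) for v in succ)

    return sum(walk(s) for s in sources)
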