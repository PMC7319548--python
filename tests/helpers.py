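"""Test-only oracles, independent of the library's dynamic programming."""

from __future__ import annotations

import itertools


def brute_force_min_cost(a_values, b_values, gap_penalty):
    """Minimum total alignment cost by explicit enumeration of all global
    alignments (monotone lattice paths), summing costs left to right.

    Also returns the smallest gap-column count among cost-optimal
    alignments.  Exponential; lengths must stay tiny.
    """
    n, m = len(a_values), len(b_values)
    cost = [[abs(a_values[i] - b_values[j]) for j in range(m)]
            for i in range(n)]
    results: list[tuple[float, int]] = []

    def explore(i, j, acc, gaps):
        if i == n and j == m:
            results.append((acc, gaps))
            return
        if i < n and j < m:
            explore(i + 1, j + 1, acc + cost[i][j], gaps)
        if i < n:
            explore(i + 1, j, acc + gap_penalty, gaps + 1)
        if j < m:
            explore(i, j + 1, acc + gap_penalty, gaps + 1)

    explore(0, 0, 0.0, 0)
    best = min(acc for acc, _ in results)
    best_gaps = min(g for acc, g in results if acc == best)
    return best, best_gaps


def all_grid_profiles(max_len, grid):
    """Every value tuple of length 1..max_len over the grid."""
    out = []
    for length in range(1, max_len + 1):
        out.extend(itertools.product(grid, repeat=length))
    return out
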