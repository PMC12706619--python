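"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: flood fill by BFS over
explicit neighbour offsets, Dice from Python sets, Wilcoxon p by full
enumeration of sign assignments.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def neighbour_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(v) for v in d)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append(d)
    return offs


def flood_fill_components(grid: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected foreground components as sets of index tuples (BFS)."""
    offs = neighbour_offsets(connectivity)
    shape = grid.shape
    todo = {tuple(ix) for ix in np.argwhere(grid > 0)}
    components = []
    while todo:
        seed = min(todo)  # deterministic order
        comp = {seed}
        todo.discard(seed)
        queue = deque([seed])
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offs:
                nb = (x + dx, y + dy, z + dz)
                if (
                    0 <= nb[0] < shape[0]
                    and 0 <= nb[1] < shape[1]
                    and 0 <= nb[2] < shape[2]
                    and nb in todo
                ):
                    todo.discard(nb)
                    comp.add(nb)
                    queue.append(nb)
        components.append(comp)
    return components


def largest_component_oracle(grid: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Largest component; ties broken by smallest lexicographic minimum index."""
    comps = flood_fill_components(grid, connectivity)
    # tie-break: among equal sizes prefer the smallest min-index component
    biggest = max(len(c) for c in comps)
    candidates = [c for c in comps if len(c) == biggest]
    best = min(candidates, key=min)
    out = np.zeros_like(grid)
    for ix in best:
        out[ix] = 1
    return out


def fill_holes_oracle(grid: np.ndarray) -> np.ndarray:
    """Fill background unreachable from the border under 6-connectivity."""
    shape = grid.shape
    bg = grid == 0
    reached = np.zeros(shape, dtype=bool)
    queue = deque()
    for ix in np.argwhere(bg):
        x, y, z = ix
        if (
            x in (0, shape[0] - 1)
            or y in (0, shape[1] - 1)
            or z in (0, shape[2] - 1)
        ):
            t = (int(x), int(y), int(z))
            if not reached[t]:
                reached[t] = True
                queue.append(t)
    offs = neighbour_offsets(6)
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in offs:
            nb = (x + dx, y + dy, z + dz)
            if (
                0 <= nb[0] < shape[0]
                and 0 <= nb[1] < shape[1]
                and 0 <= nb[2] < shape[2]
                and bg[nb]
                and not reached[nb]
            ):
                reached[nb] = True
                queue.append(nb)
    out = np.ones(shape, dtype=grid.dtype)
    out[bg & reached] = 0
    return out


def dice_oracle(a: np.ndarray, b: np.ndarray) -> float:
    sa = {tuple(ix) for ix in np.argwhere(a > 0)}
    sb = {tuple(ix) for ix in np.argwhere(b > 0)}
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def wilcoxon_enumeration(diffs) -> tuple[float, float]:
    """(W, two-sided p) by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = _midranks(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count_le = count_ge = 0
    for pattern in itertools.product((False, True), repeat=n):
        w = ranks[np.array(pattern, dtype=bool)].sum() if any(pattern) else 0.0
        if w <= w_obs + 1e-12:
            count_le += 1
        if w >= w_obs - 1e-12:
            count_ge += 1
    total = 2**n
    p = min(1.0, 2.0 * min(count_le, count_ge) / total)
    return float(w_obs), p


def boundary_voxels_oracle(grid: np.ndarray) -> set:
    """Voxels that are foreground with a 6-neighbour background (or vice versa)."""
    shape = grid.shape
    offs = neighbour_offsets(6)
    out = set()
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                v = grid[x, y, z] > 0
                for dx, dy, dz in offs:
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                        nb = grid[nx, ny, nz] > 0
                    else:
                        nb = False  # outside the grid counts as background
                    if nb != v:
                        out.add((x, y, z))
                        break
    return out
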