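"""Independent test oracles, kept free of the implementation's internals."""

import heapq
import math


def dijkstra_oracle(rates, elevation, cell_size, start, params,
                    directional=True):
    """Textbook Dijkstra with explicit relaxation over the 8-neighbor
    cell graph; returns every reachable cell's fire-arrival time."""
    nrows, ncols = rates.shape
    dist = {start: 0.0}
    visited = set()
    heap = [(0.0, start)]
    offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
               if (di, dj) != (0, 0)]
    while heap:
        t, node = heapq.heappop(heap)
        if node in visited:
            continue
        visited.add(node)
        i, j = node
        if rates[i, j] <= 0:
            continue
        for di, dj in offsets:
            ni, nj = i + di, j + dj
            if not (0 <= ni < nrows and 0 <= nj < ncols):
                continue
            if rates[ni, nj] <= 0:
                continue
            d = math.hypot(di, dj) * cell_size
            rate = 0.5 * (rates[i, j] + rates[ni, nj])
            if directional:
                rise = elevation[ni, nj] - elevation[i, j]
                if rise > 0:
                    rate *= math.exp(
                        params.slope_coef * (rise / d) ** params.slope_exp)
            nt = t + d / rate
            if nt < dist.get((ni, nj), math.inf):
                dist[(ni, nj)] = nt
                heapq.heappush(heap, (nt, (ni, nj)))
    return dist


def random_fuel_landscape(make_uniform_landscape, rng, nrows=30, ncols=30,
                          barrier_frac=0.1, relief=300.0):
    """Heterogeneous single-fuel-per-cell landscape with random barriers."""
    import numpy as np

    fuels = ["pine", "fir", "broadleaf", "others"]
    props = {f"prop_{f}": np.zeros((nrows, ncols)) for f in fuels}
    pick = rng.integers(0, 4, size=(nrows, ncols))
    for k, f in enumerate(fuels):
        props[f"prop_{f}"][pick == k] = 1.0
    burnable = rng.random((nrows, ncols)) > barrier_frac
    grid = make_uniform_landscape(nrows, ncols, burnable=burnable, **props)
    grid.elevation = rng.uniform(0, relief, size=(nrows, ncols))
    return grid
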