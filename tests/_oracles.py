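"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: dense-grid scanning
instead of closed-form interpolation, exhaustive pairwise BFS instead of
union-find, linear scans instead of bisect.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from qpcrmap.core import NO_CROSSING


def dense_grid_ct(cycles, readings, threshold, step=1e-4):
    """First grid point of the piecewise-linear curve at/above threshold."""
    cycles = np.asarray(cycles, dtype=float)
    readings = np.asarray(readings, dtype=float)
    grid = np.arange(cycles[0], cycles[-1] + step / 2, step)
    values = np.interp(grid, cycles, readings)
    above = np.nonzero(values >= threshold)[0]
    if len(above) == 0:
        return NO_CROSSING
    return float(grid[above[0]])


def dense_grid_sigmoid_root(baseline, plateau, c_half, k, threshold,
                            c_min=1.0, c_max=45.0, step=1e-4):
    """Dense-grid root of the continuous logistic itself (no sampling)."""
    grid = np.arange(c_min, c_max + step / 2, step)
    values = baseline + plateau / (1.0 + np.exp(-(grid - c_half) / k))
    above = np.nonzero(values >= threshold)[0]
    if len(above) == 0:
        return NO_CROSSING
    return float(grid[above[0]])


def brute_force_label(ct, scheme):
    """Re-bin one Ct by scanning every bin edge pair explicitly."""
    if ct is NO_CROSSING or ct >= scheme.cutoff:
        return "none detected"
    edges = list(scheme.bin_lower_bounds) + [scheme.cutoff]
    for i, label in enumerate(scheme.labels):
        if edges[i] <= ct < edges[i + 1]:
            return label
    return scheme.labels[0]  # below the first bound


def brute_force_components(coords, tol):
    """Connected components under the box-linkage rule, via BFS over all pairs."""
    n = len(coords)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if (
                abs(coords[i][0] - coords[j][0]) <= tol
                and abs(coords[i][1] - coords[j][1]) <= tol
            ):
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    components = []
    for s in range(n):
        if seen[s]:
            continue
        comp, queue = [], deque([s])
        seen[s] = True
        while queue:
            u = queue.popleft()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    queue.append(v)
        components.append(tuple(sorted(comp)))
    return sorted(components)


def brute_force_filter(records, scope, species, date_range):
    """Row-by-row predicate evaluation, no set machinery."""
    out = []
    for r in records:
        ok = True
        if scope is not None:
            ok = ok and any(r.metadata.organismScope == s for s in scope)
        if species is not None:
            ok = ok and any(r.metadata.species == s for s in species)
        if date_range is not None:
            ok = ok and date_range[0] <= r.metadata.eventDate <= date_range[1]
        if ok:
            out.append(r)
    return out
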