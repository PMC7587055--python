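"""Record filtering, coordinate clustering, and spiderfy layout.

Biological replicates are often taken at (nearly) the same spot; points whose
latitude AND longitude differ by no more than a tolerance (default 0.005
degrees) are collapsed into one cluster. The pairwise rule is extended to
connected components (single linkage via union-find), so a chain of points
each within tolerance of the next forms one cluster. Members of a
multi-point cluster get deterministic display offsets on a circle around the
centroid ("spiderfy") so each replicate stays individually visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Sequence

from .platform_io import MergedRecord

DEFAULT_CLUSTER_TOL = 0.005
DEFAULT_SPIDER_RADIUS = 0.0008


@dataclass(frozen=True)
class GeoCluster:
    """A set of records collapsed into one map point."""

    members: tuple[int, ...]            # record indices, ascending
    centroid: tuple[float, float]       # (lat, lon) mean of members
    spider_offsets: tuple[tuple[float, float], ...]  # per-member (dlat, dlon)


def filter_records(
    records: Sequence[MergedRecord],
    scope: Sequence[str] | None = None,
    species: Sequence[str] | None = None,
    date_range: tuple[date, date] | None = None,
) -> list[MergedRecord]:
    """Conjunction of the organism-scope, species, and time-range filters.

    An absent filter passes everything; the date range is inclusive on both
    ends.
    """
    if date_range is not None:
        start, end = date_range
        if start > end:
            raise ValueError(f"date_range start {start} after end {end}")
    scope_set = set(scope) if scope is not None else None
    species_set = set(species) if species is not None else None

    kept = []
    for r in records:
        m = r.metadata
        if scope_set is not None and m.organismScope not in scope_set:
            continue
        if species_set is not None and m.species not in species_set:
            continue
        if date_range is not None and not (start <= m.eventDate <= end):
            continue
        kept.append(r)
    return kept


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def spiderfy_offsets(
    n: int, radius_degrees: float = DEFAULT_SPIDER_RADIUS
) -> tuple[tuple[float, float], ...]:
    """Equal-angle circle offsets for ``n`` members; a singleton stays put."""
    if n < 1:
        raise ValueError("need at least one member")
    if n == 1:
        return ((0.0, 0.0),)
    out = []
    for k in range(n):
        theta = 2.0 * math.pi * k / n
        out.append((radius_degrees * math.cos(theta), radius_degrees * math.sin(theta)))
    return tuple(out)


def spiderfy(
    cluster: GeoCluster, radius_degrees: float = DEFAULT_SPIDER_RADIUS
) -> tuple[tuple[float, float], ...]:
    """Display offsets for a cluster's members, in member order."""
    return spiderfy_offsets(len(cluster.members), radius_degrees)


def cluster_points(
    records: Sequence[MergedRecord],
    tol_degrees: float = DEFAULT_CLUSTER_TOL,
    spider_radius_degrees: float = DEFAULT_SPIDER_RADIUS,
) -> list[GeoCluster]:
    """Collapse near-coincident records into clusters.

    Two records are directly linked iff both |Δlat| <= tol and |Δlon| <= tol;
    clusters are the connected components of that link graph. The returned
    list is sorted by (centroid latitude, centroid longitude) and is
    invariant under permutation of the input records (up to the record
    indices themselves).
    """
    n = len(records)
    coords = [
        (r.metadata.decimalLatitude, r.metadata.decimalLongitude) for r in records
    ]
    uf = _UnionFind(n)
    order = sorted(range(n), key=lambda i: coords[i])
    for a in range(n):
        i = order[a]
        for b in range(a + 1, n):
            j = order[b]
            if coords[j][0] - coords[i][0] > tol_degrees:
                break  # sorted by latitude: no later point can link to i
            if abs(coords[i][1] - coords[j][1]) <= tol_degrees:
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    clusters = []
    for members in groups.values():
        members = tuple(sorted(members))
        lat = sum(coords[i][0] for i in members) / len(members)
        lon = sum(coords[i][1] for i in members) / len(members)
        clusters.append(
            GeoCluster(
                members=members,
                centroid=(lat, lon),
                spider_offsets=spiderfy_offsets(len(members), spider_radius_degrees),
            )
        )
    clusters.sort(key=lambda c: c.centroid)
    return clusters
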