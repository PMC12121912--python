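"""Candidate inversion detection from distal excess barcode sharing."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sharing import SharingMatrix, SharingNull


@dataclass
class InversionCandidate:
    chrom: str
    start: int
    end: int
    n_pairs: int
    peak_z: float
    total_shared: int

    @property
    def interval(self):
        return (self.chrom, self.start, self.end)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def detect_inversion_candidates(matrix: SharingMatrix, null: SharingNull,
                                z_min: float = 5.0,
                                min_pair_cluster: int = 3,
                                cluster_radius: int = 2) -> list:
    """Cluster distal window pairs with z >= ``z_min`` into candidates.

    Pairs are clustered when both their window coordinates are within
    ``cluster_radius`` windows of another pair in the cluster.
    Breakpoints are read off the cluster's corner structure: molecules
    crossing the left breakpoint join windows just left of it to the
    interior end of the inversion, molecules crossing the right
    breakpoint join the interior start to windows just right of it, so
    the two maximal pairs sit diagonally adjacent across both
    breakpoints and the boundary between them is the breakpoint pair.
    An empty list is returned when nothing clusters.
    """
    out = []
    tile = matrix.tile
    for chrom, counter in matrix.counts.items():
        hits = []
        for (i, j), c in counter.items():
            if not matrix.is_distal(i, j):
                continue
            mu, sigma = null.mu_sigma(j - i)
            z = (c - mu) / sigma
            if z >= z_min:
                hits.append((i, j, c, z))
        if len(hits) < min_pair_cluster:
            continue
        uf = _UnionFind(len(hits))
        for a in range(len(hits)):
            for b in range(a + 1, len(hits)):
                if abs(hits[a][0] - hits[b][0]) <= cluster_radius and \
                        abs(hits[a][1] - hits[b][1]) <= cluster_radius:
                    uf.union(a, b)
        clusters: dict[int, list] = {}
        for a in range(len(hits)):
            clusters.setdefault(uf.find(a), []).append(hits[a])
        for members in clusters.values():
            if len(members) < min_pair_cluster:
                continue
            arr = np.asarray(members, dtype=float)
            weights = arr[:, 2]
            i_peak, j_peak, _, _ = members[int(np.argmax(weights))]
            plus = counter.get((i_peak + 1, j_peak + 1), 0)
            minus = counter.get((i_peak - 1, j_peak - 1), 0)
            if plus >= minus:
                # peak is the corner left of both breakpoints
                start = (i_peak + 1) * tile
                end = (j_peak + 1) * tile
            else:
                start = i_peak * tile
                end = j_peak * tile
            if end - start < matrix.distal_min:
                continue
            out.append(InversionCandidate(
                chrom=chrom, start=start, end=end,
                n_pairs=len(members),
                peak_z=float(arr[:, 3].max()),
                total_shared=int(weights.sum())))
    out.sort(key=lambda c: -c.peak_z)
    # long molecules can shed satellite pair clusters inside a strong
    # candidate; keep only the dominant call per overlapping region
    kept: list[InversionCandidate] = []
    for cand in out:
        overlap = False
        for other in kept:
            if cand.chrom != other.chrom:
                continue
            shared_span = min(cand.end, other.end) - max(cand.start,
                                                         other.start)
            if shared_span > 0.5 * (cand.end - cand.start):
                overlap = True
                break
        if not overlap:
            kept.append(cand)
    return kept
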