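"""Window-pair barcode sharing and its distance-decay null model.

Barcode co-occurrence between two windows normally decays with distance
on the scale of the molecule length; excess sharing between distal
windows is the signature of a rearrangement joining them.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ..core import Windows


@dataclass
class SharingMatrix:
    """Shared-barcode counts per same-chromosome window pair.

    ``counts[chrom][(i, j)]`` (window indices, i < j) is the number of
    barcodes seen in both windows, summed over samples; pairs never
    sharing a barcode are implicit zeros.  ``pair class`` is distal when
    the window distance is at least ``distal_min`` bp.
    """

    tile: int
    distal_min: int
    n_windows: dict
    counts: dict
    per_sample: dict | None = None

    def pair_distance(self, i: int, j: int) -> int:
        return abs(j - i) * self.tile

    def is_distal(self, i: int, j: int) -> bool:
        return self.pair_distance(i, j) >= self.distal_min

    def shared(self, chrom: str, i: int, j: int) -> int:
        if i == j:
            raise ValueError("pair must involve two distinct windows")
        i, j = min(i, j), max(i, j)
        return int(self.counts.get(chrom, {}).get((i, j), 0))

    def n_pairs_at_distance(self, d: int) -> int:
        return sum(max(n - d, 0) for n in self.n_windows.values())


def build_sharing_matrix(barcode_map: pd.DataFrame, windows: Windows,
                         distal_min: int = 500_000,
                         per_sample: bool = False) -> SharingMatrix:
    """Count shared barcodes for every same-chromosome window pair.

    ``barcode_map`` is the long-format map (sample, chrom, window_start,
    barcode) on the non-overlapping tile grid of ``windows``.
    """
    if windows.size != windows.step:
        raise ValueError("barcode sharing requires non-overlapping tiles")
    tile = windows.size
    if len(barcode_map) and (barcode_map["window_start"] % tile != 0).any():
        raise ValueError("window grid mismatch with barcode map")
    unknown = set(barcode_map["chrom"]) - set(windows.chrom_lengths)
    if unknown:
        raise ValueError(f"barcode map names unknown chromosomes {unknown}")

    counts: dict[str, Counter] = {c: Counter() for c in windows.chrom_lengths}
    per_sample_counts: dict = {} if per_sample else None
    if len(barcode_map):
        frame = barcode_map.assign(
            _win=(barcode_map["window_start"] // tile).astype(np.int64))
        for (sample, chrom, _), grp in frame.groupby(
                ["sample", "chrom", "barcode"], sort=False):
            wins = sorted(set(grp["_win"]))
            if len(wins) < 2:
                continue
            for pair in combinations(wins, 2):
                counts[chrom][pair] += 1
                if per_sample:
                    per_sample_counts.setdefault(
                        sample, {}).setdefault(
                        chrom, Counter())[pair] += 1
    n_windows = {c: windows.n_windows(c) for c in windows.chrom_lengths}
    return SharingMatrix(tile=tile, distal_min=distal_min,
                         n_windows=n_windows, counts=dict(counts),
                         per_sample=per_sample_counts)


# ---------------------------------------------------------------------
@dataclass
class SharingNull:
    """Robust location/scale of shared counts per distance bin.

    Bins are log-spaced in window distance; ``mu`` is the median shared
    count (implicit zeros included), ``sigma`` the larger of the
    MAD-derived scale, the standard deviation and a floor of 1 (distal
    sharing is near-degenerate at zero, and the floor keeps z-scores
    finite and conservative).
    """

    bins: pd.DataFrame = field(default_factory=pd.DataFrame)

    def mu_sigma(self, d_windows: int) -> tuple[float, float]:
        b = self.bins
        row = b[(b.d_lo <= d_windows) & (d_windows < b.d_hi)]
        if row.empty:
            row = b.iloc[[-1]]
        return float(row.mu.iloc[0]), float(row.sigma.iloc[0])


def _quantile_with_zeros(values: np.ndarray, n_zero: int, q: float) -> float:
    total = len(values) + n_zero
    if total == 0:
        return 0.0
    k = int(q * (total - 1))
    if k < n_zero:
        return 0.0
    return float(np.sort(values)[k - n_zero])


def _log_bin_edges(max_d: int) -> np.ndarray:
    if max_d < 2:
        return np.array([1, max_d + 1])
    edges = np.unique(np.round(np.geomspace(1, max_d + 1, num=18))
                      .astype(int))
    if edges[-1] <= max_d:
        edges = np.append(edges, max_d + 1)
    return edges


def distance_decay_null(matrix: SharingMatrix, exclude=None,
                        min_pairs: int = 20) -> SharingNull:
    """Estimate the sharing null per distance bin.

    ``exclude`` is an optional list of (chrom, start, end) seed regions
    whose windows are left out (for re-iteration after candidates have
    been found).  Bins with fewer than ``min_pairs`` pairs are merged
    with their neighbor.
    """
    excl = {}
    for chrom, s, e in (exclude or []):
        excl.setdefault(chrom, []).append(
            (s // matrix.tile, (e - 1) // matrix.tile))

    max_d = max(matrix.n_windows.values()) - 1
    edges = _log_bin_edges(max(max_d, 1))
    by_bin_vals: list[list] = [[] for _ in range(len(edges) - 1)]
    by_bin_excluded = np.zeros(len(edges) - 1, dtype=np.int64)

    def excluded(chrom, i, j):
        for lo, hi in excl.get(chrom, []):
            if lo <= i <= hi or lo <= j <= hi:
                return True
        return False

    n_excluded_pairs_at: Counter = Counter()
    for chrom, counter in matrix.counts.items():
        for (i, j), c in counter.items():
            d = j - i
            if excluded(chrom, i, j):
                n_excluded_pairs_at[d] += 1
                continue
            b = int(np.searchsorted(edges, d, side="right") - 1)
            b = min(max(b, 0), len(by_bin_vals) - 1)
            by_bin_vals[b].append(c)
    # windows fully excluded also reduce the zero-pair totals; for the
    # regimes of interest exclusion regions are a small genome fraction,
    # so only observed (nonzero) excluded pairs are discounted.
    rows = []
    pending_vals: list = []
    pending_total = 0
    pending_lo = edges[0]
    for b in range(len(by_bin_vals)):
        d_lo, d_hi = int(edges[b]), int(edges[b + 1])
        total = sum(matrix.n_pairs_at_distance(d)
                    for d in range(d_lo, d_hi))
        total -= sum(n_excluded_pairs_at.get(d, 0)
                     for d in range(d_lo, d_hi))
        pending_vals.extend(by_bin_vals[b])
        pending_total += max(total, 0)
        if pending_total < min_pairs and b < len(by_bin_vals) - 1:
            continue
        vals = np.asarray(pending_vals, dtype=float)
        n_zero = max(pending_total - len(vals), 0)
        mu = _quantile_with_zeros(vals, n_zero, 0.5)
        abs_dev = np.abs(vals - mu)
        mad = _quantile_with_zeros(abs_dev, n_zero, 0.5)
        denom = max(pending_total, 1)
        mean = vals.sum() / denom
        var = max((vals ** 2).sum() / denom - mean ** 2, 0.0)
        sigma = max(1.4826 * mad, float(np.sqrt(var)), 1.0)
        rows.append((int(pending_lo), d_hi, mu, sigma, pending_total))
        pending_vals, pending_total, pending_lo = [], 0, d_hi
    if pending_total or pending_vals:
        # trailing underfull bin: merge into the last emitted row
        vals = np.asarray(pending_vals, dtype=float)
        if rows:
            lo, hi, mu, sigma, tot = rows[-1]
            rows[-1] = (lo, int(edges[-1]), mu, sigma,
                        tot + pending_total)
        else:
            rows.append((int(pending_lo), int(edges[-1]),
                         0.0, 1.0, pending_total))
    bins = pd.DataFrame(rows, columns=["d_lo", "d_hi", "mu", "sigma",
                                       "n_pairs"])
    return SharingNull(bins=bins)
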