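"""Delineate the shared sex-determination region by intersecting the
three evidence channels: elevated male-female Fst, male diversity
excess, and male-specific k-mer density."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SDRInterval:
    chrom: str | None
    start: int | None
    end: int | None
    flags: pd.DataFrame
    n_windows: int
    boundary_confidence: int

    @property
    def empty(self) -> bool:
        return self.chrom is None

    @property
    def interval(self):
        return None if self.empty else (self.chrom, self.start, self.end)


def _runs_with_gap(flags: np.ndarray, max_gap: int) -> list:
    """(start, end) index runs of True values, bridging gaps <= max_gap."""
    idx = np.flatnonzero(flags)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev <= max_gap + 1:
            prev = i
        else:
            runs.append((start, prev + 1))
            start = prev = i
    runs.append((start, prev + 1))
    return runs


def delineate_sdr(track: pd.DataFrame, fst_min: float,
                  pi_ratio_min: float = 2.0, kmer_min: int = 1,
                  kmer_rel: float = 0.3, min_run: int = 3,
                  max_gap: int = 1) -> SDRInterval:
    """Find the longest window run where all three evidence flags hold.

    ``track`` needs columns chrom, start, end, fst, pi_male, pi_female,
    kmer_count on one common grid.  A window is flagged when its Fst
    reaches ``fst_min``, its male:female pi ratio reaches
    ``pi_ratio_min``, and its k-mer count reaches both ``kmer_min`` and
    ``kmer_rel`` times the 95th percentile of positive windows (the
    relative cut separates the dense SDR peak from incidental
    sex-specific k-mers elsewhere).  Runs may bridge gaps of up to
    ``max_gap`` windows; shorter than ``min_run`` means no SDR.
    """
    required = {"chrom", "start", "end", "fst", "pi_male", "pi_female",
                "kmer_count"}
    missing = required - set(track.columns)
    if missing:
        raise ValueError(f"track lacks columns {sorted(missing)}")
    track = track.sort_values(["chrom", "start"]).reset_index(drop=True)
    dup = track.duplicated(subset=["chrom", "start", "end"])
    if dup.any():
        raise ValueError("duplicate windows: tracks on different grids?")

    eps = 1e-12
    positive = track.loc[track.kmer_count > 0, "kmer_count"]
    kmer_cut = max(kmer_min,
                   kmer_rel * (positive.quantile(0.95) if len(positive)
                               else 0.0))
    flags = pd.DataFrame({
        "chrom": track.chrom, "start": track.start, "end": track.end,
        "fst_elevated": (track.fst >= fst_min).fillna(False),
        "male_pi_excess": ((track.pi_male + eps)
                           / (track.pi_female + eps)) >= pi_ratio_min,
        "kmer_dense": track.kmer_count >= kmer_cut,
    })
    all_flags = (flags.fst_elevated & flags.male_pi_excess
                 & flags.kmer_dense).to_numpy()

    best = None
    for chrom, sub in flags.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        runs = _runs_with_gap(all_flags[idx], max_gap)
        for a, b in runs:
            if b - a < min_run:
                continue
            if best is None or (b - a) > (best[2] - best[1]):
                best = (chrom, a, b, idx)
    if best is None:
        return SDRInterval(None, None, None, flags, 0, 0)
    chrom, a, b, idx = best
    rows = flags.loc[idx[a:b]]
    none_flag = ~(flags.fst_elevated | flags.male_pi_excess
                  | flags.kmer_dense)
    conf = 1
    for side in (range(idx[a] - 1, idx[0] - 1, -1),
                 range(idx[b - 1] + 1, idx[-1] + 1)):
        dist = 1
        for i in side:
            if none_flag.iloc[i]:
                break
            dist += 1
        conf = max(conf, dist)
    return SDRInterval(chrom, int(rows.start.min()), int(rows.end.max()),
                       flags, b - a, conf)
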