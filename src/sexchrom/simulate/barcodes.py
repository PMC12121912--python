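"""Molecule-level linked-read barcode simulation.

One barcode corresponds to one long DNA molecule.  Molecules are
contiguous intervals on the sample's *haplotype*; on an inverted
haplotype the coordinates inside the inversion are reflected when mapped
back to the reference, so a molecule spanning an inversion breakpoint
produces a split reference footprint joining the two distal
breakpoint-flanking regions.  That footprint is what the barcode-sharing
screen detects.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig, TruthSidecar


def hap_to_ref_segments(a: int, b: int, inverted_intervals) -> list:
    """Map a haplotype-coordinate interval [a, b) to reference segments.

    ``inverted_intervals`` is a sorted list of (start, end) intervals that
    are inverted on this haplotype.  Positions inside an inversion
    (s, e) map to ``s + e - 1 - x``; the returned segments are merged
    where contiguous and sorted by start.
    """
    segs = []
    cur = a
    for s, e in inverted_intervals:
        if b <= s:
            break
        if cur < s:
            segs.append((cur, min(b, s)))
            cur = min(b, s)
        if cur >= b:
            break
        lo, hi = max(cur, s), min(b, e)
        if lo < hi:
            segs.append((s + e - hi, s + e - lo))
            cur = hi
    if cur < b:
        segs.append((cur, b))
    segs.sort()
    merged = [list(segs[0])]
    for s0, s1 in segs[1:]:
        if s0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], s1)
        else:
            merged.append([s0, s1])
    return [tuple(m) for m in merged]


@dataclass
class MoleculeSet:
    """All simulated molecules with their reference footprints.

    ``segments[i]`` is the list of (start, end) reference segments of
    molecule ``i``; parallel arrays give sample, barcode and chromosome.
    """

    sample: np.ndarray
    barcode: np.ndarray
    chrom: np.ndarray
    segments: list

    def __len__(self):
        return len(self.barcode)

    # ------------------------------------------------------------------
    def to_barcode_map(self, tile: int) -> pd.DataFrame:
        """Long-format barcode map: sample, chrom, window_start, barcode.

        Windows are non-overlapping tiles of ``tile`` bp; a barcode is
        listed in every tile its footprint overlaps.
        """
        samples, chroms, wins, bcs = [], [], [], []
        for i in range(len(self)):
            seen = set()
            for s, e in self.segments[i]:
                seen.update(range(s // tile, (max(e - 1, s)) // tile + 1))
            for w in sorted(seen):
                samples.append(self.sample[i])
                chroms.append(self.chrom[i])
                wins.append(w * tile)
                bcs.append(self.barcode[i])
        return pd.DataFrame({
            "sample": samples, "chrom": chroms,
            "window_start": np.asarray(wins, dtype=np.int64),
            "barcode": bcs,
        })

    # ------------------------------------------------------------------
    def junction_support(self, chrom: str, start: int, end: int,
                         tol: int = 2_000, margin: int = 2_000
                         ) -> pd.DataFrame:
        """Count molecules supporting the reference vs inverted junction
        of a candidate inversion [start, end) per sample.

        A molecule supports the reference junction when one contiguous
        footprint segment straddles a breakpoint by ``margin`` on each
        side; it supports the inverted junction when its footprint is
        split into segments whose endpoints meet the two breakpoints
        within ``tol`` in the orientation-reflected pattern.
        """
        counts: dict[str, list] = {}
        on_chrom = np.flatnonzero(self.chrom == chrom)
        for i in on_chrom:
            segs = self.segments[i]
            ref_hit = any(
                (s0 <= bp - margin and s1 >= bp + margin)
                for s0, s1 in segs for bp in (start, end)
            )
            inv_hit = False
            if len(segs) >= 2:
                end_near_s = any(abs(s1 - start) <= tol for _, s1 in segs)
                end_near_e = any(abs(s1 - end) <= tol for _, s1 in segs)
                start_near_s = any(abs(s0 - start) <= tol for s0, _ in segs)
                start_near_e = any(abs(s0 - end) <= tol for s0, _ in segs)
                inv_hit = (end_near_s and end_near_e) or \
                          (start_near_s and start_near_e)
            if ref_hit or inv_hit:
                row = counts.setdefault(self.sample[i], [0, 0])
                if ref_hit:
                    row[0] += 1
                if inv_hit:
                    row[1] += 1
        frame = pd.DataFrame(
            [(s, c[0], c[1]) for s, c in sorted(counts.items())],
            columns=["sample", "ref_junction", "inv_junction"],
        )
        return frame

    def table(self) -> pd.DataFrame:
        """Flat per-segment table (for TSV round-trips)."""
        rows = []
        for i in range(len(self)):
            for j, (s, e) in enumerate(self.segments[i]):
                rows.append((self.sample[i], self.barcode[i],
                             self.chrom[i], j, s, e))
        return pd.DataFrame(
            rows, columns=["sample", "barcode", "chrom",
                           "segment", "start", "end"])

    @classmethod
    def from_table(cls, frame: pd.DataFrame) -> "MoleculeSet":
        samples, bcs, chroms, segments = [], [], [], []
        for (sample, bc, chrom), grp in frame.groupby(
                ["sample", "barcode", "chrom"], sort=True):
            samples.append(sample)
            bcs.append(bc)
            chroms.append(chrom)
            grp = grp.sort_values("segment")
            segments.append(list(zip(grp["start"].astype(int),
                                     grp["end"].astype(int))))
        return cls(np.asarray(samples, dtype=object),
                   np.asarray(bcs, dtype=object),
                   np.asarray(chroms, dtype=object), segments)


def simulate_barcode_maps(gm, truth: TruthSidecar, cfg: SimConfig
                          ) -> tuple[MoleculeSet, pd.DataFrame]:
    """Simulate linked-read molecules for every sample.

    Returns the molecule set (from which per-sample barcode maps are
    derived with :meth:`MoleculeSet.to_barcode_map`) and the per-sample
    junction support table for every *true* inversion in the config.
    """
    if cfg.molecule_length_mean >= min(cfg.chrom_lengths.values()):
        raise ConfigError("molecule length must be below chromosome length")
    rng = np.random.default_rng([cfg.seed, 101])
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()

    samples = list(truth.sex)
    inv_by_chrom: dict[str, list] = {}
    for k, inv in enumerate(cfg.inversions):
        inv_by_chrom.setdefault(inv.chrom, []).append((k, inv))

    all_sample, all_bc, all_chrom, all_segs = [], [], [], []
    m = cfg.barcode_molecules_per_sample
    for si, sample in enumerate(samples):
        ci = rng.choice(len(chroms), size=m, p=chrom_p)
        hap = rng.integers(0, 2, size=m)
        lens = np.maximum(
            rng.exponential(cfg.molecule_length_mean, size=m), 200
        ).astype(np.int64)
        starts = (rng.random(m) * lengths[ci]).astype(np.int64)
        for j in range(m):
            chrom = chroms[ci[j]]
            a = int(starts[j])
            b = int(min(a + lens[j], cfg.chrom_lengths[chrom]))
            if b <= a:
                continue
            inverted = []
            for k, inv in inv_by_chrom.get(chrom, []):
                orient = truth.hap_orientations[inv.name]
                if orient[2 * si + hap[j]]:
                    inverted.append((inv.start, inv.end))
            inverted.sort()
            all_sample.append(sample)
            all_bc.append(f"{sample}:{j}")
            all_chrom.append(chrom)
            all_segs.append(hap_to_ref_segments(a, b, inverted))

    mols = MoleculeSet(
        np.asarray(all_sample, dtype=object),
        np.asarray(all_bc, dtype=object),
        np.asarray(all_chrom, dtype=object),
        all_segs,
    )

    support_rows = []
    for inv in cfg.inversions:
        js = mols.junction_support(inv.chrom, inv.start, inv.end, tol=1)
        js.insert(0, "inversion", inv.name)
        support_rows.append(js)
    junctions = (pd.concat(support_rows, ignore_index=True)
                 if support_rows else
                 pd.DataFrame(columns=["inversion", "sample",
                                       "ref_junction", "inv_junction"]))
    return mols, junctions
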