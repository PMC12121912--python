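"""Core data containers shared by every analysis stage.

Coordinates are 0-based, half-open throughout; VCF emission converts to
1-based on the way out.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SEXES = ("F", "M")


@dataclass
class GenotypeMatrix:
    """Biallelic sites x samples alt-allele dosage matrix.

    Attributes
    ----------
    chrom, pos : arrays of length n_sites
        Chromosome name and 0-based position of each site.  Sites are
        sorted by (chrom, pos).
    ref, alt : arrays of single-character alleles.
    gt : int8 array, shape (n_sites, n_samples)
        Alt-allele dosage in {0, 1, 2}, or -1 for a missing call.
    samples : list of sample identifiers (column order of ``gt``).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.samples = list(self.samples)
        if self.gt.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"gt shape {self.gt.shape} inconsistent with "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.asarray([lookup[n] for n in names], dtype=np.intp)

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        return GenotypeMatrix(
            self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx],
            self.gt[idx], self.samples,
        )

    def take_samples(self, names) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(
            self.chrom, self.pos, self.ref, self.alt,
            self.gt[:, idx], [self.samples[i] for i in idx],
        )

    def region_mask(self, chrom: str, start: int | None = None,
                    end: int | None = None) -> np.ndarray:
        m = self.chrom == chrom
        if start is not None:
            m &= self.pos >= start
        if end is not None:
            m &= self.pos < end
        return m

    def allele_counts(self, sample_names) -> tuple[np.ndarray, np.ndarray]:
        """Return per-site (n_alleles, alt_count) over the given samples.

        Missing genotypes are excluded per site: each non-missing diploid
        call contributes two alleles.
        """
        sub = self.gt[:, self.sample_indices(sample_names)]
        called = sub >= 0
        n_alleles = 2 * called.sum(axis=1)
        alt_count = np.where(called, sub, 0).sum(axis=1)
        return n_alleles.astype(np.int64), alt_count.astype(np.int64)

    def het_matrix(self) -> np.ndarray:
        """Boolean (sites x samples) heterozygous-call indicator."""
        return self.gt == 1

    def concat(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if self.samples != other.samples:
            raise ValueError("sample sets differ")
        return GenotypeMatrix(
            np.concatenate([self.chrom, other.chrom]),
            np.concatenate([self.pos, other.pos]),
            np.concatenate([self.ref, other.ref]),
            np.concatenate([self.alt, other.alt]),
            np.vstack([self.gt, other.gt]),
            self.samples,
        )


def make_sample_table(samples, sexes, population="sim") -> pd.DataFrame:
    """Build the canonical sample table (sample, sex, population)."""
    sexes = list(sexes)
    bad = sorted(set(sexes) - set(SEXES))
    if bad:
        raise ValueError(f"sex labels must be in {SEXES}, got {bad}")
    return pd.DataFrame(
        {"sample": list(samples), "sex": sexes,
         "population": population}
    )


def samples_by_sex(sample_table: pd.DataFrame, sex: str) -> list[str]:
    return list(sample_table.loc[sample_table["sex"] == sex, "sample"])


@dataclass
class PoolCounts:
    """Per-site read counts for one sequencing pool."""

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ref_reads: np.ndarray
    alt_reads: np.ndarray
    label: str = "pool"

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_reads = np.asarray(self.ref_reads, dtype=np.int64)
        self.alt_reads = np.asarray(self.alt_reads, dtype=np.int64)
        if (self.ref_reads < 0).any() or (self.alt_reads < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_reads + self.alt_reads

    @property
    def freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.depth > 0,
                            self.alt_reads / np.maximum(self.depth, 1),
                            np.nan)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos, "ref": self.ref,
            "alt": self.alt, "ref_reads": self.ref_reads,
            "alt_reads": self.alt_reads,
        })


@dataclass(frozen=True)
class Windows:
    """A sliding-window grid on a set of chromosomes.

    ``step <= size``; windows are clipped at the chromosome end so every
    base is covered.  ``tiles`` (step == size) are used by the barcode
    sharing analysis, the overlapping 20 kb / 10 kb grid by the
    statistics tracks.
    """

    chrom_lengths: dict
    size: int
    step: int

    def __post_init__(self):
        if not (0 < self.step <= self.size):
            raise ValueError("require 0 < step <= size")

    def starts(self, chrom: str) -> np.ndarray:
        length = self.chrom_lengths[chrom]
        last = max(length - self.step, 0)
        return np.arange(0, last + 1, self.step, dtype=np.int64)

    def frame(self) -> pd.DataFrame:
        rows = []
        for chrom, length in self.chrom_lengths.items():
            starts = self.starts(chrom)
            ends = np.minimum(starts + self.size, length)
            rows.append(pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def n_windows(self, chrom: str) -> int:
        return len(self.starts(chrom))

    def window_index(self, chrom: str, position) -> np.ndarray:
        """Tile index containing ``position`` (only valid for tiles)."""
        if self.size != self.step:
            raise ValueError("window_index is defined for tiles only")
        return np.asarray(position, dtype=np.int64) // self.step


def tile_windows(chrom_lengths: dict, tile: int) -> Windows:
    return Windows(dict(chrom_lengths), tile, tile)


def sliding_windows(chrom_lengths: dict, size: int = 20_000,
                    step: int = 10_000) -> Windows:
    return Windows(dict(chrom_lengths), size, step)


def assign_sites_to_windows(pos: np.ndarray, starts: np.ndarray,
                            size: int) -> list[np.ndarray]:
    """Indices of sites falling in each window (sites may repeat when
    windows overlap).  ``pos`` must be sorted."""
    out = []
    for s in starts:
        lo = np.searchsorted(pos, s, side="left")
        hi = np.searchsorted(pos, s + size, side="left")
        out.append(np.arange(lo, hi))
    return out
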