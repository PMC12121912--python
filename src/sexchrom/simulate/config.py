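"""Configuration and truth-sidecar types for the synthetic-data module."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

GENOTYPES = ("RR", "RI", "II")


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass
class InversionSpec:
    """A polymorphic inversion segregating in the cohort.

    Parameters
    ----------
    chrom, start, end
        Inverted interval, 0-based half-open.
    linkage : {"X", "Y", "autosomal"}
        Which haplotype class may carry the inverted orientation.  A
        Y-linked inversion is carried hemizygously by heterogametic
        samples only (genotype RI); an X-linked inversion segregates in
        both sexes and can be homozygous in females.
    genotype_freqs : mapping sex -> (RR, RI, II) frequencies, optional
        Per-sex genotype composition.  Each supplied row must sum to 1.
    allele_freq : float, optional
        Population frequency of the inverted orientation; used when
        ``genotype_freqs`` is not given (orientation then sampled per
        eligible haplotype).
    divergence_boost : float, optional
        Overrides the cohort-wide ``het_boost`` for this inversion.
    name : str
        Identifier used in truth sidecars.
    """

    chrom: str
    start: int
    end: int
    linkage: str = "autosomal"
    genotype_freqs: dict | None = None
    allele_freq: float | None = None
    divergence_boost: float | None = None
    name: str = "inv"

    def __post_init__(self):
        if self.linkage not in ("X", "Y", "autosomal"):
            raise ConfigError(f"unknown linkage {self.linkage!r}")
        if not (0 <= self.start < self.end):
            raise ConfigError("require 0 <= start < end")
        if self.genotype_freqs is not None:
            self.genotype_freqs = {
                sex: tuple(float(x) for x in row)
                for sex, row in self.genotype_freqs.items()}
            for sex, row in self.genotype_freqs.items():
                if len(row) != 3 or abs(sum(row) - 1.0) > 1e-9:
                    raise ConfigError(
                        f"genotype frequencies for sex {sex!r} must be a "
                        f"(RR, RI, II) triple summing to 1, got {row}")
                if self.linkage == "Y" and row[2] > 0:
                    raise ConfigError(
                        "a Y-linked inversion cannot be homozygous (II)")
        if self.genotype_freqs is None and self.allele_freq is None:
            raise ConfigError(
                "one of genotype_freqs / allele_freq is required")

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class GeneModel:
    chrom: str
    start: int
    end: int
    name: str


@dataclass
class SimConfig:
    """Parameters of a synthetic wild cohort.

    ``theta`` is the expected background per-bp heterozygosity;
    ``het_boost`` multiplies the per-bp divergence between opposite
    inversion orientations; ``sdr_divergence`` is the per-bp density of
    X-Y fixed differences inside the SDR.  Identical (config, seed)
    pairs produce byte-identical outputs.
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    chrom_lengths: dict = field(default_factory=dict)
    window_size: int = 20_000
    step: int = 10_000
    sdr_interval: tuple | None = None  # (chrom, start, end)
    inversions: list = field(default_factory=list)
    theta: float = 1e-3
    het_boost: float = 3.0
    sdr_divergence: float = 5e-3
    n_females: int = 10
    n_males: int = 10
    seed: int = 0
    depth_mean: float = 20.0
    depth_noise: bool = True
    barcode_molecules_per_sample: int = 4_000
    molecule_length_mean: int = 40_000
    error_rate: float = 0.0
    system: str = "XY"  # "XY" (male heterogamety) or "ZW"
    fixed_composition: bool = True
    n_lof_x: int = 0
    n_lof_y: int = 0

    def __post_init__(self):
        if not self.chrom_lengths:
            self.chrom_lengths = {
                f"chr{i + 1}": int(self.chrom_length)
                for i in range(self.n_chromosomes)
            }
        self.n_chromosomes = len(self.chrom_lengths)
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self):
        if not (0 < self.step <= self.window_size):
            raise ConfigError("require 0 < step <= window_size")
        for name, value in (("theta", self.theta),
                            ("error_rate", self.error_rate)):
            if not (0.0 <= value < 1.0):
                raise ConfigError(f"{name} must lie in [0, 1)")
        if self.system not in ("XY", "ZW"):
            raise ConfigError("system must be 'XY' or 'ZW'")
        if self.sdr_interval is not None:
            chrom, start, end = self.sdr_interval
            if chrom not in self.chrom_lengths:
                raise ConfigError(f"SDR chromosome {chrom!r} not simulated")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ConfigError("SDR interval outside its chromosome")
        seen: dict[str, list] = {}
        for inv in self.inversions:
            if inv.chrom not in self.chrom_lengths:
                raise ConfigError(
                    f"inversion chromosome {inv.chrom!r} not simulated")
            if inv.end > self.chrom_lengths[inv.chrom]:
                raise ConfigError(
                    f"inversion {inv.name} extends beyond {inv.chrom}")
            for other in seen.get(inv.chrom, []):
                if inv.start < other.end and other.start < inv.end:
                    raise ConfigError(
                        f"inversions {other.name} and {inv.name} overlap "
                        f"on {inv.chrom}")
            seen.setdefault(inv.chrom, []).append(inv)
        if self.molecule_length_mean >= min(self.chrom_lengths.values()):
            raise ConfigError(
                "molecule length must be below the chromosome length")

    # -- derived ------------------------------------------------------
    @property
    def het_sex(self) -> str:
        """Sex carrying the sex-specific haplotype (Y or W)."""
        return "M" if self.system == "XY" else "F"

    @property
    def samples(self) -> list[str]:
        return ([f"F{i:02d}" for i in range(self.n_females)]
                + [f"M{i:02d}" for i in range(self.n_males)])

    @property
    def sexes(self) -> list[str]:
        return ["F"] * self.n_females + ["M"] * self.n_males

    def to_dict(self) -> dict:
        d = asdict(self)
        d["inversions"] = [asdict(i) for i in self.inversions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["inversions"] = [InversionSpec(**i)
                           for i in d.get("inversions", [])]
        if d.get("sdr_interval") is not None:
            c, s, e = d["sdr_interval"]
            d["sdr_interval"] = (c, int(s), int(e))
        return cls(**d)


@dataclass
class CrossConfig:
    """A single-pair cross with sexed offspring pools.

    ``mother_haplotypes`` / ``father_haplotypes`` list, per parental
    haplotype, the carried inversion orientation for every inversion
    name (True = inverted).  The father's haplotype at index
    ``father_y_index`` is the Y; sons inherit it obligately, daughters
    inherit the father's other (X) haplotype.
    """

    mother_haplotypes: tuple = ({}, {})
    father_haplotypes: tuple = ({}, {})
    father_y_index: int = 1
    n_sons: int = 20
    n_daughters: int = 20
    pool_depth: int = 50

    def __post_init__(self):
        if self.father_y_index not in (0, 1):
            raise ConfigError("father_y_index must be 0 or 1")
        if self.n_sons + self.n_daughters <= 0:
            raise ConfigError("cross must produce at least one offspring")
        if self.pool_depth <= 0:
            raise ConfigError("pool_depth must be positive")

    def father_x_index(self) -> int:
        return 1 - self.father_y_index


@dataclass
class TruthSidecar:
    """Ground truth emitted alongside every synthetic artifact.

    The frames are serialisable; ``haplotypes`` and ``sites`` are
    in-memory extras used by the other emitters (barcode maps,
    sequences) to stay consistent with the genotype matrix.
    """

    sex: dict = field(default_factory=dict)
    inversion_genotypes: dict = field(default_factory=dict)
    sdr: tuple | None = None
    y_deleted_genes: list = field(default_factory=list)
    lof_variants: pd.DataFrame | None = None
    # in-memory extras (not serialised)
    haplotypes: dict = field(default_factory=dict, repr=False)
    sites: dict = field(default_factory=dict, repr=False)
    hap_orientations: dict = field(default_factory=dict, repr=False)
    hap_is_y: np.ndarray | None = field(default=None, repr=False)
    extras: dict = field(default_factory=dict, repr=False)

    def genotype_counts(self, inv_name: str, sexes: dict | None = None
                        ) -> pd.DataFrame:
        """True (sex x RR/RI/II) count table for one inversion."""
        sexes = sexes or self.sex
        gts = self.inversion_genotypes[inv_name]
        rows = {}
        for sex in ("F", "M"):
            counts = {g: 0 for g in GENOTYPES}
            for sample, gt in gts.items():
                if sexes[sample] == sex and gt in counts:
                    counts[gt] += 1
            rows[sex] = counts
        return pd.DataFrame(rows).T[list(GENOTYPES)]


def fixed_genotype_counts(freqs, n: int) -> dict:
    """Largest-remainder rounding of genotype frequencies into counts."""
    freqs = np.asarray(freqs, dtype=float)
    raw = freqs * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return dict(zip(GENOTYPES, (int(c) for c in counts)))
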