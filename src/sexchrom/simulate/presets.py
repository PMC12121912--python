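"""Bundled cohort presets.

``ct_like`` and ``ns_like`` are two contrasting wild-cohort
configurations at a 20 Mb desk scale: a large polymorphic X-linked
inversion segregating in both sexes, and a male-limited Y-specific
inversion, both containing the shared SDR.  Intervals sit on a 15 Mb
sex chromosome in proportion to their positions on a ~20.7 Mb
chromosome, aligned to the 10 kb grid.  ``scale`` shrinks the whole
genome (coordinates, molecule counts) for fast end-to-end tests.
``autosomal_like`` is the negative control.
"""
from __future__ import annotations

from .config import GeneModel, InversionSpec, SimConfig

# Table-shaped genotype compositions (RR, RI, II) by sex.
CT_X_INVERSION_FREQS = {"F": (0.0, 0.15, 0.85), "M": (0.15, 0.85, 0.0)}
NS_Y_INVERSION_FREQS = {"M": (0.07, 0.93, 0.0)}

_GRID = 20_000


def _sc(bp: int, scale: float) -> int:
    return max(int(round(bp * scale / _GRID)) * _GRID, _GRID)


def ct_like(seed: int = 1, scale: float = 1.0, **overrides) -> SimConfig:
    """CT-style cohort: 20 females / 20 males, X-linked inversion almost
    fixed in females, covering the SDR."""
    kw = dict(
        chrom_lengths={"chr1": _sc(5_000_000, scale),
                       "chr2": _sc(15_000_000, scale)},
        sdr_interval=("chr2", _sc(5_620_000, scale), _sc(6_160_000, scale)),
        inversions=[InversionSpec(
            chrom="chr2", start=_sc(5_620_000, scale),
            end=_sc(9_380_000, scale), linkage="X",
            genotype_freqs=CT_X_INVERSION_FREQS, name="invX")],
        theta=8e-4, het_boost=4.0, sdr_divergence=6e-3,
        n_females=20, n_males=20, seed=seed,
        depth_mean=20.0,
        barcode_molecules_per_sample=max(int(6_000 * scale), 1_500),
        molecule_length_mean=35_000, error_rate=0.01,
        fixed_composition=True, n_lof_x=2, n_lof_y=3,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def ns_like(seed: int = 1, scale: float = 1.0, **overrides) -> SimConfig:
    """NS-style cohort: 15 females / 14 males, Y-specific inversion of
    modest internal divergence nesting the SDR."""
    kw = dict(
        chrom_lengths={"chr1": _sc(5_000_000, scale),
                       "chr2": _sc(15_000_000, scale)},
        sdr_interval=("chr2", _sc(5_440_000, scale), _sc(5_960_000, scale)),
        inversions=[InversionSpec(
            chrom="chr2", start=_sc(3_420_000, scale),
            end=_sc(9_020_000, scale), linkage="Y",
            genotype_freqs=NS_Y_INVERSION_FREQS, divergence_boost=2.5,
            name="invY")],
        theta=8e-4, het_boost=4.0, sdr_divergence=6e-3,
        n_females=15, n_males=14, seed=seed,
        depth_mean=20.0,
        barcode_molecules_per_sample=max(int(6_000 * scale), 1_500),
        molecule_length_mean=35_000, error_rate=0.01,
        fixed_composition=True, n_lof_x=0, n_lof_y=3,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def autosomal_like(seed: int = 1, scale: float = 1.0,
                   **overrides) -> SimConfig:
    """Negative control: no SDR, no inversions."""
    kw = dict(
        chrom_lengths={"chr1": _sc(3_000_000, scale),
                       "chr2": _sc(3_000_000, scale),
                       "chr3": _sc(3_000_000, scale)},
        sdr_interval=None, inversions=[],
        theta=1e-3, n_females=12, n_males=12, seed=seed,
        depth_mean=20.0,
        barcode_molecules_per_sample=max(int(2_000 * scale), 500),
        molecule_length_mean=30_000, error_rate=0.0,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def small_xy(seed: int = 0, system: str = "XY", with_sdr: bool = True,
             **overrides) -> SimConfig:
    """Fast 3-chromosome cohort for heterogamety-verdict tests."""
    kw = dict(
        chrom_lengths={"chr1": 1_200_000, "chr2": 1_200_000,
                       "chr3": 1_200_000},
        sdr_interval=("chr3", 400_000, 700_000) if with_sdr else None,
        inversions=[], theta=1.5e-3, sdr_divergence=1.2e-2,
        n_females=8, n_males=8, seed=seed, system=system,
        barcode_molecules_per_sample=200, molecule_length_mean=20_000,
        error_rate=0.0,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def small_inversion(seed: int = 0, linkage: str = "X",
                    **overrides) -> SimConfig:
    """Single 6 Mb chromosome with one 2.4 Mb inversion, for breakpoint
    localisation tests."""
    freqs = ({"F": (0.0, 0.3, 0.7), "M": (0.2, 0.8, 0.0)}
             if linkage == "X" else {"M": (0.2, 0.8, 0.0)})
    kw = dict(
        chrom_lengths={"chr1": 6_000_000},
        sdr_interval=None,
        inversions=[InversionSpec(
            chrom="chr1", start=1_800_000, end=4_200_000, linkage=linkage,
            genotype_freqs=freqs, name="inv1")],
        theta=1e-3, het_boost=4.0,
        n_females=10, n_males=10, seed=seed,
        barcode_molecules_per_sample=3_000, molecule_length_mean=30_000,
        error_rate=0.0,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def sdr_small(seed: int = 0, **overrides) -> SimConfig:
    """Compact two-chromosome XY cohort for SDR boundary-recovery tests
    (small enough that sequences and k-mers are cheap)."""
    kw = dict(
        chrom_lengths={"chr1": 1_000_000, "chr2": 1_600_000},
        sdr_interval=("chr2", 600_000, 900_000),
        inversions=[], theta=1.5e-3, sdr_divergence=1e-2,
        n_females=8, n_males=8, seed=seed,
        barcode_molecules_per_sample=200, molecule_length_mean=20_000,
        error_rate=0.0,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def default_genes(cfg: SimConfig, n_per_chrom: int = 10) -> list:
    """Evenly spaced 10 kb gene models on every chromosome."""
    genes = []
    for chrom, length in cfg.chrom_lengths.items():
        span = length // (n_per_chrom + 1)
        for i in range(n_per_chrom):
            start = (i + 1) * span
            genes.append(GeneModel(chrom, start, min(start + 10_000, length),
                                   f"{chrom}_g{i:02d}"))
    return genes


PRESETS = {
    "ct": ct_like,
    "ns": ns_like,
    "autosomal": autosomal_like,
}
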