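"""Simulate a diploid wild cohort with an SDR and polymorphic inversions.

Variation model
---------------
* Background biallelic SNPs are placed by a Poisson process whose rate is
  chosen so the expected per-bp heterozygosity equals ``theta``; allele
  frequencies are uniform on [0.1, 0.9] and haplotypes draw alleles
  independently (Hardy-Weinberg by construction).
* Inside each inversion, additional sites fixed between orientations are
  placed at per-bp rate ``theta * (het_boost - 1)``, so opposite
  orientations differ at density ``theta * het_boost`` while same
  orientations differ at the background density.
* Inside the SDR, fixed X-Y differences are placed at per-bp rate
  ``sdr_divergence``; the sex-limited haplotype (Y, or W under a ZW
  system) carries the alternate allele, so every heterogametic sample is
  heterozygous there.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..core import GenotypeMatrix, make_sample_table
from .config import (
    ConfigError,
    GENOTYPES,
    SimConfig,
    TruthSidecar,
    fixed_genotype_counts,
)

# E[2p(1-p)] for p ~ Uniform(0.1, 0.9); converts theta into a site rate.
_BG_HET_PER_SITE = 59.0 / 150.0

KIND_BG = 0
KIND_INV = 1
KIND_SDR = 2
KIND_LOF_X = 3
KIND_LOF_Y = 4

_BASES = np.array(list("ACGT"), dtype=object)


@dataclass
class SiteSet:
    """Per-chromosome variant sites with their generative roles."""

    pos: np.ndarray
    kind: np.ndarray
    inv_index: np.ndarray  # index into cfg.inversions, -1 elsewhere
    freq: np.ndarray       # background allele frequency, nan elsewhere
    ref: np.ndarray
    alt: np.ndarray

    def __len__(self):
        return len(self.pos)


def _poisson_positions(rng, rate: float, start: int, end: int) -> np.ndarray:
    if rate <= 0 or end <= start:
        return np.empty(0, dtype=np.int64)
    n = rng.poisson(rate * (end - start))
    return rng.integers(start, end, size=n, dtype=np.int64)


def build_sites(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Draw the variant-site catalogue for every chromosome."""
    sites = {}
    for chrom, length in cfg.chrom_lengths.items():
        pos_parts, kind_parts, inv_parts, freq_parts = [], [], [], []

        bg_rate = cfg.theta / _BG_HET_PER_SITE
        bg = _poisson_positions(rng, bg_rate, 0, length)
        pos_parts.append(bg)
        kind_parts.append(np.full(len(bg), KIND_BG, dtype=np.int8))
        inv_parts.append(np.full(len(bg), -1, dtype=np.int64))
        freq_parts.append(rng.uniform(0.1, 0.9, size=len(bg)))

        for k, inv in enumerate(cfg.inversions):
            if inv.chrom != chrom:
                continue
            boost = (inv.divergence_boost if inv.divergence_boost is not None
                     else cfg.het_boost)
            fix_rate = cfg.theta * max(boost - 1.0, 0.0)
            p = _poisson_positions(rng, fix_rate, inv.start, inv.end)
            pos_parts.append(p)
            kind_parts.append(np.full(len(p), KIND_INV, dtype=np.int8))
            inv_parts.append(np.full(len(p), k, dtype=np.int64))
            freq_parts.append(np.full(len(p), np.nan))

        if cfg.sdr_interval is not None and cfg.sdr_interval[0] == chrom:
            _, s, e = cfg.sdr_interval
            p = _poisson_positions(rng, cfg.sdr_divergence, s, e)
            pos_parts.append(p)
            kind_parts.append(np.full(len(p), KIND_SDR, dtype=np.int8))
            inv_parts.append(np.full(len(p), -1, dtype=np.int64))
            freq_parts.append(np.full(len(p), np.nan))

            for n_lof, kind in ((cfg.n_lof_x, KIND_LOF_X),
                                (cfg.n_lof_y, KIND_LOF_Y)):
                if n_lof:
                    p = rng.integers(s, e, size=n_lof, dtype=np.int64)
                    pos_parts.append(p)
                    kind_parts.append(np.full(n_lof, kind, dtype=np.int8))
                    inv_parts.append(np.full(n_lof, -1, dtype=np.int64))
                    freq_parts.append(np.full(n_lof, np.nan))
        elif cfg.n_lof_x or cfg.n_lof_y:
            if cfg.sdr_interval is None:
                raise ConfigError("LoF sites require an SDR interval")

        pos = np.concatenate(pos_parts)
        kind = np.concatenate(kind_parts)
        inv_index = np.concatenate(inv_parts)
        freq = np.concatenate(freq_parts)
        pos, first = np.unique(pos, return_index=True)
        kind, inv_index, freq = kind[first], inv_index[first], freq[first]

        ref = rng.choice(_BASES, size=len(pos))
        shift = rng.integers(1, 4, size=len(pos))
        base_idx = np.searchsorted(_BASES, ref.astype(str))
        alt = _BASES[(base_idx + shift) % 4]
        sites[chrom] = SiteSet(pos, kind, inv_index, freq, ref, alt)
    return sites


def _assign_inversion_genotypes(cfg: SimConfig, rng) -> tuple[dict, dict]:
    """Choose a genotype per sample per inversion and map it onto the
    two haplotypes (hap 1 of a heterogametic sample is the Y/W)."""
    samples, sexes = cfg.samples, cfg.sexes
    n = len(samples)
    genotypes: dict[str, dict] = {}
    orientations: dict[str, np.ndarray] = {}
    for inv in cfg.inversions:
        gts = {}
        orient = np.zeros(2 * n, dtype=bool)
        by_sex = {"F": [i for i, s in enumerate(sexes) if s == "F"],
                  "M": [i for i, s in enumerate(sexes) if s == "M"]}
        for sex, idx in by_sex.items():
            if not idx:
                continue
            labels = _draw_genotype_labels(cfg, inv, sex, len(idx), rng)
            for i, label in zip(idx, labels):
                sample = samples[i]
                is_het_sex = sexes[i] == cfg.het_sex
                _check_carrier(inv, sex, label, is_het_sex)
                gts[sample] = label
                if label == "II":
                    orient[2 * i] = orient[2 * i + 1] = True
                elif label == "RI":
                    if is_het_sex:
                        # hap 1 is the Y/W: Y-linked -> inverted Y;
                        # otherwise the inversion rides the single X.
                        orient[2 * i + 1] = inv.linkage == "Y"
                        orient[2 * i] = inv.linkage != "Y"
                    else:
                        orient[2 * i + int(rng.integers(2))] = True
        genotypes[inv.name] = gts
        orientations[inv.name] = orient
    return genotypes, orientations


def _draw_genotype_labels(cfg, inv, sex, n, rng) -> list[str]:
    if inv.genotype_freqs is not None and sex in inv.genotype_freqs:
        freqs = inv.genotype_freqs[sex]
        if cfg.fixed_composition:
            counts = fixed_genotype_counts(freqs, n)
            labels = [g for g in GENOTYPES for _ in range(counts[g])]
            rng.shuffle(labels)
            return labels
        draw = rng.multinomial(1, freqs, size=n).argmax(axis=1)
        return [GENOTYPES[d] for d in draw]
    if inv.genotype_freqs is not None:
        # no row for this sex: non-carriers (e.g. females for a Y
        # inversion whose table lists only males)
        return ["RR"] * n
    f = float(inv.allele_freq)
    if inv.linkage == "Y":
        if sex != cfg.het_sex:
            return ["RR"] * n
        return ["RI" if c else "RR" for c in rng.random(n) < f]
    if inv.linkage == "X" and sex == cfg.het_sex:
        return ["RI" if c else "RR" for c in rng.random(n) < f]
    dose = (rng.random(n) < f).astype(int) + (rng.random(n) < f)
    return [GENOTYPES[d] for d in dose]


def _check_carrier(inv, sex, label, is_het_sex):
    if inv.linkage == "Y":
        if not is_het_sex and label != "RR":
            raise ConfigError(
                f"{inv.name}: Y-linked inversion carried by a {sex} sample")
        if label == "II":
            raise ConfigError(
                f"{inv.name}: Y-linked inversion cannot be homozygous")
    if inv.linkage == "X" and is_het_sex and label == "II":
        raise ConfigError(
            f"{inv.name}: X-linked inversion cannot be homozygous in the "
            "heterogametic sex")


def _inject_errors(gt: np.ndarray, error_rate: float, rng) -> np.ndarray:
    """Symmetric single-allele flip with probability ``error_rate``."""
    if error_rate <= 0:
        return gt
    flip = rng.random(gt.shape) < error_rate
    up = rng.random(gt.shape) < 0.5
    out = gt.copy()
    out[flip & (gt == 0)] = 1
    out[flip & (gt == 2)] = 1
    het = flip & (gt == 1)
    out[het & up] = 2
    out[het & ~up] = 0
    return out


def simulate_population(cfg: SimConfig
                        ) -> tuple[GenotypeMatrix, pd.DataFrame, TruthSidecar]:
    """Generate the cohort genotype matrix, sample table and truth.

    Returns
    -------
    gm : GenotypeMatrix
    sample_table : DataFrame with columns sample, sex, population
    truth : TruthSidecar
        Carries per-sample sex and inversion genotypes, the true SDR,
        LoF variant origins, and the in-memory haplotypes/sites reused
        by the barcode, depth and sequence emitters.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    samples, sexes = cfg.samples, cfg.sexes
    n = len(samples)
    hap_is_y = np.zeros(2 * n, dtype=bool)
    for i, sex in enumerate(sexes):
        if sex == cfg.het_sex:
            hap_is_y[2 * i + 1] = True

    sites = build_sites(cfg, rng)
    genotypes, orientations = _assign_inversion_genotypes(cfg, rng)

    haplotypes = {}
    gm_parts = []
    for chrom in cfg.chrom_lengths:
        ss = sites[chrom]
        haps = np.zeros((2 * n, len(ss)), dtype=bool)
        bg = ss.kind == KIND_BG
        haps[:, bg] = rng.random((2 * n, int(bg.sum()))) < ss.freq[bg]
        for k, inv in enumerate(cfg.inversions):
            cols = ss.inv_index == k
            if cols.any():
                haps[:, cols] = orientations[inv.name][:, None]
        haps[:, ss.kind == KIND_SDR] = hap_is_y[:, None]
        haps[:, ss.kind == KIND_LOF_X] = ~hap_is_y[:, None]
        haps[:, ss.kind == KIND_LOF_Y] = hap_is_y[:, None]
        haplotypes[chrom] = haps

        dose = (haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8)).T
        gm_parts.append(GenotypeMatrix(
            np.full(len(ss), chrom, dtype=object), ss.pos, ss.ref, ss.alt,
            dose, samples))

    gm = gm_parts[0]
    for part in gm_parts[1:]:
        gm = gm.concat(part)
    gm.gt = _inject_errors(gm.gt, cfg.error_rate, rng)

    lof_rows = []
    for chrom in cfg.chrom_lengths:
        ss = sites[chrom]
        for kind, origin in ((KIND_LOF_X, "X"), (KIND_LOF_Y, "Y")):
            for p in ss.pos[ss.kind == kind]:
                lof_rows.append({"chrom": chrom, "pos": int(p),
                                 "origin": origin})
    lof = pd.DataFrame(lof_rows, columns=["chrom", "pos", "origin"])

    truth = TruthSidecar(
        sex=dict(zip(samples, sexes)),
        inversion_genotypes=genotypes,
        sdr=cfg.sdr_interval,
        lof_variants=lof,
        haplotypes=haplotypes,
        sites=sites,
        hap_orientations=orientations,
        hap_is_y=hap_is_y,
    )
    table = make_sample_table(samples, sexes)
    return gm, table, truth
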