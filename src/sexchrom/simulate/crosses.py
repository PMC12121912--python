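"""Single-pair crosses: Mendelian transmission with obligate X->daughter,
Y->son inheritance from the father, genotyped offspring or pooled read
counts (Pool-seq)."""
from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import GenotypeMatrix, PoolCounts
from .config import ConfigError, CrossConfig, SimConfig, TruthSidecar
from .population import (
    KIND_BG, KIND_INV, KIND_LOF_X, KIND_LOF_Y, KIND_SDR, build_sites,
)


def _parent_haplotypes(cross: CrossConfig, cfg: SimConfig, sites, rng):
    """Allele vectors for the four parental haplotypes per chromosome.

    Order: mother hap 0, mother hap 1, father hap 0, father hap 1.
    """
    inv_by_name = {inv.name: inv for inv in cfg.inversions}
    hap_specs = list(cross.mother_haplotypes) + list(cross.father_haplotypes)
    for name, inv in inv_by_name.items():
        if inv.linkage == "Y":
            for h, spec in enumerate(cross.mother_haplotypes):
                if spec.get(name):
                    raise ConfigError(
                        f"mother cannot carry Y-linked inversion {name}")
            x_idx = cross.father_x_index()
            if cross.father_haplotypes[x_idx].get(name):
                raise ConfigError(
                    f"father's X cannot carry Y-linked inversion {name}")
    is_y = np.array([False, False, False, False])
    is_y[2 + cross.father_y_index] = True

    haps = {}
    for chrom, ss in sites.items():
        H = np.zeros((4, len(ss)), dtype=bool)
        bg = ss.kind == KIND_BG
        H[:, bg] = rng.random((4, int(bg.sum()))) < ss.freq[bg]
        for k, inv in enumerate(cfg.inversions):
            cols = ss.inv_index == k
            if not cols.any():
                continue
            carried = np.array([bool(spec.get(inv.name))
                                for spec in hap_specs])
            H[:, cols] = carried[:, None]
        H[:, ss.kind == KIND_SDR] = is_y[:, None]
        H[:, ss.kind == KIND_LOF_Y] = is_y[:, None]
        H[:, ss.kind == KIND_LOF_X] = ~is_y[:, None]
        haps[chrom] = H
    return haps


def _offspring_truth(cross: CrossConfig, cfg: SimConfig, mat_choice_sons,
                     mat_choice_daughters) -> TruthSidecar:
    samples = ([f"son{i:02d}" for i in range(cross.n_sons)]
               + [f"dau{i:02d}" for i in range(cross.n_daughters)])
    sexes = ["M"] * cross.n_sons + ["F"] * cross.n_daughters
    truth = TruthSidecar(sex=dict(zip(samples, sexes)))
    pat_son = cross.father_haplotypes[cross.father_y_index]
    pat_dau = cross.father_haplotypes[cross.father_x_index()]
    for inv in cfg.inversions:
        gts = {}
        for i, m in enumerate(mat_choice_sons):
            mat = cross.mother_haplotypes[m].get(inv.name, False)
            dose = int(mat) + int(pat_son.get(inv.name, False))
            gts[f"son{i:02d}"] = ("RR", "RI", "II")[dose]
        for i, m in enumerate(mat_choice_daughters):
            mat = cross.mother_haplotypes[m].get(inv.name, False)
            dose = int(mat) + int(pat_dau.get(inv.name, False))
            gts[f"dau{i:02d}"] = ("RR", "RI", "II")[dose]
        truth.inversion_genotypes[inv.name] = gts
    truth.sdr = cfg.sdr_interval
    truth.extras["mat_choice_sons"] = np.asarray(mat_choice_sons)
    truth.extras["mat_choice_daughters"] = np.asarray(mat_choice_daughters)
    return truth


def simulate_cross_pools(cross: CrossConfig, cfg: SimConfig
                         ) -> tuple[PoolCounts, PoolCounts, TruthSidecar]:
    """Pool-seq read counts for the son and daughter pools of a cross.

    Offspring haplotypes are drawn by Mendelian transmission (one
    unrecombined maternal haplotype each; the paternal Y goes to every
    son, the paternal X to every daughter).  Read counts per site are
    Binomial(pool_depth, pool allele frequency).
    """
    if cross.n_sons + cross.n_daughters <= 0:
        raise ConfigError("cross must produce at least one offspring")
    rng = np.random.default_rng([cfg.seed, 202])
    sites = build_sites(cfg, rng)
    haps = _parent_haplotypes(cross, cfg, sites, rng)

    mat_sons = rng.integers(0, 2, size=cross.n_sons)
    mat_daus = rng.integers(0, 2, size=cross.n_daughters)
    truth = _offspring_truth(cross, cfg, mat_sons, mat_daus)
    truth.sites = sites
    truth.haplotypes = haps

    pools = {}
    for label, mat_choice, pat_idx in (
            ("sons", mat_sons, 2 + cross.father_y_index),
            ("daughters", mat_daus, 2 + cross.father_x_index())):
        chroms, poss, refs, alts = [], [], [], []
        ref_reads, alt_reads = [], []
        for chrom, ss in sites.items():
            H = haps[chrom]
            if len(mat_choice):
                mat_freq = H[mat_choice].mean(axis=0)
            else:
                mat_freq = np.zeros(len(ss))
            freq = (mat_freq + H[pat_idx]) / 2.0
            alt_n = rng.binomial(cross.pool_depth, freq)
            chroms.append(np.full(len(ss), chrom, dtype=object))
            poss.append(ss.pos)
            refs.append(ss.ref)
            alts.append(ss.alt)
            alt_reads.append(alt_n)
            ref_reads.append(cross.pool_depth - alt_n)
        pools[label] = PoolCounts(
            chrom=np.concatenate(chroms), pos=np.concatenate(poss),
            ref=np.concatenate(refs), alt=np.concatenate(alts),
            ref_reads=np.concatenate(ref_reads),
            alt_reads=np.concatenate(alt_reads), label=label)
    return pools["sons"], pools["daughters"], truth


def simulate_cross_individuals(cross: CrossConfig, cfg: SimConfig
                               ) -> tuple[GenotypeMatrix, pd.DataFrame,
                                          TruthSidecar]:
    """Individually genotyped parents and offspring of a cross.

    Returns a genotype matrix whose first two samples are the mother and
    father, a pedigree table (sample, role, sex) and the truth sidecar.
    """
    if cross.n_sons + cross.n_daughters <= 0:
        raise ConfigError("cross must produce at least one offspring")
    rng = np.random.default_rng([cfg.seed, 203])
    sites = build_sites(cfg, rng)
    haps = _parent_haplotypes(cross, cfg, sites, rng)
    mat_sons = rng.integers(0, 2, size=cross.n_sons)
    mat_daus = rng.integers(0, 2, size=cross.n_daughters)
    truth = _offspring_truth(cross, cfg, mat_sons, mat_daus)
    truth.sites = sites
    truth.haplotypes = haps

    samples = (["mother", "father"]
               + [f"son{i:02d}" for i in range(cross.n_sons)]
               + [f"dau{i:02d}" for i in range(cross.n_daughters)])
    roles = (["mother", "father"]
             + ["offspring"] * (cross.n_sons + cross.n_daughters))
    sexes = ["F", "M"] + ["M"] * cross.n_sons + ["F"] * cross.n_daughters

    parts = []
    for chrom, ss in sites.items():
        H = haps[chrom].astype(np.int8)
        cols = [H[0] + H[1], H[2] + H[3]]
        for m in mat_sons:
            cols.append(H[m] + H[2 + cross.father_y_index])
        for m in mat_daus:
            cols.append(H[m] + H[2 + cross.father_x_index()])
        gt = np.stack(cols, axis=1).astype(np.int8)
        parts.append(GenotypeMatrix(
            np.full(len(ss), chrom, dtype=object), ss.pos, ss.ref, ss.alt,
            gt, samples))
    gm = parts[0]
    for part in parts[1:]:
        gm = gm.concat(part)
    gm.gt = _inject(gm.gt, cfg.error_rate, rng)
    pedigree = pd.DataFrame({"sample": samples, "role": roles, "sex": sexes})
    return gm, pedigree, truth


def _inject(gt, error_rate, rng):
    from .population import _inject_errors
    return _inject_errors(gt, error_rate, rng)
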