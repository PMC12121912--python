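"""Fst estimators between two groups (here: males vs females).

Three estimators are exposed:

* ``hudson`` -- the plug-in form ``1 - Hw/Hb`` with
  ``Hw = p1(1-p1) + p2(1-p2)`` and ``Hb = p1(1-p2) + p2(1-p1)``, plus a
  sample-size corrected variant that replaces each within-group term by
  its unbiased estimate ``p(1-p) * n/(n-1)``.  At a fully sex-linked SNP
  (one group fixed, the other uniformly heterozygous) the plug-in form
  is exactly 0.5 for any sample sizes.
* ``wc`` -- Weir & Cockerham variance components a (among groups),
  b (among individuals within groups), c (within individuals), with
  theta = a / (a + b + c) per site and ratio-of-sums aggregation over
  windows.  This estimator also equals 0.5 exactly in the fully
  sex-linked configuration at equal group sizes.
* ``nei`` (pool form) -- ``(Ht - Hs)/Ht``, which plateaus at 1/3 in the
  same configuration; used for pooled read counts.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import GenotypeMatrix, PoolCounts, Windows, assign_sites_to_windows


# ---------------------------------------------------------------------
# site estimators
# ---------------------------------------------------------------------
def site_fst_hudson(p1: float, n1: int, p2: float, n2: int,
                    corrected: bool = False) -> float:
    """Hudson-type site Fst from allele frequencies and allele counts.

    Returns NaN when both groups are identically monomorphic
    (``Hb == 0``; the site carries no information).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 alleles per group")
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    if hb == 0:
        return float("nan")
    t1 = p1 * (1 - p1)
    t2 = p2 * (1 - p2)
    if corrected:
        t1 *= n1 / (n1 - 1)
        t2 *= n2 / (n2 - 1)
    return 1.0 - (t1 + t2) / hb


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham variance components for two groups (vectorised).

    Parameters are per-site arrays: diploid sample counts ``n``, alt
    allele frequencies ``p`` and observed heterozygote fractions ``h``.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
            / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def site_fst_wc(genotypes1, genotypes2):
    """Weir-Cockerham site Fst from two groups of diploid dosages.

    Missing calls (``< 0``) are dropped per group.  Returns the tuple
    ``(a, b, c, fst)``; a monomorphic site yields all-zero components
    and NaN fst (excluded from window sums).
    """
    g1 = np.asarray(genotypes1)
    g2 = np.asarray(genotypes2)
    g1 = g1[g1 >= 0]
    g2 = g2[g2 >= 0]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least 2 diploid samples per group")
    p1, p2 = g1.mean() / 2, g2.mean() / 2
    if (p1 == p2) and p1 in (0.0, 1.0):
        return 0.0, 0.0, 0.0, float("nan")
    h1 = float(np.mean(g1 == 1))
    h2 = float(np.mean(g2 == 1))
    a, b, c = _wc_components(len(g1), p1, h1, len(g2), p2, h2)
    a, b, c = float(a), float(b), float(c)
    denom = a + b + c
    return a, b, c, (a / denom if denom != 0 else float("nan"))


# ---------------------------------------------------------------------
# windowed estimators
# ---------------------------------------------------------------------
def _group_site_stats(gm: GenotypeMatrix, names):
    sub = gm.gt[:, gm.sample_indices(names)]
    called = sub >= 0
    n = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, sub, 0).sum(axis=1) / (2 * n)
        h = (sub == 1).sum(axis=1) / n
    return n, p, h


def windowed_fst(gm: GenotypeMatrix, group1, group2, windows: Windows,
                 estimator: str = "wc") -> pd.DataFrame:
    """Per-window male-female Fst track (ratio-of-sums aggregation).

    ``estimator`` is ``"wc"`` (Weir-Cockerham; window value
    ``sum(a)/sum(a+b+c)``) or ``"hudson"`` (window value
    ``1 - sum(Hw)/sum(Hb)``).  Windows without usable sites carry NaN,
    not zero.
    """
    if set(group1) & set(group2):
        raise ValueError("groups must be disjoint")
    if estimator not in ("wc", "hudson"):
        raise ValueError(f"unknown estimator {estimator!r}")

    n1, p1, h1 = _group_site_stats(gm, group1)
    n2, p2, h2 = _group_site_stats(gm, group2)
    usable = (n1 >= 2) & (n2 >= 2)
    poly = ~(np.isclose(p1, p2) & (np.isclose(p1, 0) | np.isclose(p1, 1)))
    usable &= poly

    if estimator == "wc":
        a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
        num = np.where(usable, a, 0.0)
        den = np.where(usable, a + b + c, 0.0)
    else:
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        hw = p1 * (1 - p1) + p2 * (1 - p2)
        informative = usable & (hb > 0)
        num = np.where(informative, hb - hw, 0.0)
        den = np.where(informative, hb, 0.0)
        usable = informative

    rows = []
    for chrom in windows.chrom_lengths:
        m = gm.chrom == chrom
        pos = gm.pos[m]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        cnum, cden = num[m][order], den[m][order]
        cuse = usable[m][order]
        starts = windows.starts(chrom)
        for idx, s in zip(
                assign_sites_to_windows(pos, starts, windows.size), starts):
            nsites = int(cuse[idx].sum())
            d = cden[idx].sum()
            fst = cnum[idx].sum() / d if (nsites and d != 0) else np.nan
            rows.append((chrom, int(s),
                         int(min(s + windows.size,
                                 windows.chrom_lengths[chrom])),
                         fst, nsites))
    return pd.DataFrame(rows,
                        columns=["chrom", "start", "end", "fst",
                                 "n_sites_used"])


def pool_fst(pool_a: PoolCounts, pool_b: PoolCounts, windows: Windows,
             min_reads: int = 4, min_count: int = 2) -> pd.DataFrame:
    """Windowed Nei-form Fst ``(Ht - Hs)/Ht`` between two read pools.

    Sites must be covered by ``min_reads`` reads in both pools and carry
    a minor-allele read count of at least ``min_count`` summed across
    pools; others are excluded.
    """
    if len(pool_a.pos) != len(pool_b.pos) or \
            (pool_a.pos != pool_b.pos).any():
        raise ValueError("pools must cover identical site lists")
    da, db = pool_a.depth, pool_b.depth
    ok = (da >= min_reads) & (db >= min_reads)
    alt = pool_a.alt_reads + pool_b.alt_reads
    ref = pool_a.ref_reads + pool_b.ref_reads
    ok &= np.minimum(alt, ref) >= min_count
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(da > 0, pool_a.alt_reads / np.maximum(da, 1), np.nan)
        pb = np.where(db > 0, pool_b.alt_reads / np.maximum(db, 1), np.nan)
    hs = (2 * pa * (1 - pa) + 2 * pb * (1 - pb)) / 2
    pbar = (pa + pb) / 2
    ht = 2 * pbar * (1 - pbar)
    ok &= ht > 0

    num = np.where(ok, ht - hs, 0.0)
    den = np.where(ok, ht, 0.0)
    rows = []
    for chrom in windows.chrom_lengths:
        m = pool_a.chrom == chrom
        pos = pool_a.pos[m]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        cnum, cden, cok = num[m][order], den[m][order], ok[m][order]
        starts = windows.starts(chrom)
        for idx, s in zip(
                assign_sites_to_windows(pos, starts, windows.size), starts):
            nsites = int(cok[idx].sum())
            d = cden[idx].sum()
            fst = cnum[idx].sum() / d if (nsites and d > 0) else np.nan
            rows.append((chrom, int(s),
                         int(min(s + windows.size,
                                 windows.chrom_lengths[chrom])),
                         fst, nsites))
    return pd.DataFrame(rows,
                        columns=["chrom", "start", "end", "fst",
                                 "n_sites_used"])


def site_fst_nei(p1: float, p2: float) -> float:
    """Classic (Ht - Hs)/Ht at a single site (pool form)."""
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
    pbar = (p1 + p2) / 2
    ht = 2 * pbar * (1 - pbar)
    if ht == 0:
        return float("nan")
    return (ht - hs) / ht
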