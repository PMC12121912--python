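"""Genotype candidate inversions per sample and classify their linkage.

Heterozygous carriers of an inversion accumulate fixed differences
between the two orientations, so their heterozygous-site density inside
the candidate is elevated relative to flanking sequence; homozygotes are
polarized reference vs inverted by molecule junction support.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ..core import GenotypeMatrix

GENOTYPES = ("RR", "RI", "II")


def _het_density(gm: GenotypeMatrix, chrom, start, end):
    m = gm.region_mask(chrom, start, end)
    span = max(end - start, 1)
    return (gm.gt[m] == 1).sum(axis=0) / span


def _two_means_split(values: np.ndarray, min_separation: float = 1.6,
                     n_iter: int = 100):
    """1-D two-cluster split; returns (is_upper, threshold) or
    (all-False, inf) when the clusters are not separated."""
    v = np.asarray(values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        return np.zeros(len(v), dtype=bool), np.inf
    c1, c2 = lo, hi
    for _ in range(n_iter):
        upper = np.abs(v - c2) < np.abs(v - c1)
        if upper.all() or not upper.any():
            break
        new1 = v[~upper].mean()
        new2 = v[upper].mean()
        if new1 == c1 and new2 == c2:
            break
        c1, c2 = new1, new2
    if c1 <= 0 or c2 / max(c1, 1e-12) < min_separation:
        return np.zeros(len(v), dtype=bool), np.inf
    threshold = (c1 + c2) / 2
    return v > threshold, threshold


def genotype_inversion(candidate, gm: GenotypeMatrix, molecules,
                       flank_bp: int | None = None,
                       min_molecules: int = 2,
                       min_separation: float = 1.6,
                       junction_tol: int | None = None) -> dict:
    """Call RR / RI / II / NA per sample for one candidate inversion.

    Samples are split heterozygous vs homozygous by a two-cluster split
    of their inside:flank heterozygous-site density ratio; homozygotes
    are polarized by majority molecule junction support (reference vs
    inverted junction).  NA is returned when junction support is below
    ``min_molecules`` and the density gives no polarity.
    """
    chrom, start, end = candidate.interval if hasattr(candidate, "interval") \
        else candidate
    length = end - start
    if flank_bp is None:
        flank_bp = max(length // 2, 200_000)
    if junction_tol is None:
        junction_tol = 20_000

    inside = _het_density(gm, chrom, start, end)
    left = _het_density(gm, chrom, max(start - flank_bp, 0), start)
    right = _het_density(gm, chrom, end, end + flank_bp)
    flank = (left + right) / 2
    eps = 1e-7
    ratio = (inside + eps) / (flank + eps)

    is_het, _ = _two_means_split(ratio, min_separation=min_separation)

    support = molecules.junction_support(chrom, start, end,
                                         tol=junction_tol,
                                         margin=junction_tol // 4)
    sup = {r["sample"]: (int(r["ref_junction"]), int(r["inv_junction"]))
           for _, r in support.iterrows()}

    calls = {}
    for k, sample in enumerate(gm.samples):
        if is_het[k]:
            calls[sample] = "RI"
            continue
        ref_n, inv_n = sup.get(sample, (0, 0))
        if ref_n + inv_n < min_molecules or ref_n == inv_n:
            calls[sample] = "NA"
        elif inv_n > ref_n:
            calls[sample] = "II"
        else:
            calls[sample] = "RR"
    if all(v == "NA" for v in calls.values()):
        raise RuntimeError("genotyping failure: all samples NA")
    return calls


# ---------------------------------------------------------------------
def genotype_frequency_table(calls: dict, sexes: dict) -> pd.DataFrame:
    """Genotype frequency table by sex (columns Ref/Ref, Ref/Inv,
    Inv/Inv) over called (non-NA) samples, plus counts."""
    rows = {}
    for sex in ("F", "M"):
        counts = {g: 0 for g in GENOTYPES}
        for sample, call in calls.items():
            if sexes[sample] == sex and call in counts:
                counts[call] += 1
        n = sum(counts.values())
        rows[sex] = {
            "n": n,
            "Ref/Ref": counts["RR"] / n if n else np.nan,
            "Ref/Inv": counts["RI"] / n if n else np.nan,
            "Inv/Inv": counts["II"] / n if n else np.nan,
        }
    return pd.DataFrame(rows).T[["n", "Ref/Ref", "Ref/Inv", "Inv/Inv"]]


def classify_inversion_linkage(calls: dict, sexes: dict,
                               y_min: float = 0.5, f_max: float = 0.1,
                               x_male_ri_min: float = 0.2,
                               min_per_sex: int = 5
                               ) -> tuple[str, pd.DataFrame]:
    """Classify an inversion as Y-linked / X-linked / autosomal / unknown.

    Y-linked: heterozygous carriers essentially confined to males (male
    RI frequency >= ``y_min``, female RI frequency <= ``f_max``) with no
    homozygous-inverted call anywhere.  X-linked: homozygous-inverted
    females exist, no male is homozygous inverted, and male heterozygotes
    are common.  Autosomal: carrier frequencies independent of sex
    (Fisher exact p > 0.05).  Anything else, or fewer than
    ``min_per_sex`` called samples per sex, is unknown.
    """
    table = genotype_frequency_table(calls, sexes)
    called = {s: c for s, c in calls.items() if c != "NA"}
    nf = int(table.loc["F", "n"])
    nm = int(table.loc["M", "n"])
    if nf < min_per_sex or nm < min_per_sex:
        return "unknown", table

    male_ri = table.loc["M", "Ref/Inv"]
    female_ri = table.loc["F", "Ref/Inv"]
    male_ii = table.loc["M", "Inv/Inv"]
    female_ii = table.loc["F", "Inv/Inv"]

    if male_ri >= y_min and female_ri <= f_max and \
            male_ii == 0 and female_ii == 0:
        return "Y-linked", table
    if female_ii > 0 and male_ii == 0 and male_ri >= x_male_ri_min:
        return "X-linked", table

    carriers = {"F": [0, 0], "M": [0, 0]}
    for sample, call in called.items():
        carriers[sexes[sample]][0 if call == "RR" else 1] += 1
    contingency = np.array([carriers["F"], carriers["M"]])
    if contingency.sum(axis=0).min() >= 0:
        _, p = stats.fisher_exact(contingency)
        if p > 0.05:
            return "autosomal", table
    return "unknown", table
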