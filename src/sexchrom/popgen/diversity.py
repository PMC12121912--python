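"""Nucleotide diversity, SNP density and normalized depth ratios."""
from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import GenotypeMatrix, Windows, assign_sites_to_windows


def site_pi(n_alleles: np.ndarray, alt_count: np.ndarray) -> np.ndarray:
    """Per-site fraction of mismatching unordered allele pairs.

    Equals ``2*p*(1-p) * n/(n-1)`` with ``p = alt/n``; sites with fewer
    than two called alleles yield 0 and are excluded upstream.
    """
    n = np.asarray(n_alleles, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
        pi = 2 * p * (1 - p) * n / np.maximum(n - 1, 1)
    return np.where(n >= 2, pi, 0.0)


def windowed_pi(gm: GenotypeMatrix, group, windows: Windows) -> pd.DataFrame:
    """Per-window nucleotide diversity of one sample group.

    The window value is the sum of per-site pi divided by the window
    length (monomorphic positions contribute zero, so unsequenced
    invariant bases need not be represented).
    """
    if not list(group):
        raise ValueError("group is empty")
    n, alt = gm.allele_counts(group)
    pis = site_pi(n, alt)
    rows = []
    for chrom in windows.chrom_lengths:
        m = gm.chrom == chrom
        pos = gm.pos[m]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        cpi = pis[m][order]
        starts = windows.starts(chrom)
        for idx, s in zip(
                assign_sites_to_windows(pos, starts, windows.size), starts):
            end = int(min(s + windows.size, windows.chrom_lengths[chrom]))
            rows.append((chrom, int(s), end,
                         cpi[idx].sum() / (end - s), len(idx)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pi",
                                       "n_sites_used"])


def snp_density(gm: GenotypeMatrix, group, windows: Windows,
                maf_min: float = 0.05) -> pd.DataFrame:
    """Count of segregating sites with MAF >= ``maf_min`` within the
    sample subset, per window (overlapping windows count sites twice)."""
    if not list(group):
        raise ValueError("group is empty")
    n, alt = gm.allele_counts(group)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    keep = (n >= 2) & (maf >= maf_min) & (maf > 0)
    rows = []
    for chrom in windows.chrom_lengths:
        m = gm.chrom == chrom
        pos = gm.pos[m]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        ckeep = keep[m][order]
        starts = windows.starts(chrom)
        for idx, s in zip(
                assign_sites_to_windows(pos, starts, windows.size), starts):
            end = int(min(s + windows.size, windows.chrom_lengths[chrom]))
            rows.append((chrom, int(s), end, int(ckeep[idx].sum())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def depth_ratio(depth: pd.DataFrame, sample_table: pd.DataFrame,
                norm_chroms=None) -> pd.DataFrame:
    """Normalized male:female depth ratio per row of a depth table.

    ``depth`` holds one row per window or gene (columns chrom/start/end
    plus one column per sample).  Each sample's depths are first divided
    by its own median over ``norm_chroms`` (all chromosomes when None;
    pass the autosomes to calibrate against a sex-linked candidate).
    The ratio is mean normalized male depth over mean normalized female
    depth; rows with zero female depth yield NaN.
    """
    males = list(sample_table.loc[sample_table.sex == "M", "sample"])
    females = list(sample_table.loc[sample_table.sex == "F", "sample"])
    missing = [s for s in males + females if s not in depth.columns]
    if missing:
        raise KeyError(f"depth table lacks samples: {missing}")
    norm_rows = (depth["chrom"].isin(norm_chroms) if norm_chroms is not None
                 else pd.Series(True, index=depth.index))
    normed = {}
    for s in males + females:
        med = depth.loc[norm_rows, s].median()
        if not np.isfinite(med) or med == 0:
            raise ValueError(f"sample {s} has zero/undefined median depth")
        normed[s] = depth[s] / med
    male_mean = pd.concat([normed[s] for s in males], axis=1).mean(axis=1)
    female_mean = pd.concat([normed[s] for s in females], axis=1).mean(axis=1)
    ratio = male_mean / female_mean.replace(0.0, np.nan)
    out = depth[[c for c in ("gene", "chrom", "start", "end")
                 if c in depth.columns]].copy()
    out["mf_depth_ratio"] = ratio
    return out
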