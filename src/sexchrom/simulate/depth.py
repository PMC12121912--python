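"""Per-sample depth tracks over genes and windows, plus loss-of-function
variant annotations with chromosome-of-origin truth."""
from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import sliding_windows
from .config import ConfigError, SimConfig, TruthSidecar


def _sample_scales(samples, cfg, rng):
    if not cfg.depth_noise:
        return {s: 1.0 for s in samples}
    return {s: float(v) for s, v in
            zip(samples, rng.lognormal(0.0, 0.15, size=len(samples)))}


def simulate_depth_and_lof(gm, truth: TruthSidecar, genes, cfg: SimConfig,
                           deleted_on_y=()):
    """Simulate read depth per gene and per window, and LoF annotations.

    Depth is Poisson around ``depth_mean`` scaled per sample (exact
    expectations when ``cfg.depth_noise`` is False).  Genes named in
    ``deleted_on_y`` lose the Y-haplotype contribution in heterogametic
    samples, halving their expected depth there.  LoF annotations attach
    the per-sex allele frequencies observed in ``gm`` to the simulated
    LoF sites, keeping their true chromosome of origin.

    Returns
    -------
    gene_depth : DataFrame (gene, chrom, start, end, one column per sample)
    window_depth : DataFrame (chrom, start, end, one column per sample)
    lof : DataFrame (chrom, pos, origin, af_female, af_male)
    """
    deleted_on_y = set(deleted_on_y)
    unknown = deleted_on_y - {g.name for g in genes}
    if unknown:
        raise ConfigError(f"deleted_on_y names unknown genes: {sorted(unknown)}")
    for g in genes:
        if g.chrom not in cfg.chrom_lengths:
            raise ConfigError(f"gene {g.name} on unsimulated chromosome "
                              f"{g.chrom!r}")
        if g.end > cfg.chrom_lengths[g.chrom]:
            raise ConfigError(f"gene {g.name} extends beyond {g.chrom}")

    rng = np.random.default_rng([cfg.seed, 303])
    samples = list(truth.sex)
    scales = _sample_scales(samples, cfg, rng)

    def draw(expected):
        if cfg.depth_noise:
            return float(rng.poisson(max(expected, 0.0)))
        return float(expected)

    gene_rows = []
    for g in genes:
        row = {"gene": g.name, "chrom": g.chrom,
               "start": g.start, "end": g.end}
        halved = g.name in deleted_on_y
        for s in samples:
            factor = 0.5 if (halved and truth.sex[s] == cfg.het_sex) else 1.0
            row[s] = draw(cfg.depth_mean * scales[s] * factor)
        gene_rows.append(row)
    gene_depth = pd.DataFrame(gene_rows)

    windows = sliding_windows(cfg.chrom_lengths, cfg.window_size, cfg.step)
    wf = windows.frame()
    deleted = [g for g in genes if g.name in deleted_on_y]
    win_rows = []
    for _, w in wf.iterrows():
        row = {"chrom": w["chrom"], "start": int(w["start"]),
               "end": int(w["end"])}
        span = row["end"] - row["start"]
        overlap = sum(
            max(0, min(g.end, row["end"]) - max(g.start, row["start"]))
            for g in deleted if g.chrom == row["chrom"])
        frac = min(overlap / span, 1.0) if span else 0.0
        for s in samples:
            factor = 1.0 - 0.5 * frac if truth.sex[s] == cfg.het_sex else 1.0
            row[s] = draw(cfg.depth_mean * scales[s] * factor)
        win_rows.append(row)
    window_depth = pd.DataFrame(win_rows)

    lof = _annotate_lof(gm, truth)
    truth.y_deleted_genes = sorted(deleted_on_y)
    return gene_depth, window_depth, lof


def _annotate_lof(gm, truth: TruthSidecar) -> pd.DataFrame:
    females = [s for s, sex in truth.sex.items() if sex == "F"]
    males = [s for s, sex in truth.sex.items() if sex == "M"]
    rows = []
    base = truth.lof_variants
    if base is None or base.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "origin", "af_female", "af_male"])
    pos_index = {(c, p): i for i, (c, p)
                 in enumerate(zip(gm.chrom, gm.pos))}
    nf, af = gm.allele_counts(females)
    nm, am = gm.allele_counts(males)
    for _, r in base.iterrows():
        i = pos_index.get((r["chrom"], r["pos"]))
        if i is None:
            continue
        rows.append({
            "chrom": r["chrom"], "pos": int(r["pos"]),
            "origin": r["origin"],
            "af_female": af[i] / nf[i] if nf[i] else np.nan,
            "af_male": am[i] / nm[i] if nm[i] else np.nan,
        })
    return pd.DataFrame(rows,
                        columns=["chrom", "pos", "origin",
                                 "af_female", "af_male"])
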