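"""Threshold rules for early Y degeneration.

Both rules are pure threshold functions: idempotent and monotone in
their inputs.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def flag_degenerate_genes(ratios: pd.DataFrame,
                          threshold: float = 0.75) -> pd.DataFrame:
    """Flag genes whose normalized male:female depth ratio is *strictly*
    below ``threshold`` (a ratio of exactly 0.75 is not degenerate).
    Genes with a missing ratio stay unflagged with NA."""
    if "mf_depth_ratio" not in ratios.columns:
        raise ValueError("need a mf_depth_ratio column")
    out = ratios.copy()
    ratio = out["mf_depth_ratio"]
    flag = ratio < threshold
    out["degenerate"] = flag.astype("boolean").mask(ratio.isna())
    return out


def fixed_lof(lof: pd.DataFrame, f_thresh: float = 0.9,
              m_thresh: float = 0.45,
              female_max_for_y: float = 0.05) -> pd.DataFrame:
    """Flag loss-of-function variants fixed on the X or the Y.

    Fixed-on-X: female allele frequency > ``f_thresh``.  Fixed-on-Y:
    male allele frequency > ``m_thresh`` (the hemizygous maximum is 0.5)
    while the female frequency is at most ``female_max_for_y``.
    """
    for col in ("af_female", "af_male"):
        if col not in lof.columns:
            raise ValueError(f"need an {col} column")
        vals = lof[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    out = lof.copy()
    out["fixed_on_x"] = (out["af_female"] > f_thresh).fillna(False)
    out["fixed_on_y"] = ((out["af_male"] > m_thresh)
                         & (out["af_female"] <= female_max_for_y)
                         ).fillna(False)
    return out


def degeneration_report(gene_flags: pd.DataFrame,
                        lof_flags: pd.DataFrame) -> dict:
    return {
        "n_genes": int(len(gene_flags)),
        "n_degenerate": int(gene_flags["degenerate"].fillna(False).sum()),
        "degenerate_genes": list(
            gene_flags.loc[gene_flags["degenerate"].fillna(False),
                           "gene"]) if "gene" in gene_flags else [],
        "n_lof": int(len(lof_flags)),
        "n_fixed_on_x": int(lof_flags["fixed_on_x"].sum())
        if len(lof_flags) else 0,
        "n_fixed_on_y": int(lof_flags["fixed_on_y"].sum())
        if len(lof_flags) else 0,
    }
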