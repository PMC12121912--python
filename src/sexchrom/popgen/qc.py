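"""The four-rule variant QC filter applied before all track statistics.

Rules, applied in order:
1. drop samples whose mean coverage is below ``min_sample_coverage``;
2. drop sites whose cohort mean depth is below ``min_site_depth`` or
   above ``max_site_depth``;
3. drop sites with a missing-call fraction above ``max_missing``
   (computed after rule 1);
4. drop sites with minor allele frequency below ``min_maf``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..core import GenotypeMatrix


@dataclass(frozen=True)
class QCThresholds:
    min_sample_coverage: float = 6.0
    min_site_depth: float = 4.0
    max_site_depth: float = 40.0
    max_missing: float = 0.2
    min_maf: float = 0.05

    def validate(self):
        for name in ("min_sample_coverage", "min_site_depth",
                     "max_site_depth", "min_maf", "max_missing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.min_site_depth >= self.max_site_depth:
            raise ValueError("min_site_depth must be below max_site_depth")


def variant_qc_filter(gm: GenotypeMatrix, sample_coverage: dict,
                      site_depth: np.ndarray,
                      thresholds: QCThresholds = QCThresholds()
                      ) -> tuple[GenotypeMatrix, dict]:
    """Apply the four QC rules and report removal counts per rule.

    Parameters
    ----------
    sample_coverage : mapping sample -> mean coverage
    site_depth : array of cohort mean depth per site (pre-filter order)
    """
    thresholds.validate()
    site_depth = np.asarray(site_depth, dtype=float)
    if len(site_depth) != gm.n_sites:
        raise ValueError("site_depth length mismatch")

    keep_samples = [s for s in gm.samples
                    if sample_coverage[s] >= thresholds.min_sample_coverage]
    removed_samples = [s for s in gm.samples if s not in keep_samples]
    out = gm.take_samples(keep_samples) if removed_samples else gm

    depth_ok = ((site_depth >= thresholds.min_site_depth)
                & (site_depth <= thresholds.max_site_depth))
    n_rule2 = int((~depth_ok).sum())

    called = out.gt >= 0
    missing_frac = 1.0 - called.mean(axis=1) if out.n_samples else \
        np.ones(out.n_sites)
    miss_ok = missing_frac <= thresholds.max_missing
    n_rule3 = int((depth_ok & ~miss_ok).sum())

    n, alt = out.allele_counts(out.samples)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    maf_ok = maf >= thresholds.min_maf
    n_rule4 = int((depth_ok & miss_ok & ~maf_ok).sum())

    keep = depth_ok & miss_ok & maf_ok
    report = {
        "samples_removed": removed_samples,
        "n_samples_removed": len(removed_samples),
        "sites_in": gm.n_sites,
        "removed_rule2_depth": n_rule2,
        "removed_rule3_missing": n_rule3,
        "removed_rule4_maf": n_rule4,
        "sites_out": int(keep.sum()),
    }
    return out.take_sites(keep), report


def report_frame(report: dict) -> pd.DataFrame:
    return pd.DataFrame(sorted(report.items()), columns=["metric", "value"])
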