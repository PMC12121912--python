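"""Decide XY vs ZW vs none per chromosome, and classify cross markers by
sex-linked segregation pattern (deterministic rules with an error
tolerance, standing in for probabilistic transcript classifiers)."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

XY = "XY"
ZW = "ZW"
NONE = "none"

MARKER_CLASSES = ("XY-consistent", "ZW-consistent", "autosomal",
                  "uninformative")


@dataclass
class HeterogametyVerdict:
    chrom: str
    verdict: str
    candidate_region: tuple | None
    n_elevated: int
    median_pi_ratio: float
    marker_counts: dict | None = None
    warning: str | None = None


@dataclass
class MarkerSegregationClass:
    classes: np.ndarray
    mismatches: np.ndarray

    def counts(self) -> dict:
        return {c: int((self.classes == c).sum()) for c in MARKER_CLASSES}


# ---------------------------------------------------------------------
def classify_cross_markers(mother_gt, father_gt, offspring_gt,
                           offspring_sex, error_eps: float = 0.0
                           ) -> MarkerSegregationClass:
    """Classify each marker of a cross by its segregation pattern.

    A marker is XY-consistent when the father is heterozygous, the
    mother homozygous, every son heterozygous and every daughter
    homozygous for the maternal allele (up to a fraction ``error_eps``
    of mismatching offspring); ZW-consistent is the sex-mirrored rule.
    Markers whose offspring genotype counts fit the Mendelian
    expectation from the parents irrespective of sex (chi-square
    p > 0.05) are autosomal; everything else, including markers with a
    missing parent call, is uninformative.
    """
    mother = np.asarray(mother_gt)
    father = np.asarray(father_gt)
    off = np.asarray(offspring_gt)
    sex = np.asarray(list(offspring_sex))
    if off.shape != (len(mother), len(sex)):
        raise ValueError("offspring matrix shape mismatch")
    sons = sex == "M"
    daughters = sex == "F"
    if sons.sum() < 2 or daughters.sum() < 2:
        raise ValueError("need at least 2 offspring of each sex")

    n_markers = len(mother)
    classes = np.full(n_markers, "uninformative", dtype=object)
    mismatches = np.zeros(n_markers, dtype=np.int64)

    for i in range(n_markers):
        m, f = mother[i], father[i]
        if m < 0 or f < 0:
            continue
        o = off[i]
        called = o >= 0
        if not called.any():
            continue
        label, mm = _classify_one(m, f, o, called, sons, daughters,
                                  error_eps)
        classes[i] = label
        mismatches[i] = mm
    return MarkerSegregationClass(classes, mismatches)


def _sex_linked_mismatches(het_parent_gt, hom_parent_gt, o, called,
                           het_kids, hom_kids):
    """Mismatches against: het-sex offspring het, hom-sex offspring
    homozygous for the (homozygous) parent's allele."""
    mm = int((o[het_kids & called] != 1).sum())
    mm += int((o[hom_kids & called] != hom_parent_gt).sum())
    return mm


def _classify_one(m, f, o, called, sons, daughters, error_eps):
    n_called = int(called.sum())
    budget = error_eps * n_called
    if f == 1 and m in (0, 2):
        mm = _sex_linked_mismatches(f, m, o, called, sons, daughters)
        if mm <= budget:
            return "XY-consistent", mm
    if m == 1 and f in (0, 2):
        mm = _sex_linked_mismatches(m, f, o, called, daughters, sons)
        if mm <= budget:
            return "ZW-consistent", mm
    exp = _mendelian_expectation(m, f)
    if exp is not None:
        obs = np.array([(o[called] == g).sum() for g in (0, 1, 2)],
                       dtype=float)
        keep = exp > 0
        if (obs[~keep] == 0).all() and keep.sum() >= 2:
            chi2 = ((obs[keep] - exp[keep] * n_called) ** 2
                    / (exp[keep] * n_called)).sum()
            p = stats.chi2.sf(chi2, int(keep.sum()) - 1)
            if p > 0.05:
                return "autosomal", int(np.abs(
                    obs - exp * n_called).sum() // 2)
    return "uninformative", 0


def _mendelian_expectation(m, f):
    probs = np.zeros(3)
    for a in ((m // 2, m - m // 2) if m != 1 else (0, 1)):
        for b in ((f // 2, f - f // 2) if f != 1 else (0, 1)):
            probs[a + b] += 0.25
    return probs


# ---------------------------------------------------------------------
def marker_sex_association(counts) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a genotype-by-sex
    contingency table."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if table.sum() <= 0:
        raise ValueError("empty table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------
@dataclass
class _ChromEvidence:
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)


def _elevated_runs(flags: np.ndarray, min_run: int) -> list:
    runs, start = [], None
    for i, f in enumerate(list(flags) + [False]):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start >= min_run:
                runs.append((start, i))
            start = None
    return runs


def infer_heterogamety(track: pd.DataFrame,
                       elevated_quantile: float = 0.99,
                       pi_ratio_min: float = 2.0,
                       min_run: int = 3,
                       markers: MarkerSegregationClass | None = None,
                       min_windows: int = 10) -> dict:
    """Per-chromosome heterogamety verdicts from a combined track.

    ``track`` needs columns chrom, start, end, fst, pi_male, pi_female.
    For each chromosome the elevation threshold is the
    ``elevated_quantile`` quantile of Fst over all *other* chromosomes'
    windows; XY requires a run of at least ``min_run`` consecutive
    elevated windows whose median male:female pi ratio reaches
    ``pi_ratio_min`` (ZW is the mirror).  When marker classes from a
    cross are supplied they must agree or the verdict is downgraded to
    none.
    """
    required = {"chrom", "start", "end", "fst", "pi_male", "pi_female"}
    missing = required - set(track.columns)
    if missing:
        raise ValueError(f"track lacks columns {sorted(missing)}")
    out = {}
    marker_counts = markers.counts() if markers is not None else None
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        scored = sub.dropna(subset=["fst"])
        if len(scored) < min_windows:
            out[chrom] = HeterogametyVerdict(
                chrom, NONE, None, 0, np.nan, marker_counts,
                warning=f"only {len(scored)} scored windows")
            continue
        others = track.loc[track.chrom != chrom, "fst"].dropna()
        if others.empty:
            threshold = scored["fst"].quantile(elevated_quantile)
        else:
            threshold = others.quantile(elevated_quantile)
        flags = (sub["fst"] >= threshold).fillna(False).to_numpy()
        eps = 1e-12
        ratio = ((sub["pi_male"] + eps)
                 / (sub["pi_female"] + eps)).to_numpy()
        # elevated differentiation must coincide with a diversity excess
        # in one sex over a minimum run of windows: a large inversion can
        # raise Fst over a span much wider than the SDR while the
        # diversity excess stays confined, so the two channels are
        # intersected per window before run-length filtering.
        xy_runs = _elevated_runs(flags & (ratio >= pi_ratio_min), min_run)
        zw_runs = _elevated_runs(flags & (ratio <= 1.0 / pi_ratio_min),
                                 min_run)
        n_xy = sum(b - a for a, b in xy_runs)
        n_zw = sum(b - a for a, b in zw_runs)
        if n_xy == 0 and n_zw == 0:
            out[chrom] = HeterogametyVerdict(chrom, NONE, None,
                                             int(flags.sum()), np.nan,
                                             marker_counts)
            continue
        verdict = XY if n_xy >= n_zw else ZW
        runs = xy_runs if verdict == XY else zw_runs
        idx = np.concatenate([np.arange(a, b) for a, b in runs])
        windows = sub.iloc[idx]
        med = float(np.median(ratio[idx]))
        region = (chrom, int(windows["start"].min()),
                  int(windows["end"].max()))
        if verdict != NONE and marker_counts is not None:
            xy_n = marker_counts.get("XY-consistent", 0)
            zw_n = marker_counts.get("ZW-consistent", 0)
            if (verdict == XY and zw_n > xy_n) or \
                    (verdict == ZW and xy_n > zw_n):
                verdict = NONE
        out[chrom] = HeterogametyVerdict(
            chrom, verdict, region if verdict != NONE else None,
            int(flags.sum()), med, marker_counts)
    return out
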