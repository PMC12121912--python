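import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sexchrom.core import sliding_windows
from sexchrom.heterogamety import (
    classify_cross_markers,
    infer_heterogamety,
    marker_sex_association,
)
from sexchrom.popgen import windowed_fst, windowed_pi
from sexchrom.simulate import CrossConfig, simulate_cross_individuals, simulate_population
from sexchrom.simulate.population import KIND_SDR
from sexchrom.simulate.presets import small_xy


# ---------------------------------------------------------------------
# marker classification
# ---------------------------------------------------------------------
def test_xy_consistent_marker():
    off = np.array([[1, 1, 1, 0, 0, 0]])
    res = classify_cross_markers([0], [1], off, "MMMFFF")
    assert res.classes[0] == "XY-consistent"


def test_zw_consistent_marker():
    off = np.array([[0, 0, 0, 1, 1, 1]])
    res = classify_cross_markers([1], [0], off, "MMMFFF")
    assert res.classes[0] == "ZW-consistent"


def test_autosomal_marker():
    # both parents het, offspring ~1:2:1 irrespective of sex
    off = np.array([[0, 1, 1, 2, 1, 1, 0, 2]])
    res = classify_cross_markers([1], [1], off, "MMMMFFFF")
    assert res.classes[0] == "autosomal"


def test_missing_parent_uninformative():
    off = np.array([[1, 1, 0, 0]])
    res = classify_cross_markers([-1], [1], off, "MMFF")
    assert res.classes[0] == "uninformative"


def test_error_tolerance():
    off = np.array([[1, 1, 1, 1, 1, 1, 1, 1, 1, 0,   # one bad son
                     0, 0, 0, 0, 0, 0, 0, 0, 0, 0]])
    sexes = "M" * 10 + "F" * 10
    strict = classify_cross_markers([0], [1], off, sexes, error_eps=0.0)
    loose = classify_cross_markers([0], [1], off, sexes, error_eps=0.1)
    assert strict.classes[0] != "XY-consistent"
    assert loose.classes[0] == "XY-consistent"
    assert loose.mismatches[0] == 1


def test_simulated_xy_cross_markers_exact():
    """On an error-free XY cross, every SDR marker is XY-consistent and
    none is ZW-consistent."""
    from tests.test_crosses import base_cfg

    cfg = base_cfg(seed=3)
    cross = CrossConfig(n_sons=12, n_daughters=12)
    gm, pedigree, truth = simulate_cross_individuals(cross, cfg)
    idx = {s: k for k, s in enumerate(gm.samples)}
    offspring = [s for s in gm.samples if s not in ("mother", "father")]
    off_sex = [pedigree.set_index("sample").loc[s, "sex"]
               for s in offspring]
    off_gt = gm.gt[:, [idx[s] for s in offspring]]
    res = classify_cross_markers(gm.gt[:, idx["mother"]],
                                 gm.gt[:, idx["father"]],
                                 off_gt, off_sex, error_eps=0.0)
    ss = truth.sites["chr2"]
    sdr_pos = set(ss.pos[ss.kind == KIND_SDR])
    is_sdr = np.array([c == "chr2" and p in sdr_pos
                       for c, p in zip(gm.chrom, gm.pos)])
    assert (res.classes[is_sdr] == "XY-consistent").all()
    assert (res.classes == "ZW-consistent")[is_sdr].sum() == 0
    counts = res.counts()
    assert counts["XY-consistent"] > counts["ZW-consistent"]


# ---------------------------------------------------------------------
# chi-square association
# ---------------------------------------------------------------------
def test_association_independent_table_zero():
    chi2, p = marker_sex_association([[25, 25], [25, 25]])
    assert chi2 == pytest.approx(0.0)


def test_association_hand_computed():
    """[[10,0],[0,10]]: all expectations 5, chi2 = 4 * 25/5 = 20."""
    chi2, p = marker_sex_association([[10, 0], [0, 10]])
    assert chi2 == pytest.approx(20.0)
    assert p == pytest.approx(stats.chi2.sf(20.0, 1))


def test_association_sex_linked_marker_large_cross():
    """A perfectly sex-linked marker in 380 offspring: p far below
    1e-50 (chi-square tail oracle)."""
    n_m, n_f = 190, 190
    chi2, p = marker_sex_association([[n_m, 0], [0, n_f]])
    assert chi2 == pytest.approx(380.0)
    assert p < 1e-50
    assert p == pytest.approx(stats.chi2.sf(380.0, 1))


def test_association_errors():
    with pytest.raises(ValueError):
        marker_sex_association([[1, 2]])
    with pytest.raises(ValueError):
        marker_sex_association([[0, 0], [0, 0]])
    with pytest.raises(ValueError):
        marker_sex_association([[5, 0], [5, 0]])


# ---------------------------------------------------------------------
# verdicts
# ---------------------------------------------------------------------
def build_track(cfg, gm, table, swap_sexes=False):
    w = sliding_windows(cfg.chrom_lengths)
    females = list(table.loc[table.sex == "F", "sample"])
    males = list(table.loc[table.sex == "M", "sample"])
    if swap_sexes:
        females, males = males, females
    track = windowed_fst(gm, females, males, w)
    track["pi_male"] = windowed_pi(gm, males, w)["pi"]
    track["pi_female"] = windowed_pi(gm, females, w)["pi"]
    return track


def test_verdict_xy_on_sdr_chromosome_only(small_xy_cohort):
    track = build_track(small_xy_cohort["cfg"], small_xy_cohort["gm"],
                        small_xy_cohort["table"])
    verdicts = infer_heterogamety(track)
    assert verdicts["chr3"].verdict == "XY"
    assert verdicts["chr1"].verdict == "none"
    assert verdicts["chr2"].verdict == "none"
    chrom, s, e = small_xy_cohort["cfg"].sdr_interval
    _, cs, ce = verdicts["chr3"].candidate_region
    assert abs(cs - s) <= 20_000 and abs(ce - e) <= 20_000


def test_sex_label_swap_gives_zw(small_xy_cohort):
    track = build_track(small_xy_cohort["cfg"], small_xy_cohort["gm"],
                        small_xy_cohort["table"], swap_sexes=True)
    verdicts = infer_heterogamety(track)
    assert verdicts["chr3"].verdict == "ZW"


def test_autosomal_simulation_all_none():
    cfg = small_xy(seed=5, with_sdr=False)
    gm, table, _ = simulate_population(cfg)
    verdicts = infer_heterogamety(build_track(cfg, gm, table))
    assert all(v.verdict == "none" for v in verdicts.values())
    assert all(v.candidate_region is None for v in verdicts.values())


def test_too_few_windows_warns():
    track = pd.DataFrame({
        "chrom": ["c1"] * 5, "start": range(0, 50, 10),
        "end": range(10, 60, 10), "fst": [0.1] * 5,
        "pi_male": [1e-3] * 5, "pi_female": [1e-3] * 5})
    verdicts = infer_heterogamety(track)
    assert verdicts["c1"].verdict == "none"
    assert "scored windows" in verdicts["c1"].warning


def test_marker_disagreement_downgrades(small_xy_cohort):
    track = build_track(small_xy_cohort["cfg"], small_xy_cohort["gm"],
                        small_xy_cohort["table"])

    class FakeMarkers:
        def counts(self):
            return {"XY-consistent": 1, "ZW-consistent": 50}

    verdicts = infer_heterogamety(track, markers=FakeMarkers())
    assert verdicts["chr3"].verdict == "none"


def test_missing_columns_error():
    with pytest.raises(ValueError):
        infer_heterogamety(pd.DataFrame({"chrom": [], "fst": []}))
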