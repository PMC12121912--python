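import numpy as np
import pytest

from tests.conftest import scan_cohort
from sexchrom.core import GenotypeMatrix
from sexchrom.invscan import (
    classify_inversion_linkage,
    genotype_frequency_table,
    genotype_inversion,
)
from sexchrom.invscan.genotype import _two_means_split
from sexchrom.simulate.barcodes import MoleculeSet
from sexchrom.simulate.presets import ct_like, ns_like


# ---------------------------------------------------------------------
# constructed-input genotyping
# ---------------------------------------------------------------------
def constructed_cohort(rng, het_samples, ii_samples, rr_samples,
                       start=300_000, end=700_000, length=1_000_000):
    """Cohort with engineered het-density ratios and junction support."""
    samples = het_samples + ii_samples + rr_samples
    n_sites = 2_000
    pos = np.sort(rng.choice(length, n_sites, replace=False))
    inside = (pos >= start) & (pos < end)
    gt = np.zeros((n_sites, len(samples)), dtype=np.int8)
    for k, s in enumerate(samples):
        base = rng.random(n_sites) < 0.2          # flank het density
        boost = rng.random(n_sites) < 0.6         # extra hets inside
        het = base | (boost & inside) if s in het_samples else base
        gt[het, k] = 1
    gm = GenotypeMatrix(np.full(n_sites, "chr1", dtype=object), pos,
                        np.full(n_sites, "A", dtype=object),
                        np.full(n_sites, "T", dtype=object), gt, samples)
    segs, names, bcs = [], [], []
    for k, s in enumerate(samples):
        for b, bp in enumerate((start, end)):
            if s in het_samples or s in rr_samples:
                names.append(s)
                bcs.append(f"{s}:r{b}")
                segs.append([(bp - 5_000, bp + 5_000)])
            if s in het_samples or s in ii_samples:
                names.append(s)
                bcs.append(f"{s}:i{b}")
                segs.append([(start - 5_000, start),
                             (end - 5_000, end)] if bp == start else
                            [(start, start + 5_000), (end, end + 5_000)])
    mols = MoleculeSet(np.asarray(names, dtype=object),
                       np.asarray(bcs, dtype=object),
                       np.full(len(names), "chr1", dtype=object), segs)
    return gm, mols


def test_constructed_density_cluster(rng):
    het = [f"h{i}" for i in range(6)]
    ii = [f"i{i}" for i in range(5)]
    rr = [f"r{i}" for i in range(5)]
    gm, mols = constructed_cohort(rng, het, ii, rr)
    calls = genotype_inversion(("chr1", 300_000, 700_000), gm, mols,
                               flank_bp=250_000, junction_tol=6_000)
    for s in het:
        assert calls[s] == "RI"
    for s in ii:
        assert calls[s] == "II"
    for s in rr:
        assert calls[s] == "RR"


def test_na_when_no_junction_support(rng):
    het = [f"h{i}" for i in range(6)]
    ii = [f"i{i}" for i in range(4)]
    rr = [f"r{i}" for i in range(4)]
    gm, mols = constructed_cohort(rng, het, ii, rr)
    keep = ~np.char.startswith(mols.sample.astype(str), "r0")
    stripped = MoleculeSet(mols.sample[keep], mols.barcode[keep],
                           mols.chrom[keep],
                           [s for s, k in zip(mols.segments, keep) if k])
    calls = genotype_inversion(("chr1", 300_000, 700_000), gm, stripped,
                               flank_bp=250_000, junction_tol=6_000)
    assert calls["r0"] == "NA"
    assert calls["r1"] == "RR"


def test_two_means_split_guard():
    flat = np.full(10, 1.0) + np.linspace(0, 0.01, 10)
    upper, thr = _two_means_split(flat)
    assert not upper.any()
    split, thr = _two_means_split(np.array([1.0] * 5 + [4.0] * 5))
    assert split.sum() == 5


# ---------------------------------------------------------------------
# preset recovery (reduced scale; full scale in acceptance tests)
# ---------------------------------------------------------------------
def test_ct_recovery_scaled():
    cfg = ct_like(seed=2, scale=0.4)
    run = scan_cohort(cfg)
    calls = genotype_inversion(run["candidates"][0], run["gm"],
                               run["mols"])
    sexes = dict(zip(run["table"]["sample"], run["table"]["sex"]))
    linkage, table = classify_inversion_linkage(calls, sexes)
    assert linkage == "X-linked"
    assert table.loc["F", "Inv/Inv"] == pytest.approx(0.85)
    assert table.loc["M", "Ref/Inv"] == pytest.approx(0.85)
    truth_counts = run["truth"].genotype_counts("invX")
    called = genotype_frequency_table(calls, sexes)
    assert called.loc["F", "n"] == truth_counts.loc["F"].sum()


def test_ns_recovery_scaled():
    cfg = ns_like(seed=2, scale=0.4)
    run = scan_cohort(cfg)
    calls = genotype_inversion(run["candidates"][0], run["gm"],
                               run["mols"])
    sexes = dict(zip(run["table"]["sample"], run["table"]["sex"]))
    linkage, table = classify_inversion_linkage(calls, sexes)
    assert linkage == "Y-linked"
    assert table.loc["M", "Ref/Inv"] == pytest.approx(13 / 14)
    assert sum(c == "II" for c in calls.values()) == 0


def test_genotyping_failure_flagged(rng):
    gm, mols = constructed_cohort(rng, [], [], [f"r{i}" for i in range(4)])
    empty = MoleculeSet(np.empty(0, dtype=object), np.empty(0, dtype=object),
                        np.empty(0, dtype=object), [])
    with pytest.raises(RuntimeError):
        genotype_inversion(("chr1", 300_000, 700_000), gm, empty,
                           flank_bp=250_000)


# ---------------------------------------------------------------------
# linkage classification
# ---------------------------------------------------------------------
def make_calls(f_counts, m_counts):
    calls, sexes = {}, {}
    i = 0
    for sex, counts in (("F", f_counts), ("M", m_counts)):
        for gt, n in counts.items():
            for _ in range(n):
                calls[f"s{i}"] = gt
                sexes[f"s{i}"] = sex
                i += 1
    return calls, sexes


def test_linkage_y():
    calls, sexes = make_calls({"RR": 15}, {"RI": 13, "RR": 1})
    linkage, _ = classify_inversion_linkage(calls, sexes)
    assert linkage == "Y-linked"


def test_linkage_x():
    calls, sexes = make_calls({"II": 17, "RI": 3}, {"RI": 17, "RR": 3})
    linkage, _ = classify_inversion_linkage(calls, sexes)
    assert linkage == "X-linked"


def test_linkage_autosomal():
    calls, sexes = make_calls({"RR": 5, "RI": 8, "II": 7},
                              {"RR": 5, "RI": 8, "II": 7})
    linkage, _ = classify_inversion_linkage(calls, sexes)
    assert linkage == "autosomal"


def test_linkage_small_sample_unknown():
    calls, sexes = make_calls({"RR": 2}, {"RI": 10})
    assert classify_inversion_linkage(calls, sexes)[0] == "unknown"


def test_frequency_rows_sum_to_one():
    calls, sexes = make_calls({"RR": 3, "RI": 4, "II": 5, "NA": 2},
                              {"RR": 6, "RI": 1, "II": 0})
    table = genotype_frequency_table(calls, sexes)
    for sex in ("F", "M"):
        assert table.loc[sex, ["Ref/Ref", "Ref/Inv", "Inv/Inv"]].sum() \
            == pytest.approx(1.0)
    assert table.loc["F", "n"] == 12  # NA excluded


def test_sex_permutation_destroys_linkage(rng):
    """Permuting sex labels converts sex-linked calls to autosomal or
    unknown in >= 95% of replicates."""
    calls, sexes = make_calls({"II": 17, "RI": 3}, {"RI": 17, "RR": 3})
    labels = list(sexes.values())
    names = list(sexes)
    broken = 0
    n_rep = 60
    for _ in range(n_rep):
        rng.shuffle(labels)
        permuted = dict(zip(names, labels))
        linkage, _ = classify_inversion_linkage(calls, permuted)
        if linkage in ("autosomal", "unknown"):
            broken += 1
    assert broken / n_rep >= 0.95
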