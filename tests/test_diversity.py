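from itertools import combinations

import numpy as np
import pytest

from sexchrom.core import GenotypeMatrix, sliding_windows
from sexchrom.popgen import depth_ratio, snp_density, windowed_pi
from sexchrom.popgen.diversity import site_pi


def pi_bruteforce(genotypes):
    """Enumerate all unordered allele pairs at one site and count
    mismatches (missing genotypes excluded)."""
    alleles = []
    for g in genotypes:
        if g < 0:
            continue
        alleles += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[g]
    pairs = list(combinations(alleles, 2))
    if not pairs:
        return 0.0
    return sum(a != b for a, b in pairs) / len(pairs)


def test_site_pi_eight_alleles_four_alt():
    """8 alleles, 4 alt: 16 mismatching of 28 pairs = 4/7."""
    assert site_pi([8], [4])[0] == pytest.approx(16 / 28)
    assert pi_bruteforce([1, 1, 1, 1]) == pytest.approx(16 / 28)


def test_site_pi_monomorphic_zero():
    assert site_pi([10], [0])[0] == 0.0
    assert site_pi([10], [10])[0] == 0.0
    assert site_pi([1], [1])[0] == 0.0  # fewer than 2 alleles -> skipped


def make_gm(rng, n_sites, n_samples, length, missing=0.1):
    pos = np.sort(rng.choice(length, size=n_sites, replace=False))
    gt = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    gt[rng.random(gt.shape) < missing] = -1
    return GenotypeMatrix(np.full(n_sites, "chr1", dtype=object), pos,
                          np.full(n_sites, "A", dtype=object),
                          np.full(n_sites, "T", dtype=object), gt,
                          [f"s{i}" for i in range(n_samples)])


def test_windowed_pi_equals_bruteforce_everywhere(rng):
    """Exact equality with pairwise mismatch enumeration on 100 random
    windows."""
    checked = 0
    while checked < 100:
        gm = make_gm(rng, n_sites=40, n_samples=6, length=50_000)
        w = sliding_windows({"chr1": 50_000}, 10_000, 10_000)
        track = windowed_pi(gm, gm.samples, w)
        for _, row in track.iterrows():
            mask = (gm.pos >= row.start) & (gm.pos < row.end)
            expected = sum(pi_bruteforce(gm.gt[i])
                           for i in np.flatnonzero(mask))
            expected /= row.end - row.start
            assert row.pi == pytest.approx(expected, abs=1e-12)
            checked += 1


def test_pi_identical_haplotypes_zero():
    gm = make_gm(np.random.default_rng(0), 20, 5, 10_000, missing=0)
    gm.gt[:] = 2
    w = sliding_windows({"chr1": 10_000}, 10_000, 10_000)
    assert (windowed_pi(gm, gm.samples, w).pi == 0).all()


def test_male_pi_exceeds_female_in_sdr(small_xy_cohort):
    cfg = small_xy_cohort["cfg"]
    gm = small_xy_cohort["gm"]
    table = small_xy_cohort["table"]
    chrom, s, e = cfg.sdr_interval
    w = sliding_windows(cfg.chrom_lengths)
    males = list(table.loc[table.sex == "M", "sample"])
    females = list(table.loc[table.sex == "F", "sample"])
    pim = windowed_pi(gm, males, w)
    pif = windowed_pi(gm, females, w)
    sel = (pim.chrom == chrom) & (pim.start >= s) & (pim.start < e)
    assert (pim.pi[sel] > pif.pi[sel]).all()


def test_empty_group_errors(rng):
    gm = make_gm(rng, 10, 4, 10_000)
    w = sliding_windows({"chr1": 10_000}, 10_000, 10_000)
    with pytest.raises(ValueError):
        windowed_pi(gm, [], w)
    with pytest.raises(ValueError):
        snp_density(gm, [], w)


# ---------------------------------------------------------------------
def test_snp_density_maf_filter(rng):
    gm = make_gm(rng, 50, 30, 40_000, missing=0)
    w = sliding_windows({"chr1": 40_000}, 40_000, 40_000)
    n, alt = gm.allele_counts(gm.samples)
    p = alt / n
    maf = np.minimum(p, 1 - p)
    expected = int(((maf >= 0.05) & (maf > 0)).sum())
    assert snp_density(gm, gm.samples, w).iloc[0]["count"] == expected


def test_snp_density_no_variants():
    gm = make_gm(np.random.default_rng(0), 10, 5, 10_000, missing=0)
    gm.gt[:] = 0
    w = sliding_windows({"chr1": 10_000}, 5_000, 5_000)
    assert (snp_density(gm, gm.samples, w)["count"] == 0).all()


def test_snp_density_overlapping_windows_double_count(rng):
    gm = make_gm(rng, 60, 20, 100_000, missing=0)
    w = sliding_windows({"chr1": 100_000}, 20_000, 10_000)
    track = snp_density(gm, gm.samples, w)
    n, alt = gm.allele_counts(gm.samples)
    p = alt / n
    maf = np.minimum(p, 1 - p)
    n_seg = int(((maf >= 0.05) & (maf > 0)).sum())
    assert track["count"].sum() >= n_seg


def test_snp_density_higher_in_inversion_heterozygotes():
    from sexchrom.simulate import simulate_population
    from sexchrom.simulate.presets import small_inversion

    cfg = small_inversion(seed=5)
    gm, table, truth = simulate_population(cfg)
    inv = cfg.inversions[0]
    gts = truth.inversion_genotypes["inv1"]
    hets = [s for s, g in gts.items() if g == "RI"][:6]
    homs = [s for s, g in gts.items() if g != "RI"][:6]
    w = sliding_windows(cfg.chrom_lengths)
    dh = snp_density(gm, hets, w)
    dr = snp_density(gm, homs, w)
    inside = (dh.start >= inv.start) & (dh.start < inv.end - 20_000)
    assert dh["count"][inside].mean() > 1.5 * dr["count"][inside].mean()


# ---------------------------------------------------------------------
def test_depth_ratio_zero_female_depth_missing():
    import pandas as pd

    from sexchrom.core import make_sample_table

    table = make_sample_table(["f1", "m1"], ["F", "M"])
    depth = pd.DataFrame({"chrom": ["auto", "sex"], "start": [0, 10],
                          "end": [10, 20], "f1": [5.0, 0.0],
                          "m1": [5.0, 5.0]})
    out = depth_ratio(depth, table, norm_chroms=["auto"])
    assert np.isnan(out.mf_depth_ratio.iloc[1])
    assert out.mf_depth_ratio.iloc[0] == pytest.approx(1.0)
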