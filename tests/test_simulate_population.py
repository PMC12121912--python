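import numpy as np
import pytest
from scipy import stats

from sexchrom.simulate import InversionSpec, SimConfig, simulate_population
from sexchrom.simulate.config import ConfigError, fixed_genotype_counts
from sexchrom.simulate.presets import ct_like, small_inversion, small_xy


def test_determinism_byte_identical():
    cfg = small_xy(seed=7)
    gm1, t1, _ = simulate_population(cfg)
    gm2, t2, _ = simulate_population(small_xy(seed=7))
    assert np.array_equal(gm1.gt, gm2.gt)
    assert np.array_equal(gm1.pos, gm2.pos)
    assert t1.equals(t2)


def test_different_seeds_differ():
    gm1, _, _ = simulate_population(small_xy(seed=1))
    gm2, _, _ = simulate_population(small_xy(seed=2))
    assert not np.array_equal(gm1.pos, gm2.pos)


def test_males_heterozygous_at_all_sdr_sites():
    cfg = small_xy(seed=3)
    assert cfg.error_rate == 0
    gm, table, truth = simulate_population(cfg)
    chrom, s, e = cfg.sdr_interval
    ss = truth.sites[chrom]
    from sexchrom.simulate.population import KIND_SDR
    sdr_pos = set(ss.pos[ss.kind == KIND_SDR])
    mask = np.array([c == chrom and p in sdr_pos
                     for c, p in zip(gm.chrom, gm.pos)])
    assert mask.sum() > 50
    males = table.loc[table.sex == "M", "sample"]
    sub = gm.take_samples(list(males))
    assert (sub.gt[mask] == 1).all()
    females = table.loc[table.sex == "F", "sample"]
    assert (gm.take_samples(list(females)).gt[mask] == 0).all()


def test_ct_fixed_composition_female_counts():
    gm, table, truth = simulate_population(ct_like(seed=5, scale=0.25))
    counts = truth.genotype_counts("invX")
    assert counts.loc["F"].tolist() == [0, 3, 17]
    assert counts.loc["M"].tolist() == [3, 17, 0]


def test_fixed_genotype_counts_largest_remainder():
    assert fixed_genotype_counts((0.07, 0.93, 0.0), 14) == \
        {"RR": 1, "RI": 13, "II": 0}
    assert fixed_genotype_counts((0.0, 0.15, 0.85), 20) == \
        {"RR": 0, "RI": 3, "II": 17}


def test_overlapping_inversions_rejected():
    with pytest.raises(ConfigError):
        SimConfig(chrom_lengths={"chr1": 1_000_000},
                  inversions=[
                      InversionSpec("chr1", 100_000, 500_000,
                                    "autosomal", allele_freq=0.5,
                                    name="a"),
                      InversionSpec("chr1", 400_000, 800_000,
                                    "autosomal", allele_freq=0.5,
                                    name="b")])


def test_y_inversion_cannot_be_homozygous():
    with pytest.raises(ConfigError):
        InversionSpec("chr1", 0, 100, "Y",
                      genotype_freqs={"M": (0.0, 0.5, 0.5)})


def test_y_inversion_confined_to_males():
    cfg = small_inversion(seed=0, linkage="Y")
    gm, table, truth = simulate_population(cfg)
    gts = truth.inversion_genotypes["inv1"]
    for sample, sex in truth.sex.items():
        if sex == "F":
            assert gts[sample] == "RR"
        assert gts[sample] != "II"


def test_invalid_configs():
    with pytest.raises(ConfigError):
        SimConfig(theta=1.5)
    with pytest.raises(ConfigError):
        SimConfig(step=0)
    with pytest.raises(ConfigError):
        SimConfig(sdr_interval=("chrX", 0, 10))
    with pytest.raises(ConfigError):
        SimConfig(chrom_lengths={"chr1": 10_000},
                  molecule_length_mean=40_000)


def test_hardy_weinberg_at_background_sites():
    """Sampled background genotypes fit HWE (per-site chi-square)."""
    cfg = small_xy(seed=11, with_sdr=False, theta=4e-3,
                   n_females=30, n_males=30)
    gm, _, truth = simulate_population(cfg)
    assert gm.n_sites >= 1000
    n, alt = gm.allele_counts(gm.samples)
    rejected = 0
    tested = 0
    for i in range(gm.n_sites):
        p = alt[i] / n[i]
        if p in (0, 1):
            continue
        g = gm.gt[i]
        obs = np.array([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()])
        exp = obs.sum() * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        if (exp < 1).any():
            continue
        chi2 = ((obs - exp) ** 2 / exp).sum()
        tested += 1
        if stats.chi2.sf(chi2, 1) < 0.01:
            rejected += 1
    assert tested >= 1000
    assert rejected / tested < 0.03


def test_heterozygote_excess_inside_inversion():
    """RI carriers are ~het_boost-fold more heterozygous than RR/II."""
    cfg = small_inversion(seed=2, linkage="X")
    gm, table, truth = simulate_population(cfg)
    inv = cfg.inversions[0]
    mask = gm.region_mask(inv.chrom, inv.start, inv.end)
    gts = truth.inversion_genotypes["inv1"]
    het = (gm.gt[mask] == 1).mean(axis=0)
    by = {"RI": [], "hom": []}
    for k, s in enumerate(gm.samples):
        by["RI" if gts[s] == "RI" else "hom"].append(het[k])
    ri, hom = np.mean(by["RI"]), np.mean(by["hom"])
    se = np.std(by["RI"]) / np.sqrt(len(by["RI"])) + \
        np.std(by["hom"]) / np.sqrt(len(by["hom"]))
    assert ri >= cfg.het_boost * hom - 3 * se * cfg.het_boost


def test_error_injection_rate_and_determinism():
    cfg = small_xy(seed=4, error_rate=0.05)
    gm1, _, _ = simulate_population(cfg)
    gm2, _, _ = simulate_population(small_xy(seed=4, error_rate=0.05))
    assert np.array_equal(gm1.gt, gm2.gt)
    clean, _, _ = simulate_population(small_xy(seed=4, error_rate=0.0))
    frac = (gm1.gt != clean.gt).mean()
    assert 0.03 < frac < 0.07


def test_zw_system_mirrors_xy():
    cfg = small_xy(seed=6, system="ZW")
    gm, table, truth = simulate_population(cfg)
    chrom, s, e = cfg.sdr_interval
    from sexchrom.simulate.population import KIND_SDR
    ss = truth.sites[chrom]
    sdr_pos = set(ss.pos[ss.kind == KIND_SDR])
    mask = np.array([c == chrom and p in sdr_pos
                     for c, p in zip(gm.chrom, gm.pos)])
    females = list(table.loc[table.sex == "F", "sample"])
    assert (gm.take_samples(females).gt[mask] == 1).all()
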