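import numpy as np
import pytest

from sexchrom.core import GenotypeMatrix, PoolCounts, sliding_windows
from sexchrom.popgen import pool_fst, site_fst_hudson, site_fst_wc, windowed_fst
from sexchrom.popgen.fst import site_fst_nei


# ---------------------------------------------------------------------
# Hudson
# ---------------------------------------------------------------------
def test_hudson_fully_sex_linked_is_half():
    """Females fixed hom-ref, males uniformly het -> exactly 0.5."""
    assert site_fst_hudson(0.0, 40, 0.5, 40) == pytest.approx(0.5)
    assert site_fst_hudson(0.0, 6, 0.5, 1000) == pytest.approx(0.5)


def test_hudson_trivials():
    assert site_fst_hudson(0.3, 20, 0.3, 20) == pytest.approx(0.0)
    assert site_fst_hudson(0.0, 20, 1.0, 20) == pytest.approx(1.0)
    assert np.isnan(site_fst_hudson(0.0, 20, 0.0, 20))
    with pytest.raises(ValueError):
        site_fst_hudson(0.5, 1, 0.5, 10)


def test_hudson_corrected_converges_monotonically():
    values = [site_fst_hudson(0.0, n, 0.5, n, corrected=True)
              for n in (4, 10, 40, 400, 4000)]
    assert all(b > a for a, b in zip(values, values[1:]))
    assert values[-1] == pytest.approx(0.5, abs=1e-3)
    assert all(v < 0.5 for v in values)


# ---------------------------------------------------------------------
# Weir-Cockerham
# ---------------------------------------------------------------------
def wc_oracle(g1, g2):
    """Independent transcription of the variance-component definitions,
    computed per allele and summed (the per-allele route used by
    reference implementations)."""
    from fractions import Fraction as F

    g1 = [int(x) for x in g1]
    g2 = [int(x) for x in g2]
    r = 2
    n = [len(g1), len(g2)]
    nbar = F(sum(n), r)
    nc = (sum(n) - F(sum(ni * ni for ni in n), sum(n))) / (r - 1)
    a_tot = b_tot = c_tot = F(0)
    for allele in (0, 1):  # ref, alt
        def dose(g):
            return (2 - g) if allele == 0 else g
        p = [F(sum(dose(x) for x in g), 2 * len(g)) for g in (g1, g2)]
        h = [F(sum(x == 1 for x in g), len(g)) for g in (g1, g2)]
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2
                 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                 - F(r - 1, r) * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                   - F(r - 1, r) * s2
                                   - F(2 * nbar - 1, 4 * nbar) * hbar)
        c = hbar / 2
        a_tot, b_tot, c_tot = a_tot + a, b_tot + b, c_tot + c
    denom = a_tot + b_tot + c_tot
    return float(a_tot / denom) if denom else float("nan")


def test_wc_fully_sex_linked_is_half_exactly():
    """At a fully sex-linked site (one group hom-ref, the other all het)
    the Weir-Cockerham estimator equals 0.5 exactly for any equal group
    size -- the expectation stated for a fully sex-linked SNP."""
    for n in (5, 20, 100):
        a, b, c, fst = site_fst_wc([0] * n, [1] * n)
        assert fst == pytest.approx(0.5, abs=1e-12)
        assert wc_oracle([0] * n, [1] * n) == pytest.approx(0.5)


def test_wc_matches_independent_oracle_on_random_sites(rng):
    for _ in range(100):
        n1, n2 = rng.integers(3, 30, size=2)
        g1 = rng.integers(0, 3, size=n1)
        g2 = rng.integers(0, 3, size=n2)
        if len(set(g1) | set(g2)) == 1 and g1[0] in (0, 2):
            continue
        *_, fst = site_fst_wc(g1, g2)
        expected = wc_oracle(g1, g2)
        if np.isnan(expected):
            assert np.isnan(fst)
        else:
            assert fst == pytest.approx(expected, abs=1e-6)


def test_wc_equal_frequency_groups_near_zero(rng):
    p = 0.4
    g1 = rng.binomial(1, p, (50, 2)).sum(axis=1)
    g2 = rng.binomial(1, p, (50, 2)).sum(axis=1)
    *_, fst = site_fst_wc(g1, g2)
    assert abs(fst) < 0.05


def test_wc_monomorphic_excluded():
    a, b, c, fst = site_fst_wc([0, 0, 0], [0, 0, 0])
    assert (a, b, c) == (0.0, 0.0, 0.0)
    assert np.isnan(fst)
    with pytest.raises(ValueError):
        site_fst_wc([0], [1, 1])


# ---------------------------------------------------------------------
# windowed
# ---------------------------------------------------------------------
def random_gm(rng, n_sites=300, n_samples=20, length=100_000):
    pos = np.sort(rng.choice(length, size=n_sites, replace=False))
    p = rng.uniform(0.1, 0.9, size=n_sites)
    gt = (rng.random((n_sites, n_samples)) < p[:, None]).astype(int) + \
        (rng.random((n_sites, n_samples)) < p[:, None]).astype(int)
    return GenotypeMatrix(np.full(n_sites, "chr1", dtype=object), pos,
                          np.full(n_sites, "A", dtype=object),
                          np.full(n_sites, "T", dtype=object),
                          gt.astype(np.int8),
                          [f"s{i}" for i in range(n_samples)])


def test_windowed_fst_random_mating_near_zero(rng):
    gm = random_gm(rng, n_sites=2000, n_samples=40, length=1_000_000)
    w = sliding_windows({"chr1": 1_000_000})
    track = windowed_fst(gm, [f"s{i}" for i in range(20)],
                         [f"s{i}" for i in range(20, 40)], w)
    vals = track.fst.dropna()
    assert abs(vals.mean()) < 3 * vals.std() / np.sqrt(len(vals)) + 0.01


def test_windowed_fst_invariances(rng):
    gm = random_gm(rng)
    w = sliding_windows({"chr1": 100_000})
    g1 = [f"s{i}" for i in range(10)]
    g2 = [f"s{i}" for i in range(10, 20)]
    base = windowed_fst(gm, g1, g2, w)
    # site order
    perm = rng.permutation(gm.n_sites)
    shuffled = GenotypeMatrix(gm.chrom[perm], gm.pos[perm], gm.ref[perm],
                              gm.alt[perm], gm.gt[perm], gm.samples)
    assert np.allclose(windowed_fst(shuffled, g1, g2, w).fst, base.fst,
                       equal_nan=True)
    # sample order within groups
    assert np.allclose(
        windowed_fst(gm, g1[::-1], g2[::-1], w).fst, base.fst,
        equal_nan=True)
    with pytest.raises(ValueError):
        windowed_fst(gm, g1, g1, w)
    with pytest.raises(ValueError):
        windowed_fst(gm, g1, g2, w, estimator="nope")


def test_windowed_fst_empty_window_is_missing(rng):
    gm = random_gm(rng, n_sites=10, length=20_000)
    w = sliding_windows({"chr1": 100_000})
    track = windowed_fst(gm, [f"s{i}" for i in range(10)],
                         [f"s{i}" for i in range(10, 20)], w)
    tail = track[track.start >= 40_000]
    assert tail.fst.isna().all()
    assert (tail.n_sites_used == 0).all()


def test_windowed_ratio_of_sums_split_invariance(rng):
    """Summing components over a window's sites equals combining the
    two halves of its site list."""
    from sexchrom.popgen.fst import _wc_components
    n1 = np.full(30, 12.0)
    n2 = np.full(30, 15.0)
    p1, p2 = rng.random(30), rng.random(30)
    h1, h2 = rng.random(30) * 0.5, rng.random(30) * 0.5
    a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    full = a.sum() / (a + b + c).sum()
    half = (a[:15].sum() + a[15:].sum()) / \
        ((a + b + c)[:15].sum() + (a + b + c)[15:].sum())
    assert full == pytest.approx(half)


# ---------------------------------------------------------------------
# pools
# ---------------------------------------------------------------------
def make_pools(freqs_a, freqs_b, depth=100, length=100_000, rng=None):
    n = len(freqs_a)
    pos = np.linspace(100, length - 100, n).astype(int)
    mk = lambda f, lab: PoolCounts(  # noqa: E731
        chrom=np.full(n, "chr1", dtype=object), pos=pos,
        ref=np.full(n, "A", dtype=object), alt=np.full(n, "T", dtype=object),
        ref_reads=np.round(depth * (1 - np.asarray(f))).astype(int),
        alt_reads=np.round(depth * np.asarray(f)).astype(int), label=lab)
    return mk(freqs_a, "a"), mk(freqs_b, "b")


def test_pool_fst_sex_linked_site_is_one_third():
    """Daughter pool fixed, son pool at 0.5: (Ht-Hs)/Ht = 1/3 with
    Ht = 0.375 and Hs = 0.25."""
    assert site_fst_nei(0.0, 0.5) == pytest.approx(1 / 3)
    a, b = make_pools([0.0] * 30, [0.5] * 30)
    w = sliding_windows({"chr1": 100_000})
    track = pool_fst(a, b, w)
    assert np.allclose(track.fst.dropna(), 1 / 3)


def test_pool_fst_equal_frequencies_zero():
    a, b = make_pools([0.3] * 10, [0.3] * 10)
    w = sliding_windows({"chr1": 100_000})
    assert np.allclose(pool_fst(a, b, w).fst.dropna(), 0.0)


def test_pool_fst_filters():
    a, b = make_pools([0.5, 0.01], [0.5, 0.0], depth=100)
    b.ref_reads[0] = 2
    b.alt_reads[0] = 1  # below min_reads in pool b
    w = sliding_windows({"chr1": 100_000})
    track = pool_fst(a, b, w, min_reads=4, min_count=2)
    assert track.n_sites_used.sum() == 0  # site 2 fails min minor count


def test_pool_fst_cross_elevates_sex_chromosome():
    from sexchrom.simulate import CrossConfig, simulate_cross_pools
    from tests.test_crosses import base_cfg

    cfg = base_cfg(seed=2)
    cross = CrossConfig(n_sons=30, n_daughters=30, pool_depth=80)
    sons, daughters, truth = simulate_cross_pools(cross, cfg)
    w = sliding_windows(cfg.chrom_lengths)
    track = pool_fst(sons, daughters, w)
    sdr = track[(track.chrom == "chr2") & (track.start >= 100_000)
                & (track.start < 200_000)]
    auto = track[track.chrom == "chr1"]
    # sibling pools carry a nonzero baseline from drawing the same four
    # parental haplotypes; the SDR must still stand clear above it
    assert sdr.fst.mean() > auto.fst.max()
    assert sdr.fst.mean() > auto.fst.mean() + 0.05
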