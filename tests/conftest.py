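import numpy as np
import pytest

from sexchrom.core import tile_windows
from sexchrom.invscan import (
    build_sharing_matrix,
    detect_inversion_candidates,
    distance_decay_null,
    genotype_inversion,
)
from sexchrom.simulate import presets, simulate_barcode_maps, simulate_population


def scan_cohort(cfg, tile=10_000, distal_min=500_000, z_min=5.0):
    """Run the simulate -> share -> detect chain on a config."""
    gm, table, truth = simulate_population(cfg)
    mols, junctions = simulate_barcode_maps(gm, truth, cfg)
    tiles = tile_windows(cfg.chrom_lengths, tile)
    matrix = build_sharing_matrix(mols.to_barcode_map(tile), tiles,
                                  distal_min=distal_min)
    null = distance_decay_null(matrix)
    candidates = detect_inversion_candidates(matrix, null, z_min=z_min)
    return {
        "cfg": cfg, "gm": gm, "table": table, "truth": truth,
        "mols": mols, "junctions": junctions, "matrix": matrix,
        "null": null, "candidates": candidates,
    }


@pytest.fixture(scope="session")
def ct_full():
    """Full-scale CT-style cohort (seed 1) with detection + genotyping."""
    run = scan_cohort(presets.ct_like(seed=1))
    assert run["candidates"], "CT detection found no candidate"
    run["calls"] = genotype_inversion(run["candidates"][0], run["gm"],
                                      run["mols"])
    return run


@pytest.fixture(scope="session")
def ns_full():
    """Full-scale NS-style cohort (seed 1) with detection + genotyping."""
    run = scan_cohort(presets.ns_like(seed=1))
    assert run["candidates"], "NS detection found no candidate"
    run["calls"] = genotype_inversion(run["candidates"][0], run["gm"],
                                      run["mols"])
    return run


@pytest.fixture(scope="session")
def small_xy_cohort():
    cfg = presets.small_xy(seed=0)
    gm, table, truth = simulate_population(cfg)
    return {"cfg": cfg, "gm": gm, "table": table, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
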