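"""Deterministic expectations for inversion segregation in a cross.

Given the parents' haplotype configuration, predicts the offspring
inversion-genotype distribution by sex under Mendelian transmission with
obligate X-to-daughter / Y-to-son inheritance from the father, together
with the qualitative differentiation/diversity pattern the cross would
show in pooled data.
"""
from __future__ import annotations

from fractions import Fraction

from ..simulate.config import ConfigError, CrossConfig

GENOTYPES = ("RR", "RI", "II")


def predict_cross_inversion_pattern(cross: CrossConfig,
                                    inversions) -> dict:
    """Expected offspring genotype distribution per sex per inversion.

    Returns a mapping inversion name ->
    ``{"sons": {...}, "daughters": {...}, "pattern": (differentiation,
    diversity)}`` with exact (Fraction-free float) probabilities.
    """
    out = {}
    for inv in inversions:
        if inv.linkage == "Y":
            for spec in cross.mother_haplotypes:
                if spec.get(inv.name):
                    raise ConfigError(
                        f"mother cannot carry Y-linked inversion "
                        f"{inv.name}")
            if cross.father_haplotypes[cross.father_x_index()].get(inv.name):
                raise ConfigError(
                    f"father's X cannot carry Y-linked inversion "
                    f"{inv.name}")
        mat = [bool(spec.get(inv.name))
               for spec in cross.mother_haplotypes]
        pat_y = bool(
            cross.father_haplotypes[cross.father_y_index].get(inv.name))
        pat_x = bool(
            cross.father_haplotypes[cross.father_x_index()].get(inv.name))

        def dist(paternal):
            d = {g: Fraction(0) for g in GENOTYPES}
            for m in mat:
                d[GENOTYPES[int(m) + int(paternal)]] += Fraction(1, 2)
            return d

        sons = dist(pat_y)
        daughters = dist(pat_x)
        differentiated = sons != daughters
        male_div = sons["RI"] > 0
        female_div = daughters["RI"] > 0
        if male_div and female_div:
            diversity = "both-diverse"
        elif male_div:
            diversity = "male-diverse"
        elif female_div:
            diversity = "female-diverse"
        else:
            diversity = "neither"
        out[inv.name] = {
            "sons": {g: float(v) for g, v in sons.items()},
            "daughters": {g: float(v) for g, v in daughters.items()},
            "pattern": ("sex-differentiated" if differentiated
                        else "undifferentiated", diversity),
        }
    return out
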