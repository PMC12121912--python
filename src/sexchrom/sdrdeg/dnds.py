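"""Nei-Gojobori (1986) dN/dS between two codon-aligned sequences.

Synonymous/nonsynonymous site counts are computed per codon position
over the mutational neighborhood (mutations creating a stop codon are
excluded from the neighborhood, so every codon still contributes
exactly three sites).  Observed differences at multi-hit codons are
averaged over mutational pathways, skipping pathways that pass through
a stop codon unless all of them do.  Proportions are Jukes-Cantor
corrected; dN/dS is reported as missing when dS is zero or a proportion
reaches the correction's 3/4 divergence limit.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import log

from Bio.Data.CodonTable import standard_dna_table

_CODON_TO_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


@dataclass
class DnDsResult:
    n_sites: float        # nonsynonymous sites (N)
    s_sites: float        # synonymous sites (S)
    n_diffs: float        # observed nonsynonymous differences (Nd)
    s_diffs: float        # observed synonymous differences (Sd)
    dn: float
    ds: float
    ratio: float          # NaN when undefined

    def defined(self) -> bool:
        return self.ratio == self.ratio  # not NaN


def _codons(seq: str, label: str) -> list:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"{label}: length not divisible by 3")
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValueError(f"{label}: ambiguity codes not supported: {bad}")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons):
        if c in _STOPS:
            raise ValueError(
                f"{label}: stop codon {c} at codon {i} (strip terminal "
                "stops before calling)")
    return codons


def _site_counts(codon: str) -> tuple[float, float]:
    """(N, S) site contribution of one codon; N + S == 3."""
    aa = _CODON_TO_AA[codon]
    s_total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in _STOPS:
                continue
            valid += 1
            if _CODON_TO_AA[mut] == aa:
                syn += 1
        s_total += syn / valid if valid else 0.0
    return 3.0 - s_total, s_total


def _path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(Nd, Sd) for one codon pair, averaged over mutational pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    blocked = []
    for order in permutations(diff_pos):
        cur = c1
        nd = sd = 0
        ok = True
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS and nxt != c2:
                ok = False
            if nxt in _STOPS or cur in _STOPS:
                nd += 1  # change through/into a stop is nonsynonymous
            elif _CODON_TO_AA[cur] == _CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (results if ok else blocked).append((nd, sd))
    use = results or blocked
    nd = sum(r[0] for r in use) / len(use)
    sd = sum(r[1] for r in use) / len(use)
    return nd, sd


def _jukes_cantor(p: float) -> float:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return float("nan")
    return -0.75 * log(1 - 4 * p / 3)


def ng86_dnds(cds_a: str, cds_b: str) -> DnDsResult:
    """NG86 dN, dS and their ratio between two codon-aligned CDS.

    The inputs must be equal-length, gap-free and stop-free; the result
    is symmetric in its two arguments.  ``ratio`` is NaN when there are
    no synonymous substitutions (dS == 0) or a Jukes-Cantor correction
    is undefined.
    """
    ca = _codons(cds_a, "cds_a")
    cb = _codons(cds_b, "cds_b")
    if len(ca) != len(cb):
        raise ValueError("sequences must be codon-aligned to equal length")

    n_sites = s_sites = 0.0
    nd = sd = 0.0
    for c1, c2 in zip(ca, cb):
        n1, s1 = _site_counts(c1)
        n2, s2 = _site_counts(c2)
        n_sites += (n1 + n2) / 2
        s_sites += (s1 + s2) / 2
        dnd, dsd = _path_diffs(c1, c2)
        nd += dnd
        sd += dsd

    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    dn = _jukes_cantor(pn)
    ds = _jukes_cantor(ps)
    if dn != dn or ds != ds or ds == 0.0:
        ratio = float("nan")
    else:
        ratio = dn / ds
    return DnDsResult(n_sites, s_sites, nd, sd, dn, ds, ratio)
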