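"""Emit haplotype and reference sequences consistent with the truth.

The reference is a random sequence per chromosome (deterministic in the
seed).  Each haplotype substitutes its alternate alleles and then
reverse-complements any inversion segment it carries, so Y/W haplotypes
contain sex-specific k-mers at the SDR fixed differences by
construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig, TruthSidecar
from .population import KIND_LOF_Y, KIND_SDR

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMPLEMENT[_a] = _b


def _revcomp_bytes(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr[::-1]]


@dataclass
class SequenceSet:
    """Sequences for one chromosome region.

    ``references`` holds the X (plain reference) and Y (reference plus
    the sex-limited SDR alleles) sequences; ``haplotypes`` maps sample
    name to its two haplotype sequences.
    """

    chrom: str
    start: int
    end: int
    references: dict = field(default_factory=dict)
    haplotypes: dict = field(default_factory=dict)

    def by_sample(self) -> dict:
        return {s: list(pair) for s, pair in self.haplotypes.items()}

    def fasta_records(self):
        yield f"{self.chrom}|refX", self.references["X"]
        yield f"{self.chrom}|refY", self.references["Y"]
        for sample, (h0, h1) in self.haplotypes.items():
            yield f"{sample}|{self.chrom}|h0", h0
            yield f"{sample}|{self.chrom}|h1", h1


def _reference_bytes(cfg: SimConfig, chrom: str) -> np.ndarray:
    rng = np.random.default_rng([cfg.seed, 404,
                                 list(cfg.chrom_lengths).index(chrom)])
    return _BASE_BYTES[rng.integers(0, 4, size=cfg.chrom_lengths[chrom])]


def emit_sequences(truth: TruthSidecar, cfg: SimConfig, chrom: str,
                   start: int = 0, end: int | None = None,
                   samples=None) -> SequenceSet:
    """Build the reference X/Y and per-sample haplotype sequences for a
    region of one chromosome.

    Inversion segments are reverse-complemented *after* allele
    substitution; a region boundary cutting through a carried inversion
    is allowed (the emitted slice is taken in reference coordinates of
    the rearranged haplotype).
    """
    if chrom not in cfg.chrom_lengths:
        raise KeyError(f"unknown chromosome {chrom!r}")
    end = cfg.chrom_lengths[chrom] if end is None else end
    if not (0 <= start < end <= cfg.chrom_lengths[chrom]):
        raise ValueError("invalid region")
    if samples is None:
        samples = list(truth.sex)

    base = _reference_bytes(cfg, chrom)
    ss = truth.sites[chrom]
    alt_bytes = np.frombuffer(
        "".join(ss.alt).encode(), dtype=np.uint8)

    refx = base[start:end].tobytes().decode()
    y_mask = (ss.kind == KIND_SDR) | (ss.kind == KIND_LOF_Y)
    ref_y = base.copy()
    ref_y[ss.pos[y_mask]] = alt_bytes[y_mask]
    refy = ref_y[start:end].tobytes().decode()

    sample_index = {s: i for i, s in enumerate(truth.sex)}
    inv_on_chrom = [inv for inv in cfg.inversions if inv.chrom == chrom]
    haps = {}
    for sample in samples:
        si = sample_index[sample]
        pair = []
        for h in (0, 1):
            hap_alleles = truth.haplotypes[chrom][2 * si + h]
            seq = base.copy()
            carry = ss.pos[hap_alleles]
            seq[carry] = alt_bytes[hap_alleles]
            for inv in inv_on_chrom:
                if truth.hap_orientations[inv.name][2 * si + h]:
                    seq[inv.start:inv.end] = _revcomp_bytes(
                        seq[inv.start:inv.end])
            pair.append(seq[start:end].tobytes().decode())
        haps[sample] = tuple(pair)
    return SequenceSet(chrom=chrom, start=start, end=end,
                       references={"X": refx, "Y": refy},
                       haplotypes=haps)
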