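"""Sex-specific k-mer extraction and windowed match density.

K-mers are canonicalised (lexicographic minimum of a k-mer and its
reverse complement) and matched exactly.  The extraction is exact set
algebra over all substrings, vectorised through fixed-width byte views
so it stays fast at megabase scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCATGCA"):
    _COMPLEMENT[_a] = _b


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """All canonical k-mers of ``seq`` in position order, as |S{k}| bytes."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    if len(arr) < k:
        return np.empty(0, dtype=f"S{k}")
    fwd = np.ascontiguousarray(sliding_window_view(arr, k)).view(
        f"S{k}").ravel()
    rc_full = _COMPLEMENT[arr[::-1]]
    rc = np.ascontiguousarray(
        sliding_window_view(rc_full, k)[::-1]).view(f"S{k}").ravel()
    return np.where(fwd <= rc, fwd, rc)


@dataclass
class KmerSet:
    """A deduplicated set of canonical k-mers with its thresholds."""

    k: int
    kmers: np.ndarray  # sorted S{k} byte strings
    min_presence: float = 0.9
    max_contam: float = 0.0

    def __len__(self):
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        if len(kmer) != self.k or len(self.kmers) == 0:
            return False
        key = canonical_kmers(kmer, self.k)[0]
        i = np.searchsorted(self.kmers, key)
        return bool(i < len(self.kmers) and self.kmers[i] == key)

    def to_text(self) -> list:
        return [k.decode() for k in self.kmers]

    @classmethod
    def from_text(cls, k: int, lines) -> "KmerSet":
        arr = np.array(sorted({ln.strip() for ln in lines if ln.strip()}),
                       dtype=f"S{k}")
        return cls(k=k, kmers=arr)


def _sample_kmer_sets(sample_seqs: dict, k: int) -> dict:
    out = {}
    for sample, seqs in sample_seqs.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        shortest = min(len(s) for s in seqs)
        if k > shortest:
            raise ValueError(
                f"k={k} exceeds shortest sequence ({shortest} bp) of "
                f"sample {sample}")
        parts = [canonical_kmers(s, k) for s in seqs]
        out[sample] = np.unique(np.concatenate(parts))
    return out


def sex_specific_kmers(male_seqs: dict, female_seqs: dict, k: int = 40,
                       min_presence: float = 0.9,
                       max_contam: float = 0.0) -> KmerSet:
    """Canonical k-mers present in at least ``min_presence`` of male
    samples and at most ``max_contam`` of female samples.

    ``male_seqs``/``female_seqs`` map sample name to one sequence or a
    list of (haplotype) sequences.
    """
    if not male_seqs or not female_seqs:
        raise ValueError("need at least one sample per sex")
    male_sets = _sample_kmer_sets(male_seqs, k)
    female_sets = _sample_kmer_sets(female_seqs, k)

    male_union, male_counts = np.unique(
        np.concatenate(list(male_sets.values())), return_counts=True)
    keep = male_counts / len(male_sets) >= min_presence
    candidates = male_union[keep]
    if len(candidates) == 0:
        return KmerSet(k, candidates, min_presence, max_contam)

    female_union, female_counts = np.unique(
        np.concatenate(list(female_sets.values())), return_counts=True)
    idx = np.searchsorted(female_union, candidates)
    idx = np.clip(idx, 0, max(len(female_union) - 1, 0))
    present = (len(female_union) > 0) & (female_union[idx] == candidates)
    contam = np.where(present, female_counts[idx], 0) / len(female_sets)
    return KmerSet(k, candidates[contam <= max_contam],
                   min_presence, max_contam)


def kmer_density(kmers: KmerSet, seq: str, windows, chrom: str,
                 offset: int = 0):
    """Count k-mer match start positions per window of ``chrom``.

    ``seq`` covers reference coordinates [offset, offset + len(seq)) of
    the chromosome; windows with no overlap of the covered region simply
    count zero.  Returns a (chrom, start, end, count) frame on the
    window grid.
    """
    import pandas as pd

    cano = canonical_kmers(seq, kmers.k)
    if len(cano) and len(kmers):
        hits = np.flatnonzero(np.isin(cano, kmers.kmers)) + offset
    else:
        hits = np.empty(0, dtype=np.int64)
    starts = windows.starts(chrom)
    rows = []
    for s in starts:
        end = int(min(s + windows.size, windows.chrom_lengths[chrom]))
        n = int(((hits >= s) & (hits < end)).sum())
        rows.append((chrom, int(s), end, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
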