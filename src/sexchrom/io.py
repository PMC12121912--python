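"""Readers and writers for the external interfaces.

Formats: VCF v4.2 (biallelic SNPs, GT field), sample/pedigree TSV,
FASTA, BED, bedgraph-style track TSV (0-based half-open), sync-style
pool counts, long-format barcode maps, truth sidecars and YAML/JSON
configs.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenotypeMatrix, PoolCounts
from .simulate.config import SimConfig, TruthSidecar

_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
_GT_VALUES = {"./.": -1, ".|.": -1, ".": -1,
              "0/0": 0, "0|0": 0,
              "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
              "1/1": 2, "1|1": 2}


# ---------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------
def write_vcf(gm: GenotypeMatrix, path, chrom_lengths=None):
    """Write a minimal VCF v4.2 with GT-only diploid genotypes
    (0-based internal positions become 1-based POS)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for i in range(gm.n_sites):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.gt[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i] + 1}\t.\t{gm.ref[i]}\t"
                     f"{gm.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF back into a genotype matrix.

    An empty VCF yields an empty matrix (a warning is left to the
    caller, see :func:`load_inputs`).
    """
    from cyvcf2 import VCF

    reader = VCF(str(path))
    samples = list(reader.samples)
    # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
    type_map = np.array([0, 1, -1, 2], dtype=np.int8)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for var in reader:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise ValueError(
                f"non-biallelic-SNP record at {var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(type_map[var.gt_types])
    reader.close()
    gt = (np.asarray(rows, dtype=np.int8) if rows
          else np.empty((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix(np.asarray(chroms, dtype=object),
                          np.asarray(poss, dtype=np.int64),
                          np.asarray(refs, dtype=object),
                          np.asarray(alts, dtype=object),
                          gt, samples)


# ---------------------------------------------------------------------
# tables and tracks
# ---------------------------------------------------------------------
def write_table(frame: pd.DataFrame, path):
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_track(track: pd.DataFrame, path):
    """Bedgraph-style TSV: chrom, start, end, value columns."""
    write_table(track, path)


def read_track(path) -> pd.DataFrame:
    return read_table(path)


def write_bed(intervals, path):
    with Path(path).open("w") as fh:
        for item in intervals:
            fh.write("\t".join(str(x) for x in item) + "\n")


def read_bed(path) -> pd.DataFrame:
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            rows.append((parts[0], int(parts[1]), int(parts[2]),
                         parts[3] if len(parts) > 3 else ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------
def write_fasta(records: dict, path):
    """``records`` maps name -> sequence string."""
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="")
         for name, seq in records.items()),
        str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------
# pools (sync-style)
# ---------------------------------------------------------------------
_BASE_ORDER = "ATCG"


def write_pools(pools, path):
    """Sync-style TSV: chrom, pos(1-based), ref, alt, then one A:T:C:G
    read-count column per pool."""
    pools = list(pools)
    first = pools[0]
    with Path(path).open("w") as fh:
        fh.write("chrom\tpos\tref\talt\t"
                 + "\t".join(p.label for p in pools) + "\n")
        for i in range(len(first.pos)):
            cols = []
            for p in pools:
                counts = {b: 0 for b in _BASE_ORDER}
                counts[str(p.ref[i])] += int(p.ref_reads[i])
                counts[str(p.alt[i])] += int(p.alt_reads[i])
                cols.append(":".join(str(counts[b]) for b in _BASE_ORDER))
            fh.write(f"{first.chrom[i]}\t{first.pos[i] + 1}\t{first.ref[i]}"
                     f"\t{first.alt[i]}\t" + "\t".join(cols) + "\n")


def read_pools(path) -> list:
    frame = pd.read_csv(path, sep="\t")
    labels = list(frame.columns[4:])
    out = []
    for label in labels:
        parts = frame[label].str.split(":", expand=True).astype(int)
        parts.columns = list(_BASE_ORDER)
        ref_reads = np.array([parts.at[i, frame.ref[i]]
                              for i in range(len(frame))])
        alt_reads = np.array([parts.at[i, frame.alt[i]]
                              for i in range(len(frame))])
        out.append(PoolCounts(
            chrom=frame.chrom.to_numpy(dtype=object),
            pos=frame.pos.to_numpy() - 1,
            ref=frame.ref.to_numpy(dtype=object),
            alt=frame.alt.to_numpy(dtype=object),
            ref_reads=ref_reads, alt_reads=alt_reads, label=label))
    return out


# ---------------------------------------------------------------------
# truth sidecar and configs
# ---------------------------------------------------------------------
def write_truth(truth: TruthSidecar, path):
    payload = {
        "sex": truth.sex,
        "inversion_genotypes": truth.inversion_genotypes,
        "sdr": list(truth.sdr) if truth.sdr else None,
        "y_deleted_genes": truth.y_deleted_genes,
        "lof_variants": (truth.lof_variants.to_dict(orient="records")
                         if truth.lof_variants is not None else []),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> TruthSidecar:
    payload = json.loads(Path(path).read_text())
    return TruthSidecar(
        sex=payload["sex"],
        inversion_genotypes=payload["inversion_genotypes"],
        sdr=tuple(payload["sdr"]) if payload.get("sdr") else None,
        y_deleted_genes=payload.get("y_deleted_genes", []),
        lof_variants=pd.DataFrame(payload.get("lof_variants", []),
                                  columns=["chrom", "pos", "origin"]),
    )


def write_sim_config(cfg: SimConfig, path):
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def read_sim_config(path) -> SimConfig:
    return SimConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------
# cross-file validation
# ---------------------------------------------------------------------
def load_inputs(vcf_path, sample_table_path, tracks=None) -> dict:
    """Load and cross-validate the primary inputs.

    Every VCF sample must appear in the sample table (offenders are
    named); chromosome names must be consistent across supplied tracks.
    An empty VCF yields an empty dataset with a warning flag rather than
    an error.
    """
    gm = read_vcf(vcf_path)
    table = read_table(sample_table_path)
    required = {"sample", "sex", "population"} - set(table.columns)
    if required:
        raise ValueError(f"sample table lacks columns {sorted(required)}")
    known = set(table["sample"])
    offenders = [s for s in gm.samples if s not in known]
    if offenders:
        raise ValueError(
            f"VCF samples missing from sample table: {offenders}")
    dataset = {"genotypes": gm, "sample_table": table, "warnings": []}
    if gm.n_sites == 0:
        dataset["warnings"].append("VCF contains no variant records")
    chroms = set(gm.chrom)
    for name, frame in (tracks or {}).items():
        extra = set(frame["chrom"]) - chroms if chroms else set()
        if chroms and extra:
            raise ValueError(
                f"track {name!r} names chromosomes absent from the VCF: "
                f"{sorted(extra)}")
        dataset[name] = frame
    return dataset
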