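# sexchrom

Sex-chromosome inference from male/female sequencing contrasts, as a
tested, reusable pipeline:

* **Synthetic cohorts** (`sexchrom.simulate`): seeded diploid wild
  cohorts with an XY (or ZW) sex-determination region (SDR), polymorphic
  X-linked / Y-linked / autosomal inversions, molecule-level linked-read
  barcode maps, single-pair crosses with sexed Pool-seq pools, depth
  tracks, loss-of-function annotations and haplotype sequences — all
  with truth sidecars, so every downstream stage is testable offline.
* **Windowed statistics** (`sexchrom.popgen`): male–female Fst
  (Weir–Cockerham and Hudson forms, ratio-of-sums over 20 kb / 10 kb
  sliding windows), per-sex nucleotide diversity, pooled (Nei-form) Fst,
  SNP density, normalized male:female depth ratios, and the four-rule
  variant QC filter (sample coverage ≥ 6×; site depth in [4×, 40×];
  missingness ≤ 0.2; MAF ≥ 0.05).
* **Heterogamety** (`sexchrom.heterogamety`): per-chromosome XY / ZW /
  none verdicts from elevated Fst intersected with a per-sex diversity
  excess, plus rule-based classification of cross markers by sex-linked
  segregation pattern and a genotype-by-sex chi-square test.
* **Inversion scan** (`sexchrom.invscan`): shared-barcode counts per
  window pair, a distance-binned robust null, candidate detection from
  distal excess sharing (z ≥ 5), breakpoint localization from the
  junction corner structure, density/junction genotyping into
  RR / RI / II, linkage classification (X-linked / Y-linked /
  autosomal), and deterministic cross-segregation predictions.
* **SDR and degeneration** (`sexchrom.sdrdeg`): sex-specific 40 bp
  canonical k-mers and their windowed density, SDR delineation by
  three-channel evidence intersection, depth-ratio degeneration flags
  (< 0.75), fixed-LoF rules (female AF > 0.9 / male AF > 0.45), and
  NG86 dN/dS with Jukes–Cantor correction for X–Y gene pairs.
* **Pipeline + CLI** (`sexchrom.pipeline`, `sexchrom.cli`): bundled
  `ct`/`ns`/`autosomal` presets chained end to end with deterministic,
  config-hash-stamped outputs.

## CLI

```sh
sexchrom all --preset ct --seed 1 --out results/ct       # full pipeline
sexchrom simulate --preset ns --seed 2 --out sim/        # artifacts only
sexchrom windows --vcf sim/cohort.vcf --samples sim/samples.tsv \
    --out tracks.tsv
sexchrom heterogamety --tracks tracks.tsv --out verdicts.json
sexchrom invscan --vcf sim/cohort.vcf --samples sim/samples.tsv \
    --molecules sim/molecules.tsv --out inversions.json
```

Every stage is also importable directly; see the module docstrings.

## Formats

VCF v4.2 (biallelic SNPs, GT), sample table TSV (`sample`, `sex`,
`population`), bedgraph-style track TSV (0-based half-open), long-format
barcode maps (`sample`, `chrom`, `window_start`, `barcode`), molecule
segment TSV, sync-style pool counts, FASTA, and YAML configs. All
internal coordinates are 0-based half-open; VCF emission converts to
1-based.
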