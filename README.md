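# bsamap

A bulked-segregant mapping toolkit for dominant single-locus traits,
built around a seeded synthetic-data generator. It covers the full
desk-scale workflow:

- **`bsamap.synthio`** — simulate an F2 cross segregating a single dominant
  locus (interference-free Haldane crossovers), pooled read depths for two
  phenotype bulks, fine-mapping marker tables, a germplasm panel genotyped
  at a diagnostic SNP, and the promoter-haplotype sequence fixtures used by
  the CAPS assay.
- **`bsamap.variantio`** — two-pool variant tables as VCF or TSV, with the
  retention filters (per-pool depth >= 20, MQ >= 20, BQ >= 20, inclusive).
- **`bsamap.bsa`** — per-SNP indices and delta(SNP-index), Monte-Carlo
  simulation of the no-QTL null to get depth-matched 95%/99% envelopes,
  sliding-window averaging (400 kb window / 200 kb step by default), and
  merged significant regions written as BED.
- **`bsamap.capsmarker`** — IUPAC-aware restriction-site scanning,
  in-silico digestion, CAPS assay design that separates two SNP alleles by
  band pattern, genotype calling from observed bands, and small CDS/protein
  length arithmetic. A small enzyme table (SspI and common 6-cutters) is
  bundled and user-extensible.
- **`bsamap.genmap`** — chi-square segregation tests, recombinant screening
  between flanking markers, and dominance-aware candidate-interval
  delimitation from recombinant genotypes.
- **`bsamap.assoc`** — D/H/R genotype-frequency summaries, carrier (D or H)
  vs non-carrier 2x2 tables, and a log-space Fisher's exact test that stays
  accurate at P ~ 1e-20.
- **`bsamap.cli`** — `bsamap` command-line front end.

## Command line

All subcommands accept `--seed` (a single global seed fanned out to
per-stage seeds) and write a `run.json` provenance record. Configs are
YAML/JSON; unknown keys are rejected. Outputs are plain TSV/VCF/BED/JSON.

```sh
# end to end: simulate an F2 + bulks, filter, scan, call regions
bsamap pipeline --seed 1 --out runs/demo

# individual stages
bsamap simulate-f2 --seed 1 --out runs/sim
bsamap bsa --variants runs/sim/variants.vcf --seed 1 --out runs/scan --plot
bsamap simulate-panel --seed 1 --out runs/panel
bsamap associate --panel runs/panel/panel.tsv --out runs/assoc.json
bsamap finemap --table markers.tsv --out interval.json
bsamap caps design --fasta alleles.fasta --out assay.json
bsamap caps call --assay assay.json --bands 152,239,391
```

Identical config + seed reproduces byte-identical outputs.

## File formats

- Variant TSV columns: `chrom pos ref alt ad_ref_p1 ad_alt_p1 ad_ref_p2
  ad_alt_p2 mq bq`; VCF carries per-pool `AD`/`DP` and site-level `MQ`/`BQ`
  INFO tags.
- Marker tables are TSV with `id`, `phenotype`, then one column per marker
  headed `name@position`.
- Panels are TSV with `accession`, `phenotype`, `genotype` (D/H/R).
- Significant regions are BED (0-based half-open) with the significance
  level (`p05`/`p01`) in the name column.
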