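# omicsmr

Summary-data Mendelian randomization (SMR) toolkit for integrating mQTL,
eQTL and GWAS summary statistics. It implements:

- the **SMR ratio test** (b_xy = b_zy/b_zx with the closed-form
  Delta-method Wald statistic) using the top cis-QTL as instrument;
- the **HEIDI heterogeneity test** that separates a single shared causal
  variant (pleiotropy) from distinct LD-linked variants (linkage) by
  comparing ratio estimates across LD-linked SNPs;
- a **multi-SNP SMR set test** combining all significant cis SNPs, with
  p-values for weighted chi-square mixtures via Kuonen's saddlepoint
  approximation (Satterthwaite fallback);
- the **three-step integration pipeline**: methylome→transcriptome (M2T and
  the reverse T2M), DNAm→trait and transcript→trait scans, realized-count
  Bonferroni thresholds, and DNAm–gene–trait triplet combination, plus
  descriptive statistics (nearest-gene proportions, within-gene effect
  direction concordance, explained-variance comparison);
- a **chromatin-state enrichment test** with variance-matched resampling of
  control probes;
- a **simulator** generating coupled genotype/DNAm/expression/trait data
  under mediation, pleiotropy, linkage and null models, observed through
  three independent samples, emitting exactly the file formats the rest of
  the package consumes.

## Input formats

- GWAS summary statistics: GCTA-COJO `.ma` text (`SNP A1 A2 freq b se p N`).
- cis-QTL summaries: tab-delimited flat format with header
  `ProbeID SNP Chr BP A1 A2 freq b se p N` (gzip accepted).
- LD reference panel: PLINK bed/bim/fam (SNP-major v1.00).
- Probe annotations: tab-delimited `ProbeID Kind Chr BP Gene Strand`.
- Chromatin states: BED (0-based half-open, label in column 4) plus a
  two-column raw-state → category collapse map.

## Command line

```sh
omicsmr simulate --fixture --out fx --seed 7      # golden multi-block fixture
omicsmr simulate --model pleiotropy --out sim     # one simulated study set

omicsmr smr --exposure fx/mqtl.flat.txt --annotations fx/probes.txt \
    --outcome fx/gwas.ma --bfile fx/panel --out out_smr

cat > cfg.yaml <<EOF
mqtl: fx/mqtl.flat.txt
eqtl: fx/eqtl.flat.txt
gwas: fx/gwas.ma
annotations: fx/probes.txt
bfile: fx/panel
EOF
omicsmr pipeline --config cfg.yaml --out out_pipe --seed 1

omicsmr enrich --targets targets.txt --universe universe.tsv \
    --annotations fx/probes.txt --bed fx/states.bed \
    --collapse-map fx/collapse_map.txt --out out_enrich --seed 1
```

Every command writes a `manifest.json` (resolved config, input checksums,
seed, per-stage row counts) beside its outputs and is deterministic given
(inputs, config, seed).

## Library layout

| module                 | contents                                             |
|------------------------|------------------------------------------------------|
| `omicsmr.summary_io`   | readers/writers, harmonization, meta-analysis, QC filters, z→beta conversion |
| `omicsmr.ldpanel`      | PLINK codec, LD correlation matrices                 |
| `omicsmr.smr`          | SMR, HEIDI, SMR-multi, saddlepoint quadratic forms   |
| `omicsmr.pipeline`     | M2T/T2M/trait scans, triplets, descriptive stats     |
| `omicsmr.enrichment`   | state annotation, variance-matched enrichment        |
| `omicsmr.simulate`     | generating models, summary-statistic emission, fixtures |
| `omicsmr.cli`          | `omicsmr` command group                              |
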