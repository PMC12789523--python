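# ervtrace

Pedigree-aware analysis of endogenous retrovirus (ERV) dynamics in a host
genome, built around koala retrovirus (KoRV)-style data:

- **`ervtrace.simulate`** — synthetic cohort generator: reference contigs,
  viral references, multi-generation pedigrees with Mendelian ERV
  transmission and Poisson de novo integrations, short-read alignment
  records (SAM), long-read iPCR junction reads, trio SNV calls and
  phenotypes, all with exact truth tables.
- **`ervtrace.discovery`** — integration-site discovery from anchored-mate
  and soft-clip (>20 bp) evidence, single-linkage clustering (≥20 reads,
  500 bp gap for KoRV / 9 kb otherwise), modal-terminus breakpoints and a
  cross-individual shared-site registry.
- **`ervtrace.zygosity`** — read-ratio genotyping (soft-clipped vs crossing
  reads, inclusive 30–70% het window, ±10 bp TSD margin), population
  genotype matrix, AAF / undetermined-fraction / Mendelian-error QC, and
  the exact binomial heterozygote-miss model.
- **`ervtrace.dynamics`** — triad-based de novo integration detection
  (joey coverage ≥40), F2 validation (≥10 reads), per-generation
  integration rates, eliminated-integration reports and elimination rates.
- **`ervtrace.dating`** — trio de novo SNV filtering (DP≥20, GQ≥20,
  AB≥0.4), per-generation / per-year germline mutation rates, LTR
  p-distance and molecular-clock colonization dating.
- **`ervtrace.longread`** — inverse-PCR long-read integration calling:
  viral-segment excision, flank filtering (>50 bp, ≥90% identity,
  mapq≥30), breakpoint peaks (>10 reads), TSD/masked-gap pairing (≤10 bp /
  ≤1,411 bp) and endogenous-vs-somatic classification (≥500 reads).
- **`ervtrace.association`** — additive logistic/linear association with
  Wald tests, ΔAIC covariate selection, Bonferroni and suggestive
  thresholds, odds-ratio-weighted genetic risk scores with bootstrap
  accuracy (100× 75/25 splits) and cutoff selection.
- **`ervtrace.io` / `ervtrace.pipeline` / `ervtrace.cli`** — pedigree TSV,
  BED, FASTA, sites VCF (symbolic `<INS:ME:*>` alleles) and SAM readers and
  writers, plus the end-to-end pipeline with a run manifest.

Internal coordinates are 0-based half-open; VCF/SAM conversion happens at
the I/O boundary.

## CLI

```sh
ervtrace run-all --out out/ --seed 1            # simulate -> ... -> risk score
ervtrace simulate --out sim/ --seed 1           # cohort + SAM/VCF/BED/TSV truth
ervtrace discover --virus-sam v.sam --host-sam h.sam --known-erv k.bed --out sites.tsv
ervtrace genotype --sites sites.vcf --genome-sam SB0001=g.sam --out matrix.tsv
ervtrace pedigree-dynamics --matrix m.tsv --coverage c.tsv --ped ped.tsv --out rep
ervtrace mutation-rate --vcf trio.vcf --sire S --dam D --joey J --haploid-length 3234982288
ervtrace date-colonization --ltr5 l5.fa --ltr3 l3.fa --rate 1.6e-9
ervtrace longread-discover --reads r.fa --virus v.fa --host h.fa --out calls.tsv
ervtrace associate --genotypes m.tsv --phenotypes p.tsv --trait case --out assoc.tsv
ervtrace risk-score --weights assoc.tsv --genotypes m.tsv --out grs.tsv
```

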