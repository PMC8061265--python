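# cceamp

Detection, quantification and monitoring of a carboxylesterase (CCE)
gene-cluster amplification that confers organophosphate resistance in the
mosquito *Aedes aegypti*.

Resistant mosquitoes carry a tandem genomic amplification of ~100 kb on
chromosome 2 spanning five CCE genes, including AAEL023844 (formerly
*CCEAE3A*), whose over-expression sequesters and degrades organophosphate
insecticides. Tracking this amplification in field populations requires
estimating per-gene copy number in single mosquitoes, classifying
structural haplotypes, and summarizing their frequencies — plus the
sequencing-side analyses that characterize the locus in the first place.
`cceamp` implements that full chain for researchers running resistance
surveillance or re-analysing pool-seq/RNA-seq data:

* **qPCR relative quantification** (`cceamp.qpcr`) — amplification
  efficiency `E = 10^(-1/slope)` from dilution series, and the
  efficiency-corrected ΔΔCt (Pfaffl) fold
  `E_t^{ΔCq_t} / E_r^{ΔCq_r}` with `ΔCq = Cq(calibrator) − Cq(sample)`,
  geometric-mean combined over multiple single-copy reference genes.
  Includes dual-color TaqMan duplex wells (FAM target / HEX control) and
  Cq calling from raw traces.
* **ddPCR quantification** (`cceamp.ddpcr`) — Poisson zero-class estimate
  `λ = −ln(n_neg / n_total)` per ~20,000-droplet well, CNV as the ratio of
  target/control concentration ratios versus a calibrator, and Pearson
  concordance between platforms on log2 folds.
* **Positivity and haplotype calling** (`cceamp.haplotypes`) — an
  individual is positive at CNV ≥ 2.5-fold; haplotype A amplifies
  AAEL019678 + AAEL023844 + AAEL005113 (*CCEAE1A*), haplotype B lacks
  *CCEAE1A*; population prevalence and haplotype-frequency summaries.
* **Amplification mapping** (`cceamp.coverage`) — windowed case/control
  depth tracks normalized by a baseline chromosome, repeat masking where
  control coverage collapses, and maximal-run segment calling with
  mask-gap bridging.
* **RNA-seq candidate filter** (`cceamp.rnaseq`) — median-of-ratios
  normalization, expression floor ≥ 0.5, one-way ANOVA + Tukey HSD on
  log2 values with Benjamini–Hochberg correction, and the candidate rule
  FC ≥ 3 versus *both* susceptible comparator lines at corrected
  p ≤ 0.001.
* **Synthetic data** (`cceamp.simulate`) — seeded generators and named
  presets encoding the characterized effect sizes (32-fold pooled CNV,
  ~80 copies in one individual, ~50-fold coverage over ~100 kb, seven
  over-expressed detoxification genes), so every stage is testable without
  sequencing downloads.

## Worked example

Simulate the pooled-qPCR preset (7 pools of 5 females from a
malathion-selected line, duplicate reactions, three calibrator samples of
the susceptible line), quantify, then genotype:

```bash
cceamp simulate g5mala_pool --out sim
cceamp qpcr --cq sim/cq_table.tsv \
    --calibrator BORA1,BORA2,BORA3 \
    --targets AAEL019678,AAEL023844,AAEL005113 \
    --references AAEL007808,AAEL005950 \
    --out folds.tsv
head -3 folds.tsv
```

```
sample_id  gene_id     fold                n_replicates  cv
POOL1      AAEL019678  27.935608358429597  2             0.021318999486928274
POOL1      AAEL023844  30.00539464765625   2             0.0562860818579008
```

Each row is one pool × gene: `fold` is genomic copy number relative to the
susceptible calibrator line (here ~28–30× for the two core cluster genes,
whose generating truth is 32×; single-run qPCR noise at σ(Cq) = 0.15 gives
~10% scatter), `cv` the replicate-level coefficient of variation.

Map the amplified segment from pool-seq depth tracks:

```bash
cceamp simulate nakh_like --out simdepth
cceamp scan --case simdepth/case.bedgraph --control simdepth/control.bedgraph \
    --baseline-contig chr1 --out regions.bed
cat regions.bed
```

```
#contig  start   end     name  fold    n_windows
chr2     450000  550000  amp1  48.732  94
```

One amplified region: 100 kb at a median 48.7-fold case/control coverage
ratio across 94 unmasked 1-kb windows (planted truth: 100 kb at 50-fold;
6 repeat-masked windows were bridged inside the call).

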