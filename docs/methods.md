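# Methods

## Relative quantification by qPCR

Copy number is estimated by efficiency-corrected ΔΔCt (Pfaffl). For a
target gene t and reference gene r,

    fold = E_t^{ΔCq_t} / E_r^{ΔCq_r},   ΔCq = Cq(calibrator) − Cq(sample),

where E is the per-gene amplification efficiency (fold of template per
cycle) fitted as `E = 10^(−1/slope)` from the least-squares regression of
Cq on log10 dilution (≥ 3 distinct levels required; a non-negative slope
is rejected as an inverted series). Efficiencies must lie in (1.0, 2.2] —
the upper bound tolerates mildly >100% apparent efficiency from pipetting
and inhibitor artifacts; anything outside indicates a failed assay. When
no standard curve is available the module assumes perfect doubling
(E = 2.0) and logs it prominently.

Technical replicates are averaged on the Cq scale (arithmetic mean),
which corresponds to a geometric mean of template quantities — the
standard treatment because Cq noise is approximately additive. Folds
against the two single-copy reference genes (AAEL007808, AAEL005950) are
combined by geometric mean, the usual multi-reference normalization; it
is permutation-invariant and homogeneous, and on noiseless input the
pipeline reproduces generating truths to machine precision. The
calibrator Cq per gene is the mean over the run's calibrator samples, so
every run must carry calibrators.

Undetermined target Cq in a non-calibrator sample is reported as fold 0
with a `no-target-amplification` flag rather than an error: biologically
it is a negative well. A sample lacking every reference gene cannot be
normalized and is skipped with a logged warning. For TaqMan duplex wells
the same formula applies with FAM as target and HEX as control; an
undetermined HEX is a failed reaction (error), since the single-copy
control must always amplify.

Cq calling from raw traces subtracts the mean of a baseline window
(cycles 3–15 by default), sets the default threshold at 10 baseline
standard deviations, and interpolates the first upward crossing linearly
between cycles. A threshold at or below the baseline noise level is
rejected.

## ddPCR

With the template split over ~20,000 droplets, the negative fraction
estimates the Poisson zero class, so `λ = −ln(n_neg / n_total)` copies
per droplet. Saturated wells (no negatives) are unquantifiable and raise
an error. The 95% CI is a Wilson score interval on the negative fraction
transformed through −ln; Wilson behaves well near the boundaries and the
transform preserves coverage because −ln is monotone. CNV is the
target/control ratio of λ in the sample divided by the same ratio in the
calibrator; droplet volume and template mass cancel, so no absolute
copies/µl are reported. Cross-platform concordance uses Pearson r on
log2 folds: copy numbers span 3–80 and a raw-scale correlation would be
dominated by the few highest values.

## Positivity and structural haplotypes

An individual is positive when any assayed cluster gene reaches 2.5-fold
(inclusive) versus the calibrator — a margin above the <2-fold technical
scatter of single-mosquito qPCR, chosen to avoid false positives.
Haplotype A requires all three cluster genes at or above threshold,
haplotype B the two 3' genes with *CCEAE1A* below. Positive patterns
matching neither rule are reported as "other" rather than forced into
A/B, since single-gene elevations plausibly reflect additional structural
haplotypes. Partial profiles (a gene failed) are still called for
positivity from the measured genes, with the haplotype downgraded to
"other" and flagged. Summaries report haplotype frequencies both as a
percentage of all genotyped individuals and as a share among positives,
because both framings are in routine use; proportions are kept at full
precision in machine output and rounded only for display.

## Coverage-ratio amplification mapping

Case (resistant) and control (susceptible) pool-seq depth tracks are
windowed (default 1 kb — a 100-kb segment then resolves at 1%
granularity), each normalized by the unweighted mean window depth of a
baseline contig unaffected by the amplification (a chromosome-1
surrogate), making the analysis invariant to library size. The per-window
case/control ratio estimates relative copy number. Control windows below
a normalized depth of 0.25 (inclusive floor: 0.25 itself is kept) are
masked: in this genome they mark repeated elements and unresolved
assembly where ratios are meaningless.

Amplified regions are maximal runs of unmasked windows with ratio ≥ 5,
bridging up to 10 consecutive masked windows; an unmasked sub-threshold
window always terminates a run. Runs with fewer than 5 qualifying windows
are discarded, boundaries are trimmed to qualifying windows, and the
region fold is the median ratio of its unmasked members — robust to
residual repeat windows. The fold floor of 5 sits far below the ~50-fold
signal of interest yet above the ≤1.5-fold shifts that heterozygous
duplications produce in pooled data. The caller is deterministic and was
verified equivalent to an exhaustive run-enumeration oracle on randomized
tracks. Coordinates are 0-based half-open throughout, matching
BED/BedGraph; gene overlap requires ≥ 1 bp under that convention.

## RNA-seq candidate filter

Counts are normalized with median-of-ratios size factors (computed over
genes with nonzero counts in all samples, rescaled to geometric mean 1).
Genes must reach normalized expression ≥ 0.5 in every replicate of every
line to be tested. Each gene is then tested by one-way ANOVA across the
three lines followed by Tukey HSD comparisons of the focal
(insecticide-selected) line against each susceptible comparator, computed
on log2(normalized + 1) — the log stabilizes variance toward the
homoscedasticity ANOVA assumes, and the pseudocount keeps zeros finite.
Benjamini–Hochberg correction is applied across genes separately within
each pairwise comparison (default); the alternative ordering — BH on the
ANOVA p, Tukey p left raw — is available as `correction="anova-first"`.
Candidates must show fold change ≥ 3 (linear group means, inclusive, in
either direction but with consistent sign) versus both comparators with
corrected p ≤ 0.001 in both. Requiring both comparators screens out genes
that merely drifted in one susceptible background. Zero-variance genes
get p = 1 when group means agree and the smallest representable p with an
`exact-separation` flag otherwise.

Tukey p-values come from scipy's studentized-range distribution, but its
`sf` costs milliseconds per value; p-values are therefore evaluated
through a monotone PCHIP interpolant of log sf built once per
(groups, df) from 600 exact scipy evaluations on q ∈ [1e-4, 80].
Interpolation error is below 1e-4 relative — negligible against any
decision threshold — and the unit tests cross-check the whole pipeline
against per-gene `scipy.stats.tukey_hsd`.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (spec, seed), bit-identical on rerun.

* **qPCR**: `Cq = baseline_cq − log(truth)/log(E) + N(0, σ)` per
  replicate. Pooled-assay presets use σ(Cq) = 0.15 cycles (duplicate
  wells), the single-mosquito preset 0.2 — typical SYBR single-plex
  scatter. Baseline Cq is 24 at 0.5 ng/µl template.
* **ddPCR**: positives ~ Binomial(n_droplets, 1 − e^(−λ)) at the default
  20,000 droplets.
* **Pool-seq depth**: Poisson per-window counts (pooled libraries at 1-kb
  windows are near-Poisson, and Poisson keeps the recovery oracle
  analytic); the planted segment multiplies the case mean; masked
  segments collapse both libraries to 5% of the mean, emulating
  repeat-associated gaps.
* **RNA-seq**: negative-binomial counts, log-normal baseline means
  (ln-mean 3, ln-sd 2, so a realistic minority of genes fall below the
  expression floor), per-sample depth factors log-uniform in [0.7, 1.4].
* **Populations**: haplotype drawn per individual at the set (f_A, f_B);
  amplified individuals draw one copy number log-uniformly over 3–80 —
  reflecting the wide observed range without assuming a mode — shared
  across the genes their haplotype spans, because a tandem amplification
  multiplies the whole segment; all folds then get multiplicative
  log-normal measurement noise (CV 0.25).

Preset effect sizes pin the characterized values: `g5mala_pool` (7 pools,
truths 32/32/8), `high_copy_individual` (one mosquito at 80 copies),
`nakh_like` (1-Mb contig, mean depth 40, one 100-kb segment at 50-fold
with two 3-kb internal masks), `mala_transcriptome` (12,000 genes,
3 lines × 4 libraries; five cluster CCEs at 10-fold, one GST at 13-fold,
one P450 at 8-fold in the focal line, plus 20 decoys elevated versus only
one comparator). The transcriptome preset uses NB dispersion 0.01 with
planted baselines ≥ 2,000 counts: each library pools 25 females, which
averages out individual biological variability, and the planted
detoxification transcripts are abundantly expressed even in susceptible
lines. Null-behaviour simulations (no planted genes) use the harsher
single-condition dispersion of 0.1.

What passing these tests shows — and does not. The generators reproduce
the *statistical* structure each stage assumes (Gaussian cycle noise,
Poisson occupancy, Poisson depth, NB counts), so recovery tests validate
the estimators and decision rules under their stated models. They do not
emulate inhibitor-distorted amplification curves, droplet rain, GC- or
mappability-dependent coverage waves, batch effects, or genuinely
correlated gene expression; performance on real data depends additionally
on those artifacts being handled upstream (trace QC, droplet gating,
alignment filtering).

## Numerical and design choices

* Positivity threshold comparisons are inclusive (≥ 2.5), as are the
  expression floor (≥ 0.5), the FC cutoff (≥ 3) and the window-ratio
  floor for region calling.
* Problem sizes: the acceptance script averages the two qPCR presets over
  10 generator seeds (their single-run scatter is ~10–20%) and scans one
  1-Mb / 1-kb-window contig; together a few seconds on one CPU.
* Seeds: presets pin seeds for reproducibility; every generator accepts
  an override so property tests can sweep seeds.
* Degenerate inputs: saturated or empty ddPCR wells, all-masked ratio
  tracks, zero-variance genes, partial CNV profiles and empty populations
  all have defined behaviour (error or flagged result) rather than NaN
  propagation.

## Known limitations

* Read alignment, duplicate marking and MAPQ filtering are upstream of
  this package; depth tracks are consumed as given.
* The segment caller reports window-resolution boundaries; it does not
  resolve breakpoints from split/discordant reads.
* qPCR absolute quantification (copies/µl) is deliberately out of scope;
  all quantities are folds versus a calibrator that must be present in
  each run.
* The haplotype classifier reads presence/absence patterns of three assay
  genes; it cannot distinguish additional structural variants that share
  those patterns ("other" is a catch-all).
* No plotting helpers are included; all outputs are plain tables readily
  plotted with pandas/matplotlib.
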