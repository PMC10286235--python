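# Methods

This note records the statistical models implemented in `poolsweep`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions, so results can be interpreted
and the design decisions audited.

## Pooled FST from read counts

Pool-seq read counts reach the analyst through two sampling stages: `n`
chromosomes are drawn from the population into the pool (binomial), then `c`
reads are drawn with replacement from the pool at each SNP. Both stages
inflate naive heterozygosity-based estimators, so the IBS estimators carry
explicit corrections:

* `Q1̂ = 1 − (n/(n−1))·(c/(c−1))·2p̂(1−p̂)` — the `c/(c−1)` factor removes
  the with-replacement read duplication; `n/(n−1)` removes the chance of
  reading the same chromosome twice. `E[Q1̂]` equals the IBS probability of
  two *distinct* chromosomes; the estimator may legitimately go slightly
  negative (e.g. −1/49 for a 1/1 read split at n = 50), which is the price
  of unbiasedness.
* `Q2̂ = p̂ᵢp̂ⱼ + (1−p̂ᵢ)(1−p̂ⱼ)` — reads are independent across pools, so
  the plug-in is already unbiased.

`FST = (Q1−Q2)/(1−Q2)` follows the ANOVA/Weir–Cockerham convention of the
pooled estimator family; the denominator choice matters (the alternative
`1−Q1` appears in some renderings) and `(1−Q2)` is the one under which the
Balding–Nichols parameter is recovered exactly in expectation:
per SNP, `E[Q1−Q2] = 2p(1−p)·c` and `E[1−Q2] = 2p(1−p)`, so the
ratio-of-sums across SNPs converges to `c`. Windows (and the genome-wide
estimate) therefore aggregate numerator and denominator separately
(ratio-of-sums), the standard choice for this family; average-of-ratios
would weight low-diversity SNPs erratically.

Multi-pool estimates average `Q1̂` unweighted over pools and `Q2̂` over
unordered pairs. A SNP enters a sum only where depth ≥ 2 in every pool
involved (Q1 needs two reads); windows with no usable SNP or a zero
denominator are dropped with a warning.

## Hp and ZHp

`Hp = 2·S_maj·S_min/(S_maj+S_min)²` with S the major/minor read-count sums
over a window; missing SNPs contribute (0, 0) rather than dropping the
window, mirroring how a fixed-SNP-count window behaves on real data with
patchy depth. Major/minor is resolved per pool per SNP (the statistic is a
within-population quantity); read-count ties assign the reference allele as
major, a deterministic convention. ZHp standardizes with the sample SD
(n−1) over all retained windows of all chromosomes jointly. A constant Hp
track has no empirical distribution to standardize against and raises.

Windows are 625 SNPs with step 312 for both scans (the FST text's "half a
window" would be 312.5; one unified integer step keeps the two scans on the
same grid). Windows never span chromosomes; trailing windows shorter than
625 SNPs are dropped, not emitted. The window midpoint
`(first_snp_bp + last_snp_bp) // 2` is the "top position" used by the
region calculus.

## EHH, iHS, XP-EHH

EHH uses the unbiased pair form `Σ n_h(n_h−1)/(n_c(n_c−1))` over carrier
haplotypes identical from the core through the evaluation marker. Distances
are physical bp throughout: the data this targets are SNP-array panels
without a genetic map. Curves are computed marker-by-marker outward with an
incremental group-refinement walk (JIT-compiled; EHH can only decrease, so
the walk stops at the first value below the cutoff).

iHH integrates the curve by trapezoid on each side, truncating at the first
marker below the cutoff with linear interpolation to the crossing; the core
contributes its own EHH at distance 0 (exactly 1 for single-allele classes;
the core-site homozygosity for the all-haplotype class used by iES, which
is the unnormalized site-EHH convention). The integration cutoff (0.05) and
the derived-frequency bounds for iHS (0.05 ≤ p ≤ 0.95) are the customary
defaults of this methodology and are exposed as parameters.

iHS standardizes `ln(iHH_A/iHH_D)` within derived-allele-frequency bins of
width 0.025 (the expectation and SD of the ratio depend strongly on p);
bins with fewer than 10 markers merge greedily with their neighbor.
XP-EHH standardizes `ln(iES₁/iES₂)` by its genome-wide mean and SD — a
single global bin, as its defining formula prescribes. Both are reported as
`−log10(2Φ(−|z|))` with outliers at ≥ 4 (i.e. a nominal two-sided Gaussian
p ≤ 1e-4). No gap penalty is applied for large inter-marker distances.

## Region calculus

Top positions within 100 kb (inclusive) merge greedily into regions;
merging partitions its input (every position lands in exactly one region)
and is idempotent. Gene annotation attaches genes whose 1-based inclusive
span overlaps `[left−50kb, right+50kb]`, the flank applied to the outermost
top positions of the region. Cross-method commonality pairs a window
midpoint with a marker position at ≤ 50 kb on the same chromosome.
Sharing across pairwise comparisons uses connected components of the
flank-extended interval-overlap graph — "identified in at least two
comparisons" does not itself define transitivity, and components make the
result order-independent. Enrichment is an upper-tail hypergeometric test
against a universe defaulting to all genes carrying at least one term, with
BH q-values over all tested terms; the enriched flag additionally requires
more than one query gene in the term, so a single spectacular gene cannot
carry a pathway. Outlier-window counts use `ceil(fraction·n)` with full tie
inclusion. Coordinates are 1-based inclusive internally; BED output is
0-based half-open.

## Array statistics

The QC cascade runs in a fixed order: sample call rate (< 95% dropped),
then per-population SNP filters — MAF < 1%, missingness > 10% (the stated
"call rate below 10%" can only sensibly mean missingness above 10%; a
literal call-rate keep-threshold of 10% would discard nearly every marker),
and Hardy–Weinberg exact p < 1e-6 — then duplicate removal (pairwise IBS
identity > 0.99 drops the later individual by id order; at 0.99 IBS and
method-of-moments IBD agree on duplicates, and IBS is deterministic), and
finally the SNP intersection across populations.

The HWE test is the exact conditional test: given n individuals and the
minor-allele count, `P(h heterozygotes) ∝ 2^h · n!/(n_AA! h! n_aa!)`; the
p-value sums probabilities ≤ the observed table's (with a 1+1e-12 relative
guard against floating-point ties). Computed in log-gamma space; verified
against exact rational enumeration for every table with n ≤ 50.

Heterozygosity and F follow the standard array-tool conventions: per-SNP
expected homozygosity uses the small-sample factor `2n/(2n−1)`; per
individual `F = (O_hom − E_hom)/(L − E_hom)` over its non-missing SNPs;
population observed/expected heterozygosity are per-SNP means (the
aggregation direction is a convention — per-SNP chosen and stated).
Genotype PCA mean-imputes missing calls per SNP, centers by 2p and scales
by √(2p(1−p)) (unit variance under HWE; scaling switchable in spirit by
operating on the raw matrix). Pool-frequency PCA is a deliberately simple
structure summary (centered read-frequency matrix at pooled MAF > 0.4); it
is *not* a covariance-model (Ω-matrix) method and is labeled a stand-in.

## Synthetic data: what it emulates, what it does not

`simulate_pools` draws ancestral frequencies from Beta(0.8, 0.8) — a
stand-in for a SNP-ascertained spectrum, since the real panel's spectrum is
not published — then pool frequencies from the Balding–Nichols Beta with
parameter `c = fst_target` (whose expectation *is* the FST, giving a
closed-form recovery target), then chromosomes binomially (default 100 per
pool = 50 diploids), then Poisson depth (default 95, matching ~90–100×
pooled coverage) and binomial reads. Sweep spans overwrite a pool's
population frequency (default demo: 0.99 over 1,500 SNPs ≈ the ~150 kb scale
of a strong recent sweep at ~10 SNPs/kb); low-het spans round the sampled
frequency to 0/1 (ties to 1), removing within-pool variation while keeping
depth realistic. There is no sequencing-error or base-quality model (QC
filters, not error modeling, are in scope), no linkage between SNPs in the
pooled simulation, and no demography beyond the single differentiation
parameter.

`simulate_sweep_haplotypes` builds a partial hard sweep: a fraction of
haplotypes copy one founder, each site reverting independently with
probability `1 − exp(−d/decay_bp)`; the background is unlinked 50%-frequency
alleles. This produces the right local EHH contrast but not a realistic
genome-wide background.

`simulate_neutral_haplotypes` is the null model for calibration and is a
founder mosaic: haplotypes switch among 20 founder haplotypes at rate
`1 − exp(−gap/25kb)`, giving multi-marker haplotype blocks (mean ~250
markers at the default ~100 bp spacing) and a varied frequency spectrum.
The choice is load-bearing: with unlinked markers the iHH/iES integrals are
dominated by one or two inter-marker gaps and the standardized scores are
strongly non-Gaussian, which says nothing about real data where EHH decays
smoothly. Under the mosaic null the binned iHS standardization is
well-calibrated (outlier fraction at the −log10 p ≥ 4 rule consistent with
its nominal 1e-4). XP-EHH remains mildly leptokurtic (excess kurtosis
≈ 0.5) under every neutral geometry examined: its global standardization
cannot cancel regional fluctuations in haplotype diversity, so its
empirical tail at ~3.9 SD is a few-fold heavier than Gaussian. This matches
the statistic's known behavior in practice and is why empirical (top-x%)
thresholds are common for XP-EHH; the package reports the Gaussian
transform as defined and leaves threshold policy to the caller. Passing
tests on these generators demonstrates estimator correctness and
calibration under the stated models — not robustness to sequencing error,
real LD structure, or demography.

## Problem sizes and determinism

Validation studies use 2 pools × 20,000 SNPs at depth ~95–100 (20 seeds per
differentiation level; 100 replicates for detection rates), haplotype
panels of 200 × 2,000 markers (100 seeds for localization) and 200 × 10,000
markers for null calibration, and 1,000 × 5,000 genotype matrices for
inbreeding recovery — sizes at which the Monte-Carlo error is far below
every tolerance asserted. All generators take explicit integer seeds;
identical parameters and seed reproduce byte-identical output, and the CLI
demo writes SHA-256 manifests so end-to-end determinism is checkable.

## Known limitations

* No genetic-map distances, gap penalties, or phasing: haplotype inputs
  must be phased and complete.
* The pooled simulation has unlinked SNPs, so FST/ZHp window values are
  independent across non-overlapping windows — real window tracks are
  locally correlated.
* The pool-frequency PCA is a structure sketch, not a demographic
  inference.
* Enrichment treats terms as flat sets (no ontology DAG propagation).
* Multiallelic sites and indels are skipped at ingestion.
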