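# Methods

This note documents the statistical models implemented in clinescan, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Genotype representation and QC

Genotypes are dosage-coded (0/1/2 copies of the ALT allele, `nan` missing)
for biallelic SNPs only; multi-allelic and indel records are skipped on VCF
import with a logged count. Coordinates are 0-based half-open internally and
converted back to 1-based on VCF/GFF3 emission, which keeps interval
arithmetic (gene flanks, LD windows) unambiguous.

QC removes, in order: SNPs whose missingness exceeds the cap (default 20%,
strict inequality, so exactly 20% survives), then monomorphic SNPs among
those remaining. Optional complete-LD culling computes pairwise r² on
pairwise-complete dosages *within chromosomes only* and, in each pair with
r² = 1, drops the SNP with higher missingness (ties: the later genomic
position). Cross-chromosome r² = 1 is treated as coincidence; restricting
the cull to one chromosome is the conservative reading when the original
procedure is underspecified. The filter is idempotent.

Heterozygote dosages are retained everywhere and never recoded: the target
panels are ~99% self-fertilizing (inbreeding coefficients ≈ 0.98–1.0), so
heterozygotes are rare but real.

## Sample partitions

Partitions assign each sample to one group or exclude it. Numeric intervals
are closed on the lower bound and open on the upper — elevation bands
[0, 1500), [1500, 3000), [3000, ∞) m, so the three-level partition exactly
refines the two-level 3,000 m split — with one documented exception: the
wild-range latitude band is closed at both ends ([30, 40]° N), and 48° E
belongs to the eastern longitude group. A single global rule was preferred
to per-site judgement because the source procedure does not state how
boundary samples were treated. Spring and winter growth habits form the
habit comparison; facultative and unknown accessions are excluded.

## Weir–Cockerham θ and the outlier scan

For each SNP, allele frequencies p_i, observed heterozygote frequencies
h_i, and sample sizes n_i per group feed the 1984 moment estimator:
n̄, n_c, p̄ (sample-size-weighted ALT frequency), s² (weighted among-group
variance of p), h̄, and then the three variance components a (among
populations), b (among individuals within populations), c (within
individuals), with θ = a/(a+b+c). θ is undefined (`nan`, never 0) when the
SNP is monomorphic across the compared groups or when any group has fewer
than two non-missing diploid calls. Negative θ is reported as-is.
Multi-group comparisons use the same estimator with r > 2. The
implementation is vectorized across SNPs and is checked against an
independent scalar term-by-term evaluation on 1,000 random instances
(agreement to 1e−12).

Unequal group sizes inflate the variance of θ, so each comparison is run on
subsamples equalized to the smallest group (without replacement), 10
iterations by default, and θ is averaged over the iterations where it is
defined — an undefined iteration contributes nothing rather than zero.
A genome-wide summary is also reported as the ratio-of-sums
Σa / Σ(a+b+c) across SNPs and iterations, the combination the original
estimator prescribes for multiple loci. This distinction matters for
validation: with two groups the per-SNP θ behaves like Fz/(Fz+1−F) with
z ~ χ²₁ at simulated differentiation F, so its *unweighted mean* across
SNPs converges to the Jensen-attenuated value (≈0.086 at F = 0.10, ≈0.157
at F = 0.20), while the multilocus ratio is unbiased for F. The validation
suite asserts both behaviors at their exact expectations.

Permutation significance reassigns group labels across the assigned samples
(1,000 permutations by default; each permutation re-runs the balanced scan,
with 1 iteration per permutation for tractability — configurable). Three
p-value variants are reported per SNP:

- `perm_p = #{θ* ≥ θ}/n_perm` — the conventional count, which can be
  exactly 0 for a SNP more extreme than every permutation;
- `perm_p_add1 = (count+1)/(n_perm+1)`;
- `perm_p_rand = (#{θ* > θ} + U·(#ties+1))/(n_perm+1)`, U ~ Uniform(0,1),
  seeded.

θ on dosage data is a discrete statistic — in an inbred panel dozens of
permutations tie with the observed value at a typical SNP — so `perm_p` is
deliberately conservative (stochastically larger than uniform under the
null), and no reweighting can make the ≥-count uniform. The randomized-rank
variant is exactly uniform under exchangeability whatever the tie
structure; it is the variant to use for calibration diagnostics, while
`perm_p` matches the field's reporting convention.

Outliers are flagged at the empirical 99th (and, more liberally, 97.5th)
percentile of averaged θ within each comparison. The threshold is the k-th
largest defined value with k = ⌈(1 − pct/100)·m⌉ and SNPs with θ ≥ threshold
are flagged: on tie-free inputs exactly ⌈0.01·m⌉ SNPs are flagged at the
99th percentile for every m (interpolating percentile definitions miss this
for m just above a round number), and ties at the threshold are all flagged.

## Structure summaries

The VanRaden kinship matrix centers each dosage column by twice its ALT
frequency and scales by 2Σpⱼ(1−pⱼ); missing dosages are mean-imputed for K
(and for the association design matrix) only — never in the stored
genotypes. PCA is an SVD of the same centered matrix (optional
unit-variance scaling of columns is provided since the original tooling's
behavior is not recoverable), with component signs fixed so the
largest-magnitude loading is positive. No LD pruning is applied before
either by default; a pruned input can simply be passed instead. Per-sample
observed heterozygosity, the inbreeding coefficient F = 1 − h_obs/h_exp
(h_exp the mean 2pq over SNPs called in that sample), and the mean pairwise
Manhattan distance (mean |Δdosage|/2 over co-called SNPs, computed via
indicator-matrix products) complete the summaries.

## Environmental variables and ICA

BIO variables are standardized column-wise before independent component
analysis. ICA is FastICA-class contrast maximization (the original analysis
used an Infomax implementation; both maximize non-Gaussianity of the
unmixed sources and recover the same subspace on these inputs) with
max 500 iterations at tolerance 1e−6; on non-convergence the fit retries
with a new derived seed up to 5 attempts. Components are ordered by the
variance of the data they reconstruct and sign-fixed by largest loading.
The default environmental "phenotype" matrix is latitude, longitude,
elevation, BIO1–BIO19, and the top 3 ICs.

## Mixed-model association (P3D)

For each variable y: samples with missing y are dropped (kinship and
covariates subset accordingly), variance components are estimated once by
REML for y = Xβ + g + e, g ~ N(0, σ²_g K), e ~ N(0, σ²_e I), with X an
intercept plus k = 3 PCs by default. The restricted likelihood is profiled
to one dimension using K = USUᵀ: for a given δ = σ²_e/σ²_g the GLS fit in
the rotated basis gives σ̂²_g in closed form, and δ is optimized on a log
grid followed by bounded refinement (δ ∈ [1e−6, 1e6]; boundary estimates
are flagged). Degenerate inputs — constant y, or K with no off-diagonal
structure, where only the total variance is identified — are flagged and
handled rather than fatal.

The per-SNP scan holds (σ̂²_g, σ̂²_e) fixed (P3D), whitens y, X, and the
mean-imputed dosage matrix by V^{-1/2}, residualizes on the covariates via
QR, and performs a Wald t-test on the dosage coefficient with
n − rank(design) degrees of freedom. No compression (grouping of
individuals) is applied: every sample is its own group, which is the
reproducible superset of unspecified compression settings. With K = I the
scan reduces exactly to per-SNP ordinary regression (verified to 1e−8 on
p-values), and under a structured null with kinship + 3 PCs the empirical
type-I error at α = 0.05 is calibrated (0.03–0.07 over 5,000 SNPs).
SNPs collinear with the covariates get p = nan and a `singular` flag.
Benjamini–Hochberg q-values (step-up, verified against an independent
implementation) are computed per environmental variable by default —
matching per-variable reporting — with pooling available by concatenating
tables before `bh_fdr`.

## LD windows and classification

r² is the squared Pearson correlation of dosages over pairwise-complete
samples (≥2 required, both variances positive) — equivalent to haplotype r²
for fully inbred lines, a documented approximation for heterozygotes. The
dense (resequencing) panel is pre-filtered to MAF ≥ 1% and < 50%
missingness. For each hit SNP the window is ±100 kb; if the hit is absent
from the dense panel, the proxy is the in-window dense SNP minimizing
|ΔMAF|, with distance breaking MAF ties and lower position breaking
distance ties — MAF similarity deliberately outranks distance, consistent
with observed proxy statistics (ΔMAF ~ 0.005 at mean distances of tens of
kb). No hard ΔMAF cap is imposed. Classification at r² > 0.45 (a fixed
default, not re-derived per dataset; an empirical-percentile mode exists):
`within_gene` if every high-LD neighbor lies in the gene containing the
proxy, `extended` if any lies outside (including a proxy in no gene),
`none` if no neighbor exceeds the threshold, `missing_window` if the window
has no usable neighbors.

## Gene proximity and haplotypes

A SNP identifies every gene whose interval extended by a 10 kb flank
contains it, boundary inclusive at exactly 10 kb; strand is ignored because
the rule is strand-symmetric; overlapping genes all match. Haplotypes over
an interval treat homozygous dosages as single alleles; samples with any
heterozygous or missing call in the interval are excluded and counted
(statistical phasing is out of scope for panels at F ≈ 0.98–1.0 — a
pre-phased VCF can be supplied instead).

## Synthetic panels

`simulate_panel` draws ancestral ALT frequencies uniform on [0.05, 0.95],
population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) at target F_ST
(degenerate at F = 0), and genotypes with the selfing-equilibrium
inbreeding coefficient F_is = s/(2−s); at the default s = 0.99, F_is ≈ 0.98
and heterozygotes nearly vanish. Defaults emulate the motivating study's
scale: 8 populations × 98 accessions (784), 5,800 SNPs on 7 chromosomes
with arm-weighted (U-shaped Beta(0.4, 0.4)) SNP density, 2% missingness.
Population centers span latitude 24–56° N, longitude −4–96° E, and
alternating elevations from 300 to 4,100 m so every standard partition is
populated; individuals jitter around their center. Temperature-like
variables (BIO1–11) fall linearly with latitude and elevation,
precipitation-like variables (BIO12–19) track longitude and latitude, each
with shared ("regional weather") plus individual noise at gradient-scale
SD 0.4 — correlated mixtures that give ICA genuine sources. Winter growth
habit concentrates at milder sites.

Adaptive loci (default 58 ≈ 1% of SNPs; the validation scenarios use 20)
replace the Balding–Nichols frequency with a per-individual logistic cline:
P(ALT) = sigmoid(cline_strength · z), z the standardized value of the
linked environmental variable at that individual's location. The default
cline_strength of 3.0 moves frequencies from ~0.05 to ~0.95 across the
gradient — a strong cline, the regime in which scan recovery is a
well-posed question. A Balding–Nichols generator was chosen over a
coalescent because it matches the F_ST parameterization the estimator
targets and runs in seconds; externally simulated VCFs can be fed to the
same pipeline. Gene models are non-overlapping intervals with arm-weighted
density (central third thinned), with genes created around planted loci and
labeled as the candidate subset; the outgroup table reports the true
ancestral base with a configurable mismatch rate producing unpolarizable
sites.

What the generator does **not** emulate: realistic linkage (background SNPs
are independent given population frequencies, so LD-based validation uses
the dedicated haplotype-block generator instead), demographic history,
ascertainment bias of array SNPs, or spatially autocorrelated sampling.
Consequently the validation demonstrates estimator correctness and
calibration under the island model, not robustness to isolation-by-distance
or to real LD structure.

## End-to-end recovery experiment

`combined_scan_recovery` plants 20 strong clines along the temperature axis
(BIO1) in panels of 10 × 50 samples, 2,000 SNPs, F_ST = 0.08, and runs the
differentiation comparison aligned with that axis (two-level elevation)
plus the MLM on BIO1; hits are the union of 99th-percentile outliers and
q ≤ 0.25 associations. Over 20 replicates the scan recovers ~90% of planted
loci at observed FDR ~0.15. Two properties of this design are worth
stating. First, percentile outlier calling always flags the top 1%, so
every comparison *not* aligned with a planted cline contributes almost pure
false positives to a union — which is why the experiment pairs each
comparison with the axis it interrogates, and why multi-comparison unions
on real data should be read as candidate lists, not discoveries. Second,
the mixed model absorbs population-level environmental signal into the
kinship term, so nearly all recovery power here comes from the
differentiation scan; correlative approaches regain their advantage when
clines vary within populations more than the structure captured by K — the
power trade-off known from the simulation literature.

## Validation problem sizes and numerical conventions

The validation suite uses 2,000-SNP two-group panels for estimator
recovery, 1,000 SNPs × 200 permutations for null calibration, 5,000 SNPs
for type-I error, and 20 replicates for the recovery experiment — sizes at
which the measured quantities' Monte-Carlo error is comfortably inside the
asserted tolerances while the whole suite runs in well under a minute.
Tolerances: 1e−12 for oracle equality, 1e−8 for the OLS reduction, ±0.02
for F_ST recovery, [0.03, 0.07] for type-I error at α = 0.05. Seeds derive
from a single master seed via `numpy.random.default_rng`; all scans are
bit-reproducible given the seed and sample order.
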