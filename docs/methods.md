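# Methods

This note documents the models implemented in `pleiokit`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Synthetic genotypes and summary statistics

Genotypes come from a latent-Gaussian (copula) model: within each LD
block two latent haplotype processes per individual follow an AR(1)
autocorrelation `block_rho**|i-j|`; each is thresholded at the
allele-frequency quantile and the two indicators summed into a {0,1,2}
dosage.  This yields Hardy–Weinberg genotypes with a controllable,
positive-definite block correlation; blocks are independent and
separated by 2 Mb so no LD window spans two blocks.  Note that
thresholding attenuates correlation: a latent correlation of 0.9
corresponds to a dosage-scale r of about 0.76 (tetrachoric relation
`(2/pi)·arcsin(rho)` at frequency 0.5), which matters when constructing
panels with a target dosage r².

Paired summary statistics follow a bivariate causal mixture.  Each SNP
is causal for trait A only (`pi_a`), trait B only (`pi_b`), both
(`pi_shared`), or neither.  Standardized causal effects are Gaussian
with variance `h2 / E[n_causal]`; shared effects have proportional
magnitudes, with the trait-B sign flipped with probability
`1 − sign_concordance`.  With equal per-trait variances the correlation
of shared effects is `2·sign_concordance − 1`, which is how the
generator dials a target genetic correlation.  Marginal z-scores are
drawn per block as `z ~ N(sqrt(N)·R·beta, R)` with `R` the shrunk
empirical block correlation of the panel (ridge 0.02, escalated only if
a Cholesky factorization fails).  This is the standard infinitesimal
GWAS approximation; it is exact for OLS association in the large-N
limit and orders of magnitude faster than regenerating individual-level
data.

Defaults: minor allele frequencies uniform on (0.05, 0.5] (matching the
MAF>0.05 QC filter), heritabilities 0.4 (the middle of the 0.27–0.48
range typical for volumetric brain phenotypes), GWAS sample sizes
30,000 (discovery-scale), LD blocks of 40 SNPs with AR(1) 0.8.  Hard
calls only: imputation dosage uncertainty is not simulated, though an
INFO column is carried through and filtered on when present.

What the generator does **not** emulate: realistic human LD maps,
population structure and relatedness, imputation error, the X
chromosome, and allele-frequency/effect-size coupling.  Tests passing on
these data therefore establish the correctness and calibration of the
statistical machinery under its own assumptions, not robustness to the
full messiness of real biobank data.

The clinical cohort generator produces five volumes per subject as
covariate effects (sex, age, age², standardized ICV, site intercepts)
plus a per-diagnosis offset expressed in residual-SD units plus Gaussian
noise; the whole-brainstem volume is the sum of the four regional
volumes plus independent noise, so contrasts with and without the
whole-brainstem covariate differ genuinely.  Region baselines and
residual SDs are fixed at plausible volumetric scales (e.g. pons
15,000 ± 1300 mm³); offsets in residual-SD units are recovered directly
as Cohen's d by the contrast model.

## Association and QC

Variant QC removes, in fixed order: INFO < 0.5 (when present),
MAF < 0.05 (strict inequality, so a variant at exactly 0.05 is kept),
missingness > 5%, and exact Hardy–Weinberg p < 1e−6.  The HWE test is
the exact conditional test (sum of probabilities of heterozygote counts
no more likely than observed given the allele counts), not the
chi-square approximation.

Association is OLS of phenotype on dosage with covariates, computed by
residualizing both phenotype and dosages on the covariate design
(Frisch–Waugh–Lovell); degrees of freedom are taken from the full model
(`n − k − 1`) so the result equals the full multiple regression to
machine precision.  Categorical covariates expand to indicators;
rank-deficient designs are rejected with the collinear columns named;
constant dosage columns yield flagged NA rows rather than errors.
p-values are floored at 1e−300 to keep `−log10 p` finite.  Relatedness
exclusion is expressed as a sample mask supplied by the caller; kinship
estimation is out of scope.

## Clumping dialect

Thresholds: independent significant SNPs at pairwise r² < 0.6 within a
1 Mb window (dependence is r² ≥ 0.6, so the boundary case is dependent,
consistent with the candidate-SNP rule), leads at r² < 0.1, candidates
at r² ≥ 0.6, merge distance 250 kb.  Selection is greedy by ascending
significance with (chromosome, position) tie-break — the convention of
the standard clumping tools.  The window is physical distance between
variant positions, not distance from a clump border.  Because candidate
spans can overlap even when leads are far apart, loci are additionally
merged when their spans overlap; this keeps per-trait loci pairwise
disjoint, which the downstream cross-trait merge assumes.  Cross-trait
unique regions are formed by ≥1 bp interval overlap; alternative rules
(lead distance) would give slightly different unique-region counts.

## Conditional/conjunctional FDR

The estimator is the stratified-ECDF counting formula with pi0 fixed at
1 (a conservative upper bound; nothing in the framework pins pi0 down
and conservatism is preferred).  Two evaluation paths:

* **Exact** (default, no pruning): each variant's cFDR is the counting
  formula evaluated at its own (p1, p2) with "≤" ties exactly as
  written, computed in O(m log m) by 2-D dominance counting.  This path
  reproduces hand counts bit-for-bit and is used whenever LD can be
  ignored.
* **Grid + pruning**: one variant per LD block (connected components at
  r² > 0.1 within 1 Mb) per iteration, default 20 iterations.  Stratum
  sizes and threshold counts are *pooled* (summed) across iterations
  before the ratio is taken — averaging ratios of near-empty strata
  would be wildly unstable.  The nominal grid is −log10 p1 from 0 to
  7.3 in steps of 0.1; conditioning knots sit at the four Q–Q cutoffs
  (p2 ≤ 1, 0.1, 0.01, 0.001) with half-decade interpolation knots.
  Conditioning deeper than p2 ≤ 0.001 is clamped to the strictest knot.
  A stratum averaging fewer than 25 variants per pruning iteration is
  widened to the next coarser knot (the same escape used for exactly
  empty strata): at desk scale such a stratum typically spans one or
  two LD blocks, and an ECDF ratio estimated from it collapses toward
  p1 itself, destroying FDR control.  With the widening rule the null
  false-discovery proportion over 50 replicates at m = 20,000 is at the
  nominal level.  Monotone non-increase of the table along both −log10
  axes is enforced by antitonic (pool-adjacent-violators) regression —
  a running minimum would bias the table downward by selecting noise
  minima.  Table values are bilinearly interpolated in −log10 space to
  each variant and clipped to [p1, 1].

Order of operations is fixed and documented: region exclusion (extended
MHC chr6:25,119,106–33,854,733 and 8p23.1 chr8:7,242,715–12,483,982,
hg19, inclusive bounds; MAPT/APOE coordinates are config-supplied),
then genomic inflation control (lambda = median(z²)/0.455 over all
SNPs; z divided by sqrt(lambda) only when lambda > 1 — no deflation),
then harmonization and FDR construction.  Conjunctional FDR is the
per-variant maximum of the two reciprocal conditional FDRs; both
directions share the same pruning masks, so the result is exactly
symmetric in trait order.  Shared loci are clumped on conjFDR values
exactly as p-values are; the per-locus effect direction is
sign(z1·z2) at the minimum-conjFDR lead.

## Heritability and genetic correlation

GREML uses a single genetic variance component (no MAF stratification).
All solves happen in the eigenbasis of the GRM, where the covariance is
diagonal; updates are average-information steps with an EM fallback
whenever an AI step would decrease the restricted likelihood, variance
components clamped at 1e−8, convergence at |Δ logL| < 1e−6 (max 100
iterations).  Standard errors come from the inverse AI matrix, the h²
standard error by the delta method.  With a near-identity GRM the model
degenerates to a single Gaussian variance; the fit then recovers the
total (the usual unbiased residual variance) and warns that h² is
weakly identified.

LD scores are sums of adjusted r² (`r² − (1−r²)/(n_ref−2)`) within a
1 Mb window.  LDSC regression weights are `1/max(l, 1)` with an
optional two-step intercept (from the chi² < 30 subset); the full
iterative heteroskedasticity weighting of the reference implementation
is deliberately not reproduced — at desk scale the simple weights give
indistinguishable point estimates and the jackknife absorbs the
efficiency loss.  Jackknife blocks are contiguous, `ceil(m/100)` capped
at 200.  The cross-trait slope gives `rho_g`; rg = rho_g/sqrt(h2_1·h2_2)
with the whole ratio re-estimated per delete-one block.  Intercepts are
reported, never constrained, so sample overlap shows up in the
cross-intercept rather than biasing rg.  LDSC assumes polygenicity:
with a few hundred causal SNPs the chi-square-on-l regression is valid
in expectation but extremely noisy, so recovery tests run in the fully
polygenic regime.

For LDSC-style pruning the keep-one-per-block rule is applied at
r² ≥ 0.2 (reading the threshold as a pruning criterion, its only
sensible direction).

## Clinical contrasts

Controls are the pooled healthy subjects sharing at least one scanner
site with the cases of the diagnosis under test; site enters as a fixed
effect when more than one site remains.  Cohen's d is derived from the
group-term t statistic (`d = t(n1+n2)/(sqrt(n1 n2) sqrt(df))`), the
standard covariate-adjusted conversion; the alternative (adjusted
marginal means over a pooled SD) would differ slightly and is not
implemented.  Negative d means cases have smaller volumes.  The full
matrix is 9 tests per diagnosis (whole brainstem; four regions each
with and without the whole-brainstem covariate) — 99 tests for the 11
standard diagnostic groups — and Benjamini–Hochberg runs once across
the whole matrix.

## Numerical conventions

All in-memory coordinates are 1-based inclusive; BED exports are
0-based half-open (round-trip tested).  Autosomes only.  Every
stochastic routine takes an explicit seed; there is no hidden global
randomness.  p-values are floored at 1e−300.  PLINK-1 binary,
tab-separated summary statistics (with a column-alias table for common
dialects), GCTA binary GRM and BED region files are the on-disk
formats.

## Problem sizes used by the test suite and acceptance script

Null-calibration runs use 20,000 SNPs in 500 LD blocks with 50
replicates; GREML recovery uses n = 2000 samples and M = 5000 SNPs with
25 phenotype replicates against a single cached GRM eigendecomposition;
LDSC recovery uses m = 20,000 with a 500-sample LD reference.  These
sizes were chosen as the smallest at which each estimator's sampling
error is small relative to the effects being checked.

## Known limitations

No mixed-model association, no bivariate GREML, no partitioned LDSC,
no local genetic correlation or colocalization, no kinship estimation,
no X chromosome, no imputation handling beyond an INFO passthrough.
The conditional FDR grid path is tuned for desk-scale inputs; at
biobank scale (millions of variants) the stratum-occupancy floor would
essentially never trigger and the conditioning clamp could be deepened.
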