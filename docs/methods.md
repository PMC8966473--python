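# Methods

## Setting and model

The package targets replicated introduction designs: one large source
population, *m* derived populations independently founded from it, and
genotype samples (~20 diploid individuals per population) taken τ
generations after founding. All statistics work on the frequency of the
allele that is **minor in the source sample** (ties at 0.5 polarize to the
VCF alternate allele, a deterministic, file-order-independent rule).
Polarizing every population to one allele preserves the *direction* of
change, which is what both the eigenanalysis loadings and the summed
selection coefficients exploit.

Sites are dropped when any population has fewer than `min_called_fraction`
(default 0.5) of its chromosomes called, or when the same allele is fixed
in every population (such sites produce zero-length change vectors that
cannot be normalized). The default missingness filter is deliberately
permissive and configurable; panel-level QC (depth, MAF, HWE) is assumed to
have happened upstream.

## Window eigenanalysis

Windows contain exactly *n* consecutive SNPs (default 200), tiled per
chromosome; a terminal remainder is **discarded** rather than analysed,
because the permutation null is built from windows of exactly *n* SNPs and
mixing window sizes would break exchangeability between observed and null
statistics. Windows live in SNP-index space, not base-pair space, so every
window has the same matrix dimension regardless of SNP density. (The
simpler per-75-kb mean |ΔAF| summary, by contrast, uses base-pair windows,
half-open `[start, start+75000)` tiled from position 1.)

For each window, X (m × n) holds derived-minus-source frequency changes;
rows are normalized to unit Euclidean length, making the analysis
scale-free — a population with uniformly larger drift contributes a
*direction*, not a magnitude. C = XXᵀ then has unit diagonal and trace m,
so eigenvalues are directly comparable across windows: λ₁/m is the fraction
of total change variance on the leading shared axis. A window with an
all-zero row (a population with literally no change, essentially only
possible in degenerate constructed data) is excluded and logged, since a
zero vector has no direction.

Numerical choices: the decomposition uses a dense symmetric eigensolver on
the explicit m × m matrix; eigenvector sign is fixed by making the first
population's loading non-negative (falling back to the next population when
that loading is numerically zero, |v| ≤ 1e-10), purely to make outputs
reproducible — the sign is mathematically arbitrary. Loadings within 1e-10
of zero are labelled indeterminate rather than forced into a parallel or
antiparallel call. For eigenvector k > 1 the test statistic is the
cumulative sum λ₁+…+λ_k, which is monotone in "excess shared variance"
where a single λ_k is not; the single eigenvalues are still reported.

## Permutation null

Each permutation (1) draws a window of *n* consecutive SNPs at a uniformly
random start index, rejecting windows that would span a chromosome
boundary; (2) pools all individuals across the source and derived
populations and reshuffles labels, preserving the original group sizes, the
group inheriting the source label acting as pseudo-source (a
`derived_only` variant keeps source individuals fixed and shuffles only
derived ones); (3) recomputes frequencies, ΔAF, normalization and the
eigendecomposition exactly as for observed windows. Windows yielding an
all-zero ΔAF row are redrawn (bounded at 100 attempts). P-values use the
add-one rule `p = (1 + #{null ≥ obs}) / (1 + n_perms)`, which can never be
zero; outlier calls compare the observed statistic against the empirical
null quantile (default 0.999, linear-interpolation quantile).

**Calibration regime.** Relabelling individuals is an exact permutation
test when individuals are exchangeable across populations — i.e. when
post-founding drift is small next to binomial sampling noise (sample sizes
of 20 give sampling variance p(1−p)/40 per population; drift adds
Σ_t 1/(2N_t) of independent row variance that the shuffled pseudo-groups do
not reproduce). The package's calibration test therefore uses a neutral
genome with large census sizes (N = 2×10⁴ for all 7 generations), where the
observed 0.99-quantile exceedance matches its nominal 1% within the exact
binomial interval. With realistic drifting censuses (hundreds of
individuals) the null is **conservative**: drift inflates the independent
(non-shared) component of each change vector, observed λ₁ shifts *down*
relative to the null, and fewer than nominal windows exceed the cutoff.
Empirically, the study-shaped default design gives an observed mean λ₁
about 0.2 below the null mean and essentially zero false positives at the
0.99 quantile. This direction of error costs power but not validity, and is
worth knowing when interpreting a genome scan with very strong drift.

## Wright-Fisher drift simulator

Neutral drift is simulated per SNP on frequencies, not individuals:
`p_t = Binomial(2N_t, p_{t-1}) / 2N_t` for t = 1…τ, with generation 1 the
founding bottleneck. This is the exact neutral Wright-Fisher sampling model
for unlinked loci; individual-based machinery adds nothing when all
downstream use is per-SNP frequency change. No mutation is added (negligible
over ≤ 8 generations), and 0/1 are absorbing. The simulator reproduces the
closed-form drift laws used as test oracles: E[p_τ] = p₀ (martingale) and
Var[p_τ] = p₀(1−p₀)[1 − Π_t (1 − 1/(2N_t))].

Founder frequencies either copy an observed source frequency table (the
source sample taken as representative of founding frequencies, justified by
a large source population and short sourcing-to-sampling interval) or are
drawn from the neutral folded spectrum, density ∝ 1/p + 1/(1−p) truncated
to [1/(2Nₑ), 0.5]; the antiderivative of that density is logit(p), giving
exact inverse-CDF draws. An optional `maf_min` truncation emulates the
MAF-filtered SNP panels typical of empirical scans.

Dated mark-recapture census series are collapsed to per-generation sizes
with a helper that takes a generation length (default 7.9 months) and the
**harmonic mean** of census points within each generation interval —
harmonic because drift variance compounds as 1/N, so low-census episodes
dominate; empty intervals inherit the previous generation's size. The Nₑ
used to initiate simulations is a required input with no default: it is a
property of the user's source population, not of the method.

## Selection coefficients

The standardized coefficient `s = (2/τ)·ln(p_τq₀/p₀q_τ)` is the per-
generation additive selection intensity that would deterministically
produce the observed log-odds change. The selection model used throughout
(simulator and synthetic generator) is the diploid **multiplicative**
model, genotype fitnesses 1 : e^{s/2} : e^{s}. Its marginal allele-fitness
ratio is exactly e^{s/2} at any frequency, so log-odds grow by exactly s/2
per generation and the estimator inverts deterministic selection without
bias; it agrees with the textbook 1 : 1+s/2 : 1+s parameterization to
first order in s (the latter's discrete-time logit increment falls ~10%
below s/2 by s = 0.3, which is why the exponential form is the package's
canonical definition).

Final frequencies of exactly 0 or 1 are clamped to `c` and `1−c` before the
log (default `c = 1/(2·n_chr + 1)` with n_chr the sampled chromosomes in
that population — the frequency an unobserved allele could have just below
the detection limit). Founding frequencies of 0 or 1 are rejected: change
from a fixed founder is undefined under this model. Outputs carry the clamp
used; only SNPs hitting fixation are sensitive to it.

Signed s is summed within SNPs across populations — maximized by large,
co-directional change, cancelled by antiparallel change. Neutral thresholds
come from the census-conditioned simulations: per-replicate per-SNP s per
population, summed across populations with replicate r of each population
paired (founding is independent, so any fixed pairing is exchangeable and
fixed pairing keeps memory bounded), pooled, and the 0.99/0.999/0.9999
quantiles taken of |summed s| (two-sided by default, since drift is
symmetric; a one-sided option retains the signed distribution). Flagged
SNPs get the highest exceeded tier, tiers are nested, and per-chromosome
observed counts are reported next to the expectation (tail fraction ×
chromosome SNP count).

Note one structural asymmetry inherent to this comparison: observed s is
computed from *sample* frequencies while the neutral thresholds come from
*latent* simulated frequencies, so finite-sample noise inflates observed
|s| slightly relative to the null. The package's calibration test avoids
the confound by comparing simulated observations with simulated thresholds;
users applying small sample sizes should expect mildly anti-conservative
tails from this source.

## Synthetic-data generator

`SyntheticDesign` defaults emulate the target study design: one source and
four derived populations, 20 diploid samples each, τ = 7 generations,
founding bottlenecks of 100–200 individuals recovering into the high
hundreds-to-low-thousands with seasonal fluctuation (one population
crashing to 80 after founding before recovering), Nₑ = 1000 founder
spectrum truncated at MAF 0.05, 5% missing genotypes, and uniformly placed
SNP positions on 25-Mb chromosomes. Selected loci are single SNPs with a
per-population s vector; a "selected window" is planted as a run of
selected SNPs with equal s inside one window span. Derived-population
frequencies evolve through the drift kernel with the deterministic
selection update applied before each binomial draw; sampled genotypes are
Binomial(2, p) per individual; whether the VCF ALT allele is the minor
allele is randomized per site so the polarization code is genuinely
exercised. Everything is reproducible from one seed, and a truth table
(coordinates, founder frequency, per-population s, sign pattern) accompanies
every dataset.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate robustness against: linkage disequilibrium (SNPs are
independent, while real windows of 200 consecutive SNPs are correlated, one
reason the real method uses an empirical permutation null rather than an
analytic one), migration between populations, overlapping generations and
sex structure, genotyping error beyond uniform missingness, and
coverage-dependent call quality.

## Validation problem sizes

The shipped validation uses: 1,000 random windows for the eigen-algebra
bounds; a ~10⁵-SNP, 100-sample neutral genome with a 2,000-permutation null
and ~510 windows for calibration; 10⁴ replicates for the drift-law checks;
2,000 replicates at N = 5000, τ = 20 for selection-coefficient recovery;
4×10⁴ observed values against thresholds pooled from 8×10⁶ simulated ones
for tier calibration; and 20 replicate genomes (10 in the acceptance
script) with 1,000-permutation nulls for end-to-end power. These sizes give
Monte-Carlo error comfortably inside each test's tolerance while keeping a
full run in minutes on one core.

## Known limitations

- The permutation null is conservative under strong drift (see above);
  power comparisons across populations with very different census histories
  should account for this.
- Windows in SNP-index space have variable physical span; regions of
  extreme SNP density map to short windows and vice versa.
- The s estimator is a moment-style inversion, not a likelihood: it has no
  sampling-error model and should be read as standardized change, with
  significance coming only from the simulation quantiles.
- Multiallelic sites and indels are skipped at input rather than
  decomposed.
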