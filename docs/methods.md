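# Methods

## Model and scope

The package addresses admixture mapping in two-way admixed cohorts. All
inference assumes the **hybrid-isolation model**: a single admixture event
λ generations ago with no subsequent gene flow. Each individual *j* carries
a European admixture proportion m_j; each of their haplotypes starts in a
Bernoulli(m_j) ancestry and accumulates recombination breakpoints as a
Poisson process with rate λ per Morgan, redrawing its ancestry
Bernoulli(m_j) at every breakpoint (a "pool" redraw rather than a forced
switch). This makes ancestry tract lengths exponential with rate λ per
Morgan and gives the haploid transition kernel over a gap of *d* Morgans

    P(next = European | current) = (1 − e^{−λd}) m + e^{−λd} · 1[current is European],

with stationary start Bernoulli(m). The diploid hidden chain is the product
of two independent haploid chains (4 ordered states); unphased genotypes are
emitted as one Bernoulli(p_ancestry) draw per haplotype using
ancestry-specific allele frequencies, and missing genotypes emit 1. The
simulator implements exactly this generative process, so fitting the HMM to
simulated cohorts is a clean parameter-recovery oracle: the test suite
demands mean |m̂ − m| < 0.03 and λ̂ ∈ [4, 11] at the reference configuration
(100 individuals, 500 AIM-grade markers, m ~ Beta(2,8), λ = 7).

The redraw formulation was chosen over a 2-state flip chain precisely so the
simulator and the inference transition kernel coincide by construction; the
two parameterizations are close for small m but not identical.

## Differentiation statistics

δ = |p₁ − p₂|. F_ST uses Wright's variance-standardized two-population form
s²/(p̄(1−p̄)) with the population (K = 2, unweighted) variance
s² = ((p₁−p̄)² + (p₂−p̄)²)/2 = δ²/4. This estimator reproduces the anchor
that ties the two selection thresholds together — min F_ST = δ² (= 0.36 at
δ = 0.6), attained at symmetric frequencies p̄ = 1/2, with maximum
δ/(2−δ) at the boundary p₁ = 0. Parental sample sizes do not weight the
estimator. Sites fixed for the same allele in both populations return
F_ST = 0 with a log note.

SIC is the mutual information (base-2; the base is configurable and r_i is
invariant to it) of the joint allele × ancestral-origin table
a₀₀ = (1−m)p_YRI, a₀₁ = m·p_CEU, a₁₀ = (1−m)(1−p_YRI), a₁₁ = m(1−p_CEU).
It is zero when the parental frequencies coincide or m ∈ {0, 1}, and for a
strong AIM (p_CEU = 0.2, p_YRI = 0.9) at m = 0.2 evaluates to ≈ 0.2755
bits. Values below 1e-14 bits are cleaned to exactly 0 so that the
"δ = 0 ⇒ SIC = 0" identity holds in floating point.

## Panel selection

`select_aims` implements the six-step iterative procedure described in the
README. Points the published description leaves open, resolved here:

- **Conflict order.** When several bin-top pairs violate r² < r2_max, the
  pair with the highest r² (max over the two parental samples) is resolved
  first, with a lexicographic SNP-id tie-break; this makes the outcome
  deterministic and independent of bin iteration order.
- **Tie rule.** Criterion values are compared after rounding to 4 decimal
  places; at a tie the SNP with the larger bp coordinate ("distal", farther
  from pter) is discarded.
- **Pair scope.** All pairs of bin-top SNPs within a chromosome are tested,
  not only adjacent bins.
- **Stopping rule.** Iteration ends when no pair has r² ≥ r2_max in either
  parent, i.e. the final panel satisfies r² < r2_max in **both** parents —
  consistent with the discard condition, which fires on either.
- **r² definition.** Squared Pearson correlation of unphased genotype
  dosages over pairwise-complete samples (composite LD); no phasing is
  assumed. Constant dosage vectors give r² = 0 by convention.
- **Empty bins.** Bins whose candidates are exhausted contribute no marker;
  no cross-bin replacement is attempted.
- Coordinates are 1-based; bin index = floor((bp − 1)/bin_size).

Termination is guaranteed: every iteration removes exactly one SNP from a
finite pool. The whole algorithm is cross-checked against an independent
brute-force re-implementation (no caching, full recomputation per
iteration) on fixtures with planted duplicate columns and exact ties.

VIF pruning removes, within each sliding window of retained SNPs, the SNP
with the largest VIF = 1/(1−R²) while any VIF exceeds the maximum, where R²
is the least-squares multiple correlation of a dosage column on the other
window columns (mean-imputed, centered; exact collinearity gives infinite
VIF, so duplicate columns lose exactly one copy — the distal one on ties).
Windows never span chromosomes.

## QC

Filters run in a fixed order — sample call rate, SNP call rate, MAF, exact
HWE — each on the already-filtered data, all thresholds inclusive (defaults
0.95 / 0.95 / 0.01 / 1e-3). The HWE test is the exact conditional test
(sum of probabilities of heterozygote counts no more probable than the
observed one, given the allele counts), computed in log space and verified
against exact rational enumeration; a chi-square test would misbehave at
MAF near the 0.01 boundary. HWE is computed per dataset on all retained
samples; monomorphic sites return p = 1.

## Local-ancestry inference and map power

Posteriors come from scaled forward–backward over the 4-state diploid
chain, vectorized across individuals, and are marginalized to the unordered
European allele count k ∈ {0,1,2}. Evaluation between markers augments the
chain with emission-free grid loci (default spacing 1 cM), so grid
posteriors are exact chain marginals rather than linear interpolations of
marker posteriors. Forward–backward is verified against exhaustive
enumeration of all 4^L hidden paths (max |Δ| < 1e-8 for L ≤ 6).

Fitting alternates (twice) an m fixed-point — set each m̂_j to the
posterior mean European haplotype fraction over markers, iterate to
|Δm̂| < 1e-4 — with a bounded 1-D likelihood search for λ on [0.5, 50]
(xatol 0.02). m̂ is initialized by a per-individual least-squares moment
estimator from mean dosages. **Limitation:** the fixed-point update is an
exact EM step only for unlinked loci; with linked transitions the
likelihood can decrease by a relatively tiny amount mid-path (observed:
single steps of ~0.2 on log-likelihoods of ~3×10⁴). The first step always
ascends and the net change is positive; the tests assert exactly that.
Estimates target the *realized* genome ancestry fraction; on short genomes
the latent Beta draw and the realized fraction differ materially, which is
why the simulator's default map is human-scale (22 autosome-like
chromosomes, ≈35.4 Morgans total — at λ = 7 the latent-vs-realized gap is
≈0.02, within the recovery tolerance).

Numerical guards: parental frequencies are clamped to [1e-4, 1−1e-4] so no
genotype has zero likelihood under either ancestry; m is clamped to
[1e-6, 1−1e-6].

Map power: X_ij is the Shannon entropy (bits) of the posterior q_ij, G_j
the entropy of the prior ((1−m̂_j)², 2m̂_j(1−m̂_j), m̂_j²), and
r_i = 1 − Σ_j X_ij / Σ_j G_j, clamped to [0,1]. The ratio-of-sums
aggregation (rather than a mean of per-individual ratios) is numerically
stabler when some G_j ≈ 0; both forms satisfy the endpoint conditions
r_i = 0 when X_ij = G_j for all j and r_i = 1 under perfect information.
1/r_avg is reported to 2 decimals as the sample-size inflation factor.

## Mapping statistics

The locus-genome statistic is case-only: with ρ = (1, ψ₁, ψ₂) over African
allele counts (ψ₂ = 2.80 default, ψ₁ = √ψ₂ multiplicative), each case
contributes log₁₀ of (posterior · ρ)/(prior · ρ) and the LOD is the sum
over cases — the likelihood-ratio statistic divided by 2 ln 10. A single
fixed risk model is used rather than averaging over a model set. The
case-control statistic is a reconstruction: per-individual deviation of
posterior-mean local African ancestry from genome-wide 1 − m̂_j, compared
between groups with a Welch-type standard error (sample variances, ddof 1);
zero variance in both groups defines z = 0. Its null behaviour is
established by simulation: pooled |z| > 1.96 rate within [0.02, 0.09] and
genome-wide max LOD < 2 in ≥ 80% of 50 null replicates; a spiked ψ₂ = 2.8
locus is localized by the max-LOD grid point to within 5 cM in ≥ 80% of
replicates with 500 cases drawn from a 4,000-individual pool (a large pool
keeps weighted case sampling from saturating the ancestry-risk signal).

## Simulator: what it does and does not emulate

Parental panels draw per-SNP frequency pairs from two presets: `"aims"`
(δ ~ U(0.6, 0.8), mean frequency uniform over the feasible range — the
profile of a selected AIM panel) and `"random"` (Balding–Nichols with
F_ST = 0.075, the CEU–YRI scale, giving mean δ ≈ 0.14 — the genome-wide
spectrum). Genotypes are Binomial(2, p); positions are uniform with
1 cM ≡ 1 Mb. Defaults: 100 individuals, Beta(2, 8) admixture (mean
European ancestry 0.2), λ = 7 generations, human-scale 22-chromosome map.
All randomness flows from one seeded generator; CLI output writes a JSON
sidecar recording the seed.

Deliberately not emulated: coalescent haplotype structure and background LD
(parental SNPs are independent unless the block-correlation mode plants r²
blocks, which exists only to exercise the pruning code), recombination-rate
heterogeneity (the cM→bp map is linear), genotyping error beyond uniform
missingness, and X-chromosome hemizygosity (the X is treated as diploid
throughout). Consequently, passing tests demonstrate correctness of the
algorithms under the hybrid-isolation model, not robustness to model
misspecification on real data — e.g. real background LD would make the
independence between markers assumed by the HMM optimistic, and continuous
gene flow would bias λ̂.

Phenotypes under a risk locus are sampled without replacement with weights
ψ₂^(k_African/2) at the SNP nearest the locus; with a sampling fraction
well below 1 the realized case risk ratio (k = 2 vs k = 0) stays within
[2.3, 3.3] of the nominal 2.8.

## Other design choices

- Strand handling in `harmonize`: the first dataset fixes orientation;
  others may match directly, swapped (dosage 2−g), or on the opposite
  strand; strand-ambiguous A/T and C/G SNPs are kept only on an exact
  ordered match, since swap and strand flip are indistinguishable there.
- PED carries no allele orientation; the reader orients lexicographically.
  VCF stores the genetic-map position in an `INFO CM=` field (String-typed
  so it round-trips at full precision); EIGENSTRAT `.snp` stores Morgans.
- `random_panel` uses Python `round()` on fraction × N (so 10% of 21,637
  ids yields 2,164) and a seeded NumPy generator.
- Panel summaries exclude adjacent-marker gaps whose physical interval
  overlaps a centromere; without a centromere table all gaps are included
  and the summary is flagged.
- Problem sizes in the test suite (e.g. 50 null replicates at n = 200;
  20 localization replicates at 500 cases from a pool of 4,000; 2,000-SNP
  panels for the map-power ordering) were chosen as the smallest designs
  at which the Monte-Carlo bands above are stable.
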