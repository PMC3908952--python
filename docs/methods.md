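# Methods

## Calling model

Genotype likelihoods are diploid two-component mixtures per read (see the
README for the formulas). Two conventions exist in the field for the
probability of observing a specific non-matching base given the true allele:
`e` (the quality already states "this base call is wrong") and `e/3`
(spreading the error uniformly over the three possible miscalls). This
package uses the `e` convention. It keeps the heterozygote likelihood at
exactly 0.5 per informative read — the symmetry that makes the printed PL
triples interpretable (a 36-read pileup with 4 alternate reads at BQ 30 /
MQ 60 yields PL₀ = −10·(32·log₁₀(0.999/0.5) + 4·log₁₀(0.001/0.5)) ≈ 12 in
the independent mode, matching the published genotype likelihoods for the
mosaic carrier) — and it is the convention under which the sensitivity sweep
calibrates onto the published per-depth averages. Under `e/3` the simulated
sweep is uniformly too sensitive (flat mean ≈ 9.8% instead of ~13%) for any
dependency coefficient.

QUAL is defined as −10·log₁₀ P(k=0 | D, F) *including the prior*. This is
validated by the worked examples: PL₀ = 185 under the full θ=0.001 prior
gives QUAL 155 = 185 − 10·log₁₀(φ₀/φ₁), exactly as printed, and the same
definition reproduces 185/183/165/176 and 12.3/10.6/4.57/0.0684 across the
other prior settings.

The call decision uses the complement posterior mass: a site is called when
P(k>0 | D, F) > 1 − p. In exact arithmetic this is identical to
P(ref | D, F) < p, but it keeps the p = 1 contract ("emit every site with
any variant evidence") exact when P(ref) rounds to 1.0 in double precision
at high depth.

## Error dependency and calibration

The correlated mode ranks the reads within each observed-allele class by
descending base quality and discounts the i-th read's quality to q·η^i.
This emulates the diminishing evidential value of stacked identical calls
caused by correlated sequencing/alignment error. η is a calibration
parameter:

* `ErrorModelConfig` defaults to η = 0.83, the classical dependency default
  for real reads with heterogeneous qualities.
* The sensitivity sweep uses η = 0.985 (`sensitivity.CALIBRATED_ETA`),
  calibrated once by scanning η ∈ (0, 1] and minimizing the joint distance
  of the sweep means to the published averages (13% flat, 16.9% default
  over depths 4–100), then frozen. For the simulator's indel-free,
  constant-quality reads the optimum sits just below the independent limit;
  with the frozen value the sweep reproduces means of 11.9% / 15.5% and the
  exact depth-4 endpoints 25% / 50%. The residual ~1–1.4 percentage-point
  shortfall against the published averages is attributable to the
  original pipeline's internals (BAQ, per-strand error bucketing and its
  exact dependency recursion) that are not described in enough detail to
  replicate; the ordering, endpoints and significance structure of the
  comparison are insensitive to it.
* η = 1 reproduces the independent mode exactly (a tested invariant).

BAQ (probabilistic realignment) is deliberately a no-op: every simulated and
fixture read is an indel-free 100M alignment, where realignment leaves base
qualities unchanged. Externally BAQ-adjusted qualities can be supplied
directly in the pileup TSV.

## Priors

* **full**: neutral Wright–Fisher, φ_k = θ/k (k ≥ 1), φ₀ = 1 − θ·H_M;
  requires θ·H_M < 1. Default θ = 0.001.
* **cond2**: the spectrum induced by the allele-frequency density 2(1 − f),
  φ_k = 2(M+1−k)/((M+1)(M+2)). The general-M form was chosen because at
  M = 2 it yields (1/2, 1/3, 1/6), which reproduces the printed cond2 QUALs
  (10.6 and 183) exactly.
* **flat**: uniform over k.

Per-site calling applies the prior vector directly; EM refinement
(φ_k ← mean over sites of P(k | D_s, φ)) is an explicit, optional step with
defaults tol = 1e−6, max_iter = 100. Non-convergence warns rather than
raises, returning the last iterate flagged `converged=False`.

## Multi-sample calling

P(D | k) is computed by sequential convolution of per-sample polynomials
Σ_g C(2,g)·L_i(g)·x^g, divided by C(2n, k) — never by enumerating the 3^n
genotype vectors (enumeration is retained only as a test oracle). Each
sample's likelihoods are max-normalized first, so the computation is stable
for arbitrary sample counts. Per-sample genotypes are re-scored as
argmax_g L_i(g)·w_g with Hardy–Weinberg weights at the posterior-mean
allele frequency f̂ = E[k|D]/2n; ties break toward the
reference-preferring lower genotype. GQ is min(99, round(−10·log₁₀(1 − max
genotype posterior))); the genotype-confidence values printed alongside the
published QUALs are not exactly reproducible by any simple posterior
formula, so GQ is reported but not treated as a validated surface.

## Simulator

A pure function of (depth, n_alt, spec): no randomness. Defaults follow the
simulated-data description — 100 bp paired-end reads, base quality Phred 30,
mapping quality Phred 60, the mismatch at query offset 50 ("the middle of
the read", MD:Z:50G49 against a reference G), strands alternating +/− within
each allele class (odd classes place the extra read on +), proper-pair flags
(99/147), mates one 300 bp insert away so they never cover the site. The
reference is a repeating ACGT pattern (no homopolymers) with G forced at the
site. Mutant fractions are realized as integer alternate-read counts
n_alt = 0..⌊d/2⌋ per depth d (the per-depth minimum-VAF curve is a series of
spikes at the depths where an additional alternate read becomes necessary,
which implies integer counts); a 1% VAF lattice can be mapped onto counts by
rounding if needed.

What the simulator does *not* emulate: sequencing errors in non-focal reads,
indels, quality heterogeneity, GC/coverage bias, duplicate reads, and
misalignment. Passing sweeps therefore demonstrate the prior/threshold
arithmetic of the caller under idealized evidence, not robustness to
artifacts — that is exactly the controlled comparison the sensitivity
experiment requires, and why the hard-filter tiers exist for real data.

## Sensitivity evaluation

For each configuration (default full θ=0.001 p=0.5; flat; cond2; θ=0.01;
θ=0.1; p=0.75; p=1.0) and each integer depth 4..100, alternate counts are
scanned ascending and the first called count recorded with its QUAL.
Summaries (mean/min/max) aggregate over depths with a detection at ≤ 50%
mutant fraction (all depths, for every shipped configuration).
Configurations are compared with the two-sided Wilcoxon signed-rank test on
the paired per-depth minimum percentages: zero differences dropped, exact
null up to 25 pairs, continuity-corrected normal approximation above. The
whole seven-configuration sweep is deterministic and runs in roughly a
second.

## Hard filters

Tier 1 (moderate): QUAL ≥ 10 (90% base-call accuracy), DP ≥ 4, alternate
reads ≥ 2, strand-bias P ≥ 1e−4, base-quality-bias P ≥ 1e−100, tail-bias
P ≥ 1e−4, HWE P ≥ 1e−4, and exclusion of sites within or adjacent to
(interpreted as within 1 bp of) repeats, including homopolymers ≥ 5 bp.
Tier 2 (stringent): ≥ 3 alternate reads on both strands combined with ≥ 1 on
each, all four bias P ≥ 0.01, and exclusion of user-flagged
artifact-prone genes. Tiers are evaluated independently. Strand bias is a
two-sided Fisher exact test on the allele × strand table; the other biases
are two-sided Welch t-tests between reference- and alternate-supporting
reads (Mann–Whitney available as an option), with any group of size < 2
giving P = 1. The tail statistic is the distance from the nearer read end.
HWE uses a 1-df chi-square against expected counts at the estimated allele
frequency; vacuous (n ≤ 1 or monomorphic) cases return 1. Novelty is
consumed as a precomputed boolean; database filtering and functional
annotation are out of scope.

## Numerical policy and degenerate inputs

All posterior work is done after max-normalizing likelihoods; probabilities
are renormalized before output. PL rounding is half-away-from-zero, clamped
at 0. Empty pileups yield the uninformative likelihood (0,0,0)/PL (0,0,0),
so the no-data posterior equals the prior. Third-allele observations
contribute the error term to both mixture components (an overall shift that
cancels in PLs); the alternate allele at a triallelic site is the non-
reference allele with the highest base-quality sum, ties alphabetical.
QUAL is floored at 0 and the non-variant posterior at 1e−320 before taking
logs.

## Known limitations

* Indels, haploid/sex chromosomes and physical phasing are out of scope.
* The correlated-error mode is a one-parameter emulation of error
  dependency, not a reimplementation of any specific caller's recursion;
  its η is meaningful only relative to this package's mixture model.
* With error probabilities clamped at 0.75, reads whose discounted quality
  falls below ~1.25 become uninformative rather than counter-informative;
  extremely deep single-allele stacks under strong discounting can
  therefore saturate.
* Real-exome absolute variant counts require the original patient data and
  are not reproducible here; fixtures emulate only the printed read counts
  and PL triples.
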