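# Methods

## Fluctuation analysis

### Model

The mutant-count distribution per culture is a compound Poisson. The number
of mutational events is Poisson with mean m; each event founds a clone whose
final size follows the Lea–Coulson law P(Y = y) = 1/[y(y+1)] (y >= 1), the
deterministic-exponential-growth limit Y = floor(1/U), U ~ Uniform(0,1).
When a fraction ε of the culture is plated, each clone contributes
Binomial(Y, ε) countable colonies. For ε = 1 the count distribution is the
Ma–Sandri–Sarkar (MSS) recursion

    p_0 = e^{-m},    p_n = (m/n) Σ_{i=0}^{n-1} p_i / (n - i + 1),

which we evaluate, for any ε, as the Panjer recursion of the compound
Poisson over the thinned clone-contribution law h_k(ε). The thinning sum
over clone sizes y is truncated with an explicit tail bound
(P(Y > y) · BinomCDF(n_max; y, ε) < 1e-10), so no closed form is assumed for
the partial-plating distribution.

The model has no phenotypic lag, differential mutant fitness, or cell death;
clone sizes are capped at N_t only in the generator (the cap's probability
mass, ~m/N_t, is negligible at realistic N_t).

### Estimation

m is estimated by maximizing the log-likelihood with bounded scalar
minimization started from the zero-class heuristic m_0 = -ln(f_0)/(1-h_0).
95% confidence intervals are profile-likelihood bounds solving
l(m) = l(m_hat) - χ²₁(0.95)/2 = l(m_hat) - 1.9207 by bracketed root finding.
An all-zero experiment yields m_hat = 0 with a closed-form upper bound
1.9207 / [n(1-h_0)]. The mutation rate is μ = m/N_t with the CI endpoints
divided identically; N_t comes from CFU titers and is supplied per
experiment. Rates are compared with a likelihood-ratio test (alternative:
separate μ per experiment; null: shared μ, with m_i = μ·N_t,i), p-values
from the χ²₁ upper tail, and families of comparisons adjusted with
Benjamini–Hochberg (via statsmodels).

Counts at or above a configurable threshold (default 1000) are treated as
right-censored, entering through log P(X >= threshold). This mirrors plating
practice — jackpot plates beyond a few hundred colonies are not accurately
countable — and bounds the O(n²) cost of the count-distribution recursion.
The censored likelihood is exact for the censored observation scheme, so
estimates and intervals remain valid.

### Validation studies

Problem sizes were chosen so each study completes in seconds to a couple of
minutes on one core: CI coverage uses 1,000 simulated experiments of 30
cultures at m = 2, ε = 1 (nominal 95%, accepted within 3 binomial SEs);
likelihood-ratio type-I error uses 1,000 null pairs of 20 cultures at a
shared rate; the partial-plating distribution is checked against 10^6
simulated cultures at m = 2, ε = 0.2, per count class where the normal
approximation is sound (expected class count >= 10); and the MLE is checked
against a nested log-grid search (five refinement stages, agreement to 1e-6
relative).

## Gel-based ribonucleotide quantification

### Procedure

Embedded ribonucleotides render DNA alkali-labile, so RER-deficient genomic
DNA runs as a fragment smear on a denaturing gel. Per lane, working on the
densitometry histogram (image → profile extraction is upstream and out of
scope):

1. a uniform background (default: the 2nd-percentile lane intensity;
   overridable as a constant) is subtracted and negatives clipped;
2. the profile is smoothed with a cubic smoothing spline targeting 40
   effective degrees of freedom. The penalty λ is found by bisection on the
   exact trace of the smoother matrix (achieved df within 0.25, tighter than
   the 0.5 contract), cached per distance grid;
3. ladder-lane peaks (local maxima with prominence >= 5% of the lane
   maximum, refined to sub-grid accuracy by parabolic interpolation of log
   intensity — exact for Gaussian bands; manual positions may be supplied
   for supervised assignment) are paired with ladder sizes largest-size-to-
   smallest-distance, averaged across marker lanes, and d = a + b·ln(sz) is
   fitted by least squares (b < 0);
4. intensity per distance interval at d <= d_max converts to a fragment
   count n_sz = I_sz/sz, because staining intensity is proportional to
   fragment mass; Σ(sz·n_sz) = ΣI holds identically on the kept intervals;
5. the mean fragment size s̄z̄ = Σ(sz·n_sz)/Σ(n_sz) is corrected for
   fragments that migrated past the cutoff: s̄z̄_corr = s̄z̄·exp(-sz_min/s̄z̄),
   exact in expectation for exponentially distributed fragment sizes (which
   uniform nicking produces); breakpoints per genome are N = G/s̄z̄_corr with
   G = 9.28e6 nt of single strand for E. coli MG1655 (4.64 Mbp duplex);
6. ribonucleotides per genome in an RER-deficient sample are
   N_ribo = N_sample - mean(N over RER-proficient lanes of the same gel).
   Negative differences are reported with a warning rather than clamped, to
   keep the differencing semantics visible for QC.

Defaults: sz_min = 500 nt (the cutoff is an analyst's choice made to avoid
the noise-dominated small-fragment end; it is always echoed in outputs),
ladder band sizes come from the run config. Summary tables report, per
strain over replicate gels: mean ± SD per genome; per-Mb and kb-per-rN
computed per replicate then averaged (so kb-per-rN is the mean of ratios,
not the ratio of means); fold difference of means over the wild-type
reference; and an unpaired two-sided Welch t-test against the reference
(scipy). Display rounding: per-genome and per-Mb to integers, folds to 2 dp,
kb-per-rN to 1 dp.

A lane that is identically zero after background subtraction raises a data
error rather than returning an empty profile: such a lane has no signal and
every downstream quantity (mean fragment size, breakpoints) would be
undefined.

### What the generator emulates

The lane generator nicks a *linear* single-strand molecule of length G at
per-nucleotide rate ρ (Binomial(G-1, ρ) distinct positions, uniform), so the
K+1 fragment lengths always sum to G; circular end effects are negligible at
G ≈ 9.28e6. Each lane pools 20 genome equivalents — a deliberately
scaled-down stand-in for the ~10^7 genomes loaded on a real gel, chosen so
per-lane sampling noise of the mean fragment size is small relative to the
pipeline's 10% end-to-end tolerance, as it is in practice. Fragments deposit
mass-proportional intensity at d = a + b·ln(sz) with Gaussian band spread,
constant background, and additive Gaussian noise. Ladder lanes are rendered
with equal mass per band (equimolar loading visibility). The generator does
not emulate lane-to-lane mobility drift, saturation of the imager, partial
RNase H2 digestion, or well compression of very large fragments, so passing
tests demonstrate correctness of the arithmetic and robustness to additive
noise — not robustness to those instrument artifacts.

## Mutation spectra

Substitutions are called from pre-aligned, ungapped isolate sequences
against the reference window (mismatch positions, offset + index, 1-based);
ambiguous bases are skipped. Only positions in the closed interval
[1516, 1717] of rpoB are scored. Calls are collapsed by Watson–Crick
complementation onto six base-pair classes (CG→GC, CG→AT, CG→TA, AT→TA,
AT→CG, AT→GC); CG→TA and AT→GC are transitions, the rest transversions, and
transitions + transversions = total by construction. Percentages are of
total calls (1 dp in reports); an empty spectrum reports absent percentages
rather than zeros. Hotspots are positions carrying at least 5% of all calls
(the threshold is a reporting convention, configurable), sorted by count
then position. A Monte-Carlo contingency comparison between strains is
provided as exploratory plumbing; it is not part of the core procedure.

Isolates with no in-window substitution are simply absent from the call
table; callers tracking identified/assayed denominators should count input
isolates themselves.

## Numerical and design notes

- All generators and studies take explicit integer seeds (or Generators);
  there is no global random state.
- The pmf recursion floors probabilities at 1e-300 before logs; likelihood
  maximization uses xatol ~1e-9 and CI roots xtol ~1e-8·(1+m_hat).
- Calibration requires at least two distinct ladder sizes and a detected
  peak per band; a mismatch raises a calibration error instead of guessing
  the pairing.
- Tab-separated tables with a header row are the interchange format;
  thousands separators are stripped on read. Every CLI run writes a
  manifest.json with stage, inputs, parameters and package version.

## Known limitations

- The fluctuation model excludes phenotypic lag, mutant fitness effects and
  post-plating mutation; estimates under those violations are biased in
  known directions and should be interpreted accordingly.
- The cutoff correction assumes near-exponential fragment sizes; strongly
  non-uniform nicking (e.g., clustered damage) would bias s̄z̄_corr.
- One ε per experiment: platings at mixed dilutions must be converted to a
  single effective plating fraction by the caller.
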