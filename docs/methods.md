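# Methods

## Model

One target species, one marker locus, `K` haplotypes with population
frequencies `π = (p_1, …, p_K)`, `Σ p_i = 1`. Under panmixia the
haplotype counts among the `N_j` contributors to sample `j` are
`n_·j ~ Multinomial(N_j, π)`, so contributor frequencies
`q_ij = n_ij / N_j` satisfy `E[q_ij] = p_i` and
`Var(q_ij) = p_i (1 − p_i) / N_j`. The observed within-sample read
frequencies `f_ij` are assumed conditionally unbiased for `q_ij`; every
noise source downstream of contributor sampling is absorbed into a single
multiplicative inflation `ξ ≥ 1`:

    Var(f_ij) = ξ p_i (1 − p_i) / N_j .

By the CLT this motivates `f_ij ~ Normal(p_i, ξ p_i (1 − p_i) / N_j)` and,
assuming independence across the `k` haplotypes with `0 < p_i < 1`,

    lnL(N) = (k/2) ln N − (k/2) ln ξ − ½ Σ ln(2π p_i(1−p_i)) − (N/2ξ) S,
    S = Σ_i (f_i − p_i)² / (p_i (1 − p_i)),

maximised at `N̂ = ξ k / S`. Unobserved haplotypes (`f_i = 0`, `p_i > 0`)
stay in the sum — absence is informative. Haplotypes with `p_i ∈ {0, 1}`
are kept in the vector for stable indexing but excluded from likelihood
sums (they would divide by zero and carry no frequency information). A
haplotype with reads but reference frequency zero is an error by default
(the reference was estimated without this sample's haplotypes and should
be re-derived); `on_novel="drop"` discards those reads and renormalises.

`N` is treated as a continuous positive parameter throughout: the closed
form is continuous, and rounding before interval construction would
distort coverage. An integer presentation (`ContributorEstimate.n_rounded`)
exists for reporting only.

Key working assumptions, in decreasing order of importance: panmixia (no
population structure, no kin groups — a mother–calf pair at a
mitochondrial locus is one haplotype, not two contributors), ASVs are
real haplotypes (denoise upstream), observation noise is unbiased with
respect to haplotype identity (no amplification bias), and `ξ` is known
or defaulted. `ξ` defaults to 1 and is never estimated internally;
estimates under noisy data with `ξ = 1` are biased low, roughly by the
true inflation factor.

## Confidence intervals

The 100(1−α)% interval is the set of `N` with
`lnL(N) ≥ lnL(N̂) − χ²₁,₁₋α / 2` (1.9207 at α = 0.05). Because `lnL`
depends on `N` only through `(k/2)(ln N − N/N̂)`, the endpoints are exact
multiples of `N̂`: in the ratio `r = N/N̂` the boundary condition is
`ln r − r + 1 = −χ²₁,₁₋α / k`, with one root in (0, 1) and one in
(1, ∞), found by Brent's method to 1e-12 and cached per `(k, α)`. This is
algebraically equivalent to bracketed root finding on `lnL` itself and is
verified against a 0.001-resolution grid scan in the tests. Degenerate
case: `S = 0` (observed frequencies equal the reference exactly) makes
`lnL` increase without bound; such samples are reported `divergent` with
`ci_high = ∞` and a display cap of 1e6 as the point value.

## Ploidy minimum

`k_obs` observed haplotypes imply at least `k_obs` contributors at a
haploid locus and `ceil(k_obs / 2)` at a diploid one; unknown ploidy
(heteroplasmy) disables the bound. The bound is imposed by truncation
after estimation — the point estimate and lower CI bound are raised to
the minimum (`censored_at_min` flags this) — rather than by
reparameterising the likelihood, since it is a logical constraint, not a
probabilistic one.

## Population frequencies from eDNA

`p̂_i = (1/M) Σ_j f_ij` over the `M` samples with any target detection,
each sample weighted equally regardless of read depth (read counts are
compositional; depth-weighting would import library-size artefacts).
When the same data provide the reference and the estimates, the reference
for sample `j` is the leave-one-out mean `π̂^(−j)`, computed through the
identity `(M π̂ − f_j)/(M − 1)` and verified against explicit subset
re-averaging to 1e-12. An optional frequency floor (default 0) pins
near-zero averaged frequencies at a minimum and rescales the rest, for
stability of the downstream division by `p_i(1 − p_i)`; the floor used is
recorded in the output metadata.

## Replicates and extensions

Biological (bottle) replicates of one site are combined by an
equal-weight average of their frequency vectors — consistent with the
equal-weight philosophy above — with read-pooling available behind a
flag; `k_obs` is the union of haplotypes observed across replicates. Two
optional operations extend the core: a method-of-moments estimator
`N = ξ Σ p_i(1−p_i) / Σ (f_i − p_i)²` (this package's own moment-matching
construction, provided for comparison; it ignores per-haplotype
information weights and is generally less efficient — note that for a
two-haplotype locus it coincides with the MLE algebraically), and
multi-locus combination, which sums per-locus log-likelihood curves; the
sum stays in the same one-parameter family, so the joint MLE
`Σ k_l / Σ (S_l / ξ_l)` and its profile interval remain closed-form.

## Simulator

The generator mirrors the physical chain with molecule-level provenance.

* **Contributors**: haplotype iid from `π`; body size and distance
  uniform on configured ranges; optional groups share one distance.
* **Shedding**: expected molecules `shed_rate · size^β` with β = 0.75
  (metabolic allometry); the draw is Poisson — the minimal-assumption
  choice for discrete molecule counts.
* **Decay/transport**: each contributor's molecules survive independently
  with probability `exp(−decay · distance)` (binomial thinning).
* **Bottle replicates**: a fixed fraction (`bottle_volume`) of the pooled
  molecules drawn without replacement (multivariate hypergeometric over
  contributors), independently per replicate from the full pool.
* **Sequencing**: a fixed read count drawn multinomially from the
  bottle's haplotype frequencies, optionally perturbed per technical
  replicate by a multiplicative lognormal term
  `p'_i ∝ s_i · exp(ε_i)`, `ε_i ~ N(0, error)` — keeps probabilities
  positive and is the natural "noise on proportions" choice. No
  amplification bias is modelled.

Two presets define the study conditions. `ideal`: shed rate 1000, unit
sizes, zero distances, no decay, no error, `bottle_volume = 1`, 100,000
reads — the only residual noise is contributor sampling itself (ξ ≈ 1).
`realistic`: sizes and distances uniform on (1, 100), decay 0.01 per
distance unit (the farthest contributor retains e⁻¹ ≈ 37% of its
molecules), 5% lognormal process error, 10% bottle volume, 1000 reads.
Benchmarks draw the true contributor number uniformly on 1–200 per site.
The convergence experiment instead fixes a mean contributor level per
scenario and draws per-site numbers from a zero-truncated Poisson (a site
enters a dataset only when someone contributed), levels
{1, 2, 5, 10, 25, 50, 100}, sample counts {5, 10, 20, 50, 100}, smaller
counts nested as prefixes of larger simulated datasets to reduce
Monte-Carlo noise between curve points.

What the simulator deliberately omits — and hence what passing tests do
not demonstrate about field data: population structure and kinship,
amplification bias and chimeras, false/erroneous ASVs, spatial transport
geometry (distance is a 1-D abstraction), qPCR-style absolute
quantification, and multi-species interactions in the sequencing pool.

## Numerical and design notes

* All randomness flows from one `numpy.random.Generator`; a fixed seed
  reproduces counts, truth tables and CSV outputs bit for bit. File
  writes are atomic (temp file + rename) with `# key = value` metadata
  headers.
* Frequency vectors must sum to 1 within 1e-9; read counts are validated
  as nonnegative integers; zero-read samples are legal objects excluded
  from both `M` and estimation.
* Batch estimation vectorises the closed form and reuses cached CI ratio
  roots per distinct `k`, so 5000-sample experiments run in seconds.
* Estimator sampling distribution: with the reference known,
  `S ≈ χ²-distributed`, so `N̂/N ≈ k/χ²` — a reciprocal-χ² with a heavy
  upper tail. For markers with few informative haplotypes (k ≲ 6) the
  estimator's variance is tail-dominated: samples whose frequencies land
  near `π` by chance produce very large estimates, and moment-based
  summaries such as Pearson correlations over thousands of samples are
  unstable across seeds. Rank correlations or tail-robust summaries are
  more stable descriptions of estimator skill on conserved markers; the
  reported benchmarks nonetheless use plain Pearson correlation with
  divergent estimates excluded and the exclusion count logged.
* In the realistic preset the effective inflation works out to ξ ≈ 1.5
  (size/distance heterogeneity ≈ 1.3×, sequencing ≈ N/reads, error term
  minor). Estimating with ξ = 1 therefore underestimates large `N` and
  the nominal 95% intervals undercover — the expected behaviour when
  downstream noise is unmodelled. The decay constant 0.01 is a package
  default, not a measured quantity; stronger decay concentrates the
  effective contributor pool and degrades estimates further.

## Benchmark problem sizes

The validation script and the acceptance tests use 5000 simulated samples
per estimation benchmark and 20–30 replicate datasets per convergence
cell; the whole validation completes in about a minute on one CPU.
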