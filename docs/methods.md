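# Methods

`codivabc` tests whether a set of co-distributed taxon pairs — one species
sampled on both sides of a shared biogeographic barrier, one locus per pair
— diverged simultaneously or in several temporal pulses. It does so with a
hierarchical Approximate Bayesian Computation (HABC) analysis in the
msBayes tradition: hyperparameters describing the community-level
divergence history sit above per-pair demographic nuisance parameters that
are integrated out by coalescent simulation.

## Model

**Hyperparameters.** A study of *Y* pairs shares Ψ ∈ {1..Ψ_max}, the number
of possible divergence times, drawn uniformly; Ψ times τ₁..τ_Ψ are drawn
iid U(0, τ_max); each pair is independently assigned one class uniformly at
random. Some drawn classes may end up unoccupied; the number of *realized*
distinct times is recorded alongside the drawn Ψ, and both are reported.
The headline dispersion index is Ω = Var(τ)/E(τ) over the *Y* per-pair
times (population variance by default, i.e. dividing by *Y*; a sample-
variance flag is available). Ω = 0 under strictly simultaneous divergence
and grows with temporal discordance; following the source literature, Ω is
treated as the more reliable indicator, with Ψ summaries reported
alongside.

**Per-pair demography.** Each pair follows a two-population
isolation-with-migration (IM) coalescent: two descendant populations of
scaled diversity θ₁ = θ₂ ~ U(θ_min, θ_max) split from an ancestral
population (θ_A = θ/2 by default, configurable ratio) at the pair's τ,
exchanging migrants at rates m₁, m₂ ~ U(0, 2·m̄) where m̄ is the
configured per-barrier mean migration rate (typically an IMa estimate
supplied as prior information); a uniform prior with matching mean is the
least-structured way to honour a mean-only constraint.

**Time and rate scaling.** All times are in units of the expected pairwise
coalescence time of a reference population with θ_ref = θ_max/2. A
population with diversity θ and locus rate multiplier ρ has pairwise
coalescence rate ρ·θ_ref/θ per unit time, and mutations fall per site per
lineage at ρ·θ_ref/2 per unit. Consequences used as test oracles:
within-population E[π] = θ (independent of ρ); for two samples in one
population E[TMRCA] = θ/θ_ref units; with no migration,
dE[π_net]/dτ = ρ·θ_ref. The multiplier ρ (default 20 for mtDNA, 1 for
cpDNA/ITS) therefore makes fast loci accumulate divergence 20× faster over
the same τ, which is how rate disparity between marker types is
accommodated in a joint analysis.

**Mutation model.** Finite sites, length L, 4-state kernel with
transition/transversion parameter κ (default 4) and uniform base
frequencies (K80 form). Divergent mtDNA violates infinite sites, which is
why a finite-sites model is used. Each branch can be realised either by
explicit Poisson mutation events or by sampling every site from the exact
finite-time K80 transition probabilities; the two are
distribution-identical (sites are independent given the genealogy) and the
simulator picks whichever needs fewer random draws. One child branch of
the root is folded into its sibling (valid by reversibility and
stationarity of the chain). Sub-models the engine does not include:
recombination, post-divergence bottlenecks or growth, linkage between
loci.

## Summary statistics

Per pair: π within each population (mean pairwise difference proportion,
missing data excluded pairwise), π_b between populations, net divergence
π_net = π_b − (π₁+π₂)/2 (an exact identity of the vector), Watterson's
θ_W per side, and Tajima's D per side (NaN sentinel when undefined: S = 0,
n < 3, or n = 3 where the variance constants vanish identically). Across
pairs: the mean and population variance of each statistic. NaN slots are
mapped to 0 when vectors are compared, identically for observed and
simulated data. Tamura–Nei (TN93) corrected distances (Dx, Dy, Dxy, and
net Da) are computed for observed data with base frequencies estimated
from the pooled compared sequences (configurable); saturation (a
non-positive logarithm argument) raises an error naming the offending
pair.

## ABC engine

A reference table of n_sims hyperprior draws is simulated (the full-scale
configuration is 10⁶ draws with 2,000 accepted; desk-scale analyses and
the test suite use 5×10⁴/500, stated where used). Rejection keeps the
n_accept draws closest to the observed data in standardized Euclidean
distance; ties break by row index and zero-variance columns are dropped
with a warning, so runs are bit-reproducible for a seed.

**Comparison features.** By default the distance runs on 16 across-pair
features: the mean and variance over pairs of each per-pair statistic,
with π_b and π_net first divided by ρ so fast and slow loci are on a
common per-unit-time scale. The rationale is twofold: the hyperparameters
Ψ and Ω are functions of the across-pair τ distribution, so exchangeable
across-pair summaries are the natural comparison; and a fixed, low
dimension avoids the well-known acceptance-rate collapse of
high-dimensional rejection ABC (with the full 8Y+16-column vector the
distance is dominated by θ-matching and the τ-structure signal is
drowned). The raw full vector remains available (`feature_mode="all"`),
and the choice is logged in output provenance.

**Regression adjustment.** Optional (`adjust=True`): weighted local-linear
regression of E(τ), Var(τ) and Ω on the standardized features
(Epanechnikov weights at the acceptance radius), evaluated at the observed
point, adjusted draws clamped to the prior support. Ω mode is a Gaussian
KDE (Silverman bandwidth) maximized on a 512-point grid over the accepted
range; quantiles are empirical (weighted when adjustment weights exist).

**Ψ estimators.** Ψ is discrete; the baseline mode and mean come from
plain accepted counts. Under the unconstrained class-assignment prior the
drawn Ψ label is only weakly coupled to the realized divergence-time
pattern (a draw labelled Ψ = k may realize fewer distinct times), so the
counts-based mode is diluted toward the uniform prior and should be read
as a conservative diagnostic. When adjustment is on, the engine also
reports the multinomial-logit regression mode: P(Ψ | features) fitted by
weighted multinomial logistic regression and evaluated at the observed
point. The categorical fit uses its own, wider kernel tolerance — the
nearest max(n_accept, n_sims/10) draws (capped at 20,000) with
Epanechnikov weights — because a multi-class logit on 16 features needs
far more training draws than the retained posterior sample; regression
tolerances larger than the rejection tolerance are standard in
regression-ABC. The logit mode is the recommended Ψ point estimate and the
one comparable to logit-based Ψ modes in the comparative-phylogeography
literature.

**Conversions.** IMa-style migration estimates are converted to effective
immigrants per generation as θ·m/2 (2Nm of the receiving population under
θ = 4Nμ).

## Synthetic studies

The generator reuses the IM simulator with fixed (not prior-drawn)
parameters and writes FASTA + manifest TSV + a truth JSON. Presets imitate
published barrier-set shapes: 10, 5, 3 and 2 pairs per barrier, a 10-pair
scenario with three divergence pulses, single-locus pairs, mtDNA 20×
faster than cpDNA/ITS, and (for the 2-pair set) per-side sample sizes like
16/6 and 10/11. Defaults elsewhere are n₁ = n₂ = 10 and L = 600 — typical
single-marker phylogeography scale with runtimes in seconds. Per-pair θ
truths (0.004–0.04) span realistic cpDNA-to-mtDNA diversity.

Two presets exist specifically for parameter-recovery checks:
`tuxtlas-like` (Y = 5, one pulse at τ = 1.5) and `pulsed-like` (Y = 8, two
pulses at τ = 0.3 and 2.5). Both use predominantly slow (cpDNA/ITS-scale)
loci by design: at mtDNA rates under the study-scale θ_ref, expected
divergence exceeds ≈1.6 substitutions/site per τ unit, so any τ beyond
roughly 0.5 lies past mutational saturation and carries almost no
divergence-time information — a genuine limitation of deep mtDNA
comparisons under this scaling, not of the implementation. The
barrier-mimicry presets (`isthmus-like`, `isthmus2-like`,
`depression-like`) keep realistic mtDNA-heavy rosters.

What the generator does not emulate: base-composition bias, rate
heterogeneity among sites, alignment error, sampling structure within
populations. Passing recovery tests therefore demonstrate correctness of
the inference machinery under the model's own assumptions, not robustness
to real-data violations of them.

## Numerical and edge-case choices

- θ values are floored at 10⁻¹² when building rates; a floored population
  coalesces essentially instantly. θ_ref = 0 yields a mutation-free
  (monomorphic) study.
- Genealogy simulation carries an iteration cap of 10⁷ events and fails
  loudly on pathological parameter draws.
- All τ = 0 gives Ω = 0 by convention (simultaneous at time zero).
- Random-number discipline: one root seed; the hyper-draw stream and each
  pair-simulation seed derive from it by counter-based splitting, so runs
  are reproducible and checkpoints byte-identical.
- Sequences are handled uppercase, U maps to T, and ambiguity codes other
  than N are rejected with their position.

## Problem sizes used by the test suite and acceptance script

Closed-form calibrations use 20,000 replicates (3 Monte-Carlo-SE bands);
the scaling-pin regression uses 3,000 replicates per τ level at
θ_ref = 0.002, L = 4000, compared against the exact K80/exponential
quadrature expectation; prior-recovery uses 20,000 simulated draws;
recovery experiments run 20 seeded replicates at 50,000 simulations / 500
accepted with regression adjustment. The full-scale 10⁶-draw configuration
is a config value and runs unchanged, just longer.

## Known limitations

- Single locus per pair: co-divergence is inferred by ruling out
  differences in coalescent times from one marker; multi-locus extensions
  are out of scope.
- Ψ is intrinsically weakly identified under the unconstrained
  class-assignment prior (a draw labelled Ψ = k may realize fewer distinct
  times); Ω is the more reliable indicator and both raw and realized Ψ are
  reported.
- Saturated loci (deep mtDNA) bound the usable τ range as described above.
- The rejection posterior for Ω without adjustment is conservative
  (prior-contaminated) at desk-scale table sizes; the regression-adjusted
  summaries are the recommended output.
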