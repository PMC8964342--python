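# Methods

## Model

The multi-site neutral model treats `M` local communities (sequencing
samples) as exchangeable samples coupled to one regional metacommunity.
Three layers define the generative process:

1. **Metacommunity.** Relative taxon frequencies β̄ follow a stick-breaking
   (Dirichlet-process) prior with concentration θ, the fundamental
   biodiversity number: θ = ν/(1−ν)·(N−1) for speciation probability ν and
   metacommunity size N.  θ controls regional richness; at θ → 0 a single
   taxon dominates, and expected observed richness grows roughly as
   θ·log(1 + J/θ).
2. **Local communities.** Site *i*'s composition π̄ᵢ ~ DP(Iᵢ, β̄), with
   immigration rate Iᵢ = (Nᵢ−1)·mᵢ/(1−mᵢ).  Large Iᵢ pins the site to the
   regional composition; small Iᵢ lets ecological drift dominate.  Because
   Nᵢ (the census size of the local community) is not observable from
   sequence data, the sample read depth Jᵢ stands in for it when converting
   between mᵢ and Iᵢ — the standard convention in neutral-model fitting, and
   the reason a fitted m is a per-read, not per-cell, quantity.
3. **Observation.** Reads are a multinomial sample of size Jᵢ from π̄ᵢ.
   Marginalizing π̄ᵢ gives the Dirichlet-multinomial likelihood over the
   observed taxa plus one explicit unrepresented-mass category β_u.
   Multinomial coefficients are included so log-likelihood values are
   comparable across count vectors of equal depth.

The forward-in-time picture behind layer 2 is a zero-sum Moran process: at
each event a random individual dies and is replaced by an immigrant from the
metacommunity (probability m) or a local offspring (probability 1−m).  The
package includes this simulator (`forward_hubbell`), and one of the
acceptance checks verifies that its stationary taxon-frequency law matches
the Dirichlet/DP approximation at the matched Iᵢ within total variation
0.05 — the empirical justification for using the DP marginal everywhere
else.

## Inference

A four-step Gibbs sweep targets the joint posterior of (θ, β̄, I, T), where
T_ij is the latent number of immigration "ancestors" (CRP tables) behind the
x_ij reads of taxon j at site i (1 ≤ T_ij ≤ x_ij whenever x_ij ≥ 1):

- θ | S, T: density ∝ θ^S Γ(θ)/Γ(θ+T) · Gamma(θ | α, ζ), with S the observed
  taxon count and T the grand ancestor total.  The unsigned-Stirling factor
  of the exact conditional is constant in θ and dropped.
- β̄ | T, θ ~ Dirichlet(T_·1, …, T_·S, θ); the last component is β_u.
- Iᵢ | Tᵢ, Jᵢ: density ∝ Γ(Iᵢ)/Γ(Jᵢ+Iᵢ) · Iᵢ^{Tᵢ} · Gamma(Iᵢ | η, ν).
- T_ij | x_ij, Iᵢ, β_j ~ Antoniak(Iᵢβ_j, x_ij), realized by sequential
  Chinese-restaurant simulation — O(x_ij) per draw with no Stirling tables,
  which matters at read depths in the thousands.  All cells of a sweep are
  flattened into one vectorized pass over the reads.

The θ and I conditionals are non-standard 1-D densities; both are updated by
slice sampling (stepping-out + shrinkage) in log-parameter space, which is
derivative-free and scale-robust.  The test suite validates both against
grid-normalized densities (KS < 0.02 at 10⁴ draws) and the ancestral-count
sampler against the exact Antoniak pmf (computed from log-space Stirling
numbers, kept as an oracle for n ≤ a few hundred).

**Protocol.** Defaults follow the standard reporting convention for this
sampler: 50,000 sweeps, the first 25,000 discarded, summaries as posterior
medians with 2.5%/97.5% credible limits over the retained sweeps, and every
10th post-burn-in sweep (2,500 parameter sets: θ, I, β̄) stored for the
neutrality tests.  Initialization: β̄ from pooled relative abundances with
β_u = 1/(1+ΣJᵢ), Iᵢ = 10, T_ij at the expected CRP table count rounded and
clamped to [1, x_ij].  A same-seed rerun is bit-identical.

**Priors.** θ and each Iᵢ carry Gamma(shape, rate) priors, default
Gamma(0.1, 0.001).  The shape < 1 keeps the prior diffuse near zero; the
small rate keeps it diffuse *at scale*.  This matters: with a rate of 0.1
the exponential tail is already informative for values in the tens to
hundreds — exactly where θ (~20–170) and Iᵢ (~25–450) live at 16S read
depths — and in self-simulation experiments it dragged the posterior of m
down ~25% and collapsed credible-interval coverage for m to 0/20, versus
~95% nominal coverage with rate 0.001.  All four constants are configurable.

**Reported parameters.** Tables print one m per metacommunity; the pooled
value is the posterior median of the across-site mean of mᵢ (per-site
medians and intervals are also emitted).  The M-value is the across-site
mean of the per-site median Iᵢ — the average median number of immigrants per
local-community generation.

## Neutrality tests

For each stored parameter set k, one replicate dataset is simulated at the
observed depths and compared with the observed data under that same set:

- **Metacommunity level** (full neutral assembly): β̄*ₖ ~ Stick(θₖ) drawn
  fresh, sites simulated from DP(Iᵢₖ, β̄*ₖ), replicate scored under
  (Iₖ, β̄*ₖ); the observed matrix is scored under (Iₖ, βₖ) from the trace.
- **Local level** (local neutrality given an arbitrary regional
  composition): β̄ held at the stored draw, with the unrepresented mass β_u
  re-broken into novel atoms by stick breaking at θₖ before simulation.

pseudo-P is the fraction of sets with L_sim ≤ L₀ (ties count toward the
tail, conservative toward non-rejection; the complement 1−pseudo-P is also
reported for bookkeeping conventions that tabulate the opposite tail).  The
verdict is neutral-compatible when pseudo-P > 0.05.  L₀ is recomputed under
each stored set by default — the construction that makes observed and
simulated likelihoods exchangeable under the null — with a fixed-L₀ variant
(observed likelihood frozen at its across-set median) behind a switch.

Two numerical points proved load-bearing:

- Site simulation uses the exact marginal of sequential Pólya-urn sampling
  from a DP restricted to a fixed atom partition: p ~ Dirichlet(I·β̄),
  counts ~ Multinomial(J, p).  This is identical in distribution to the urn
  and vectorizes.
- Replicates must be scored at full taxon resolution.  Aggregating all novel
  mass into one category inflates simulated likelihoods (a lump of reads in
  one category is far more probable than the same reads split across many
  novel taxa) and makes the local test reject *true* neutral data.  Stick
  truncation uses residual mass 1e-8, far below read-depth resolution.

Calibration, verified in the suite: with parameters known, pseudo-P is
approximately Uniform(0,1); with parameters fitted, it concentrates near 0.5
on neutral data and the pass rate over replicate datasets is ~100%.

**Power limitation.** Posterior-predictive tests of this form compare data
with replicates from *refitted* parameters.  Site-specific multiplicative
selection (the niche control below) is largely absorbed by a lower fitted m
and a compromise β̄, so the test retains little power against it even at
extreme selection strengths; passing the neutrality test therefore shows
compatibility with neutral assembly, not the absence of selection.  This
mirrors the known absence of a Type-II-error guarantee for such tests.

## Synthetic data

The generators emulate the structure of a couple-level semen/vaginal
transmission study whose OTU tables are not publicly archived: 23 couples ×
three sites (semen CM, vaginal before CNA, vaginal after CNB), read depths
log-normal around role means 1,712 (CM) and 2,854 (CNA/CNB).  Defaults:
depth CV 0.3 with a floor of 200 reads (the source reports only means, so
dispersion is a package choice, configurable); θ_true = 50 and m_true = 0.05
per site, matching the scale of estimates typical for such data.  Each
couple draws an independent β̄ ~ Stick(θ) and assembles its three sites at
the Iᵢ implied by m_true and the site's depth.

The **niche control** multiplies the acceptance weight of a random half of
each site's taxa by `niche_effect` (≥ 1, with 1 recovering the neutral null
exactly) and renormalizes, preserving depth while reducing cross-site
compositional similarity.  It raises mean across-site Bray-Curtis
dissimilarity as intended and serves the power analysis discussed above.

What the generators do *not* emulate: sequencing error, chimeras, 16S
copy-number variation, taxonomy (labels are arbitrary integers in
stick-discovery order), or any real within-couple similarity calibration —
no published within-couple statistics exist to match.  Passing tests on
synthetic data therefore demonstrate correctness of the inference machinery
under the model's own assumptions, not robustness to real-data artifacts.

## Pipeline

Samples are grouped into four metacommunity settings per couple —
CM+CNA+CNB, CM+CNA, CM+CNB, CNA+CNB — each fitted and tested independently
(independent chains per couple × setting; chain seeds derive
deterministically from the master seed and the couple/setting indices, so
every cell reproduces).  Taxa are aligned within a couple by label union;
taxa absent from all sites of a grouping are dropped for that grouping only.
Couples missing a role are excluded from the affected settings with a
warning; per-couple failures are recorded and excluded from means, never
silently dropped.  Setting summaries report unweighted means over couples
and passing rates = 100 × #{P > 0.05}/#couples.

Cross-setting comparisons of per-couple m and θ use the Wilcoxon signed-rank
test paired by couple (each setting is measured on the same couples), with
an unpaired Mann-Whitney variant behind a flag.  Raw p-values are reported;
Benjamini-Hochberg-adjusted values are added in separate columns as an
extension.  A self-comparison (all paired differences zero) returns p = 1
with a warning.

## Problem sizes and numerical choices

- Acceptance-style experiments use 5,000-sweep chains (2,500 burn-in, 250
  stored sets) at J = 2,500, M = 3 — sizes at which posterior medians are
  stable to a few percent — and the acceptance script runs 8 couples at the
  study depths with 3,000-sweep chains.
- Coverage experiments count each 95% credible interval separately (θ and
  m); per-interval coverage is the quantity a ≥90% bound can meaningfully
  constrain, since even two perfectly calibrated 95% intervals jointly cover
  only ~90% of the time.
- The forward-Moran validation uses 4,000 replicates in 10
  equal-probability bins so the total-variation estimator's noise floor
  (~0.03) sits below the 0.05 bound being checked.
- Degenerate inputs: a positive count on a zero-mass taxon yields −∞ (an
  impossible observation, distinct from a validation error); β entries below
  1e-300 are floored only when paired with zero counts; log-parameter values
  beyond ±600 are treated as zero-density during slice sampling.
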