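# Methods

`dombayes` is an in-silico workbench for studying how much statistical
power a Bayesian multi-marker association model gains from modelling
dominance.  It has three layers: a forward population/trait simulator, the
BayesC and BayesD mixture-model samplers, and sliding-window WPPA
inference with power/precision evaluation.  This note records the models,
the defaults and why, the numerical choices, and what the simulations do
and do not establish.

## Population simulation

A single chromosome of 1 Morgan is simulated forward in time through a
Fisher-Wright diploid population with random mating (selfing allowed),
Poisson-distributed crossovers (expectation = genetic length per meiosis,
positions uniform on the map) and infinite-sites mutation on a continuous
physical axis.  The genetic-physical map is linear; the default physical
length is 1.6e8 bp, which with the 1e-8 /bp/meiosis mutation rate gives
about 1.6 new mutations per gamete.

**Demography.**  1051 generations: Ne = 600 for the first 650, a
log-linear decline to Ne = 100 by generation 1000, a constant phase at
100, and a final expansion in which 1500 individuals are generated as one
offspring generation of the last breeding population (the only way to
obtain 1500 distinct individuals from Ne = 100 without resampling
artifacts).  Log-linear decay keeps the proportional decline rate
constant, with the approach to Ne = 100 happening over the last
generations.  The decline window and the physical length are the two
genuinely open parameters of this protocol; they were fixed jointly, once,
by the protocol's two published diagnostics: the final sample must
segregate ~7k SNPs with MAF > 0.01, and the LD pattern must look bovine
(short-range r^2 near 0.6 decaying steeply to ~0.15 beyond 1 cM), which
is what makes denser marker panels pay off.  The gradual 650-1000 decline
with a 1.6e8 bp genome satisfies both; a decline squeezed into the last
ten generations also yields ~7k SNPs but produces a flat LD curve under
which a 2k panel maps no better than a 0.5k panel, and a 1e8 bp genome
under the gradual decline yields only ~4.4k SNPs.  All of these are
config fields, including an arbitrary per-generation schedule override.

**Founders.**  650 generations at Ne = 600 are far fewer than the ~4 Ne
needed to reach mutation-drift equilibrium from a monomorphic start, so
founder haplotypes are drawn at coalescent equilibrium (msprime, same Ne,
mutation and recombination rates, infinite sites on a continuous genome)
and the stated 1051 generations are then simulated forward.  This is the
standard hybrid initialisation for forward simulators; with monomorphic
founders the final sample would carry only ~3k MAF > 0.01 SNPs instead of
~7k.  Setting `equilibrium_founders=False` (or a zero mutation rate)
reproduces the monomorphic-founder behaviour; explicit founder haplotypes
can also be injected, which the test suite uses to verify the neutral
martingale property of allele-frequency trajectories.

**Marker panels.**  The "7k" panel is all sites with MAF > 0.01 (causal
sites included: it mimics full sequence).  The 2k/1k/0.5k panels take
sites with MAF > 0.03 at approximately equal genetic distances: a uniform
grid of target positions is laid over the map and the nearest eligible,
not-yet-used SNP is chosen for each target (ties towards the lower
position); causal sites are excluded.

## Trait architecture

Each trait has 15 causative loci drawn from the segregating sites with
MAF > 0.05 and pairwise genetic distance >= 2 cM (random-order greedy
placement with restarts, which succeeds whenever a feasible subset
exists).
The joint effect distribution couples dominance to additive size: the
dominance coefficient h = d/|a| is N(0.2, 0.3^2) and a | h ~ N(0,
exp(3h)) (exp(3h) is the conditional variance), so loci with larger
dominance coefficients tend to carry larger additive effects, dominance
is directional (heterozygotes sit above the homozygote mean on average),
and overdominance (h > 1) occurs at the normal-tail rate of ~0.4%.

Breeding values, dominance deviations and genetic values follow the
Falconer decomposition (see the `trait_model` docstrings for the exact
expressions); allele frequencies are fixed at sampling time from the
final-generation sample and reused throughout, and V_A, V_D are the
empirical variances of BV and DV over the 1500 individuals, not
Hardy-Weinberg closed forms.  The residual variance is set so the
narrow-sense heritability is 0.3; when a trait's dominance variance is so
large that this would make V_E negative, the whole trait is resampled
(the event is counted on the returned object).  The expected inbreeding
depression is sum_j 2 p_j q_j d_j.

**A reproducibility caveat.**  Under this protocol — exactly as stated —
the mean dominance-variance fraction of *phenotypic* variance across
traits is ~0.03 and the mean inbreeding depression is ~0.28 phenotypic
SDs.  The study this protocol emulates reports 0.10 (median 0.08) and
0.023 for these two summaries.  We could not find any reading of the
stated distributions that reproduces both printed numbers; notably, the
dominance fraction of *genetic* variance V_D/(V_A + V_D) does come out
near 0.10 with median near 0.08.  The package implements the protocol as
stated and reports the summaries as defined; the two affected
distribution-level checks in the acceptance suite therefore fail against
the printed values, deliberately.  All structural results (power
orderings, precision levels) are insensitive to this labelling question
because the samplers receive the simulated variance components
themselves.

## BayesC / BayesD

The linear model is y = 1 mu + X a + W d + E with X the 0/1/2 mutant
dosage, W the heterozygote indicator, and E ~ N(0, v_e I) with v_e fixed
at its simulated value — variance components and the expected inbreeding
depression are inputs, never sampled.  Each SNP effect is a two-component
scale mixture: important with prior probability pLD (indicator gamma_j),
and the unimportant component is the same distribution scaled by epsilon
= 0.01 (an effects-scale reading: under gamma_j = 0 effect variances are
epsilon^2 times larger-component variances).  Under the large component
|a_j| is folded-t with 2.5 degrees of freedom and scale s_a, the sign is
symmetric, and d_j | a_j ~ N(mu_h |a_j|, sigma_h^2 a_j^2), which makes
|a| and the dominance coefficient independent a priori and is invariant
under the epsilon-scaling (so the conditional is shared by both mixture
components).  No frequency-dependent sign prior is used (nothing is under
selection in the simulations).

**Calibration.**  s_a is moment-matched so the prior-expected additive
variance over the panel equals the input V_A:

    s_a^2 = V_A / [ df/(df-2) * (pLD + (1-pLD) eps^2) * sum_j H_j ],

with H_j = 2 p_j q_j from the panel allele frequencies.  For BayesD,
(mu_h, sigma_h) solve the two-moment system matching the prior-expected
dominance variance (sum_j H_j^2 E[d^2], with E[d^2] = (mu_h^2 +
sigma_h^2) E[a^2]) to V_D and the prior-expected inbreeding depression
(sum_j H_j E[d], with E[d] = mu_h E[|a|]) to the input depression.  If the
system is infeasible (depression demands more second moment than V_D
allows) the dominance-coefficient prior falls back to (0.2, 0.3) — the
generating values — and the spec is flagged.  pLD follows the density
schedule pLD = 5.5 * 0.7^t * 15 / M with M = 250 * 2^t.

**Sampling.**  One Gibbs cycle updates the intercept, then each SNP in
fixed ascending order (reproducibility over randomised sweeps), then the
per-SNP latent t-scale.  The t prior is the standard normal scale-mixture
augmentation: a_j | psi_j ~ N(0, c_j psi_j) with c_j in {1, eps^2} and
psi_j ~ ScaledInv-chi2(df, s_a^2).  In BayesC, (gamma_j, a_j) has a
conjugate normal-mixture full conditional.  In BayesD, d_j | a_j is
conjugate normal, and (gamma_j, a_j) | d_j is updated by a Metropolis
step proposing from the BayesC full conditional and accepting with the
dominance-prior density ratio — the proposal cancels everything except
p(d_j | a_j), so the acceptance probability is exactly that ratio and the
kernel leaves the posterior invariant.  Correctness is enforced by
prior-reproduction tests: with the likelihood switched off the chain must
reproduce the analytic prior (inclusion rate, folded-t quantiles of
a | gamma=1, epsilon ratio of the component scales, and the N(mu_h,
sigma_h^2) law of d/|a|).  Quantiles are used instead of the raw second
moment because a t with 2.5 df has no finite fourth moment, so a sample
variance has no usable standard error.

The default chain is 20,000 cycles, 10,000 burn-in, every 100th sample
stored (100 stored samples).  Implementation notes: genotype rows are
kept as raw int8 and the column-centring is carried algebraically
(centred dot products need only the raw dot, the column mean and the
residual sum, and the intercept folds into a scalar), the working
residual is float32 with a double-precision refresh every 1000 cycles,
and monomorphic columns are skipped with their effect pinned at zero.
Identical seeds give bit-identical samples.

## WPPA inference

One window is anchored at every panel SNP (as many windows as SNPs),
spanning a fixed genetic length, half-open [anchor, anchor + size) so
that disjoint tilings never double-count; windows at the chromosome end
are truncated, not dropped.  For each stored sample the window genomic
variance is sum_j [H_j alpha_j^2 + H_j^2 d_j^2] with alpha_j = a_j +
(q_j - p_j) d_j (d = 0 for BayesC).  Its equal-distribution expectation
uses E[alpha^2] = V_A / sum_j H_j and E[d^2] = V_D / sum_j H_j^2 over the
whole panel — the unique normalisation for which the expectations tile to
V_A + V_D genome-wide, which is unit-tested as an exact identity.  The
same expectation, dominance term included, is used for BayesC and BayesD
scans, so their q_w ratios are on a common scale.  WPPA is the fraction
of stored samples with q_w strictly above 1 (ties count as
non-exceedance); a window whose expectation is zero while samples are not
is reported as NaN.

## Power, L-power, precision

A causative locus is detectable when its variance contribution H alpha^2
+ H^2 d^2 exceeds the mean equal-distribution expectation of the
windows (of the configured size) containing it — the same bar that q_w >
1 implies, resolved per window because that is the detection trigger.  It
is "large" when it explains > 2.5% of the trait's genetic variance (V_A +
V_D).  A locus is mapped at a threshold when a window with WPPA above the
threshold intersects the 1 cM flank around it; precision is the extent of
the contiguous cluster of significant windows nearest the locus (lower
bound: the window size; a cluster intersecting two loci's flanks counts
for both).  Power is mapped/detectable per trait, averaged over traits
(the per-trait averaging matches how spreads are reported); L-power
restricts both counts to large loci; traits with no (large) detectable
locus drop out of the respective average.

## Problem sizes used by the shipped checks

The full study design (10 populations x 5 traits x 4 densities x 50
replicates) is deliberately scaled down in the shipped test-suite and
acceptance script, as the package's own verification budget: the power
and precision surfaces use 10 traits (2 populations x 5) with BayesC on
the 2k and 0.5k panels and BayesD on the 0.5k panel; the
trait-architecture summaries use 50 traits on 2 populations; the
sequence-density check uses 3 populations; MCMC settings are never
reduced (always 20,000 cycles).  At this replication the L-power and
precision points carry Monte-Carlo error of roughly +-0.05-0.1, which is
inside the tolerances asserted.

## What the simulations do not show

The generator emulates one idealised chromosome: a single 1-Morgan
segment, neutral evolution (no selection, migration, or population
structure), a linear genetic-physical map, no genotyping error or
missingness, and phenotypes from a purely additive-plus-dominance
genetic architecture with Gaussian residuals.  Passing tests therefore
say nothing about epistasis, structured populations, imperfectly known
variance components (here the samplers receive the true simulated
values), or multi-chromosome genomes.  Known limitations: pLD is never
estimated from data; BayesD mixing degrades when a large dominance
effect sits on a near-zero additive effect (the Metropolis step must
drag |a| through the origin); and the equal-distribution expectation is
a reconstruction from its defining property (genome-total = V_A + V_D),
not a transcription of a published derivation.
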