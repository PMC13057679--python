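# Methods

`idload` implements a pedigree-based analysis of inbreeding depression that
goes beyond a single global depression slope: each ancestor that causes
inbreeding in its descendants carries its own *inbreeding depression load*
(IDL), a random genetic effect expressing how much phenotypic change that
ancestor's hidden recessive burden produces per unit of partial inbreeding.
This note documents the models, algorithms, parameter choices and numerical
conventions, and what the synthetic-data tests do and do not demonstrate.

## Inbreeding coefficients

**Wright's F** is the probability that an individual carries two alleles
identical by descent (IBD) at a random locus, equal to half the additive
relationship between its parents.  `meuwissen_luo_F` computes it through the
decomposition A = L D L′ of the numerator relationship matrix: for animal
*x* with parents *s* and *d*,

    F_x = ½ a_sd = ½ Σ_j d_j L_sj L_dj,

where L rows (expected genome contributions of ancestors) are built by a
sparse upward traversal and d_j is the Mendelian-sampling variance of
ancestor *j*.  Animals with any unknown parent get F = 0.  The dense
recursive tabular method (`tabular_relationship`, guarded at 5,000 animals)
serves as the exact oracle; the test suite checks elementwise agreement to
1e−12 on random pedigrees.

**Mendelian-sampling variances.**  d = 0.5 − 0.25(F_s + F_d) with both
parents known and d = 1 for founders.  For an animal with exactly one known
parent we use d = 0.75 − 0.25 F_known.  This single-known-parent convention
is a declared design choice (several are defensible); it is validated
internally by the requirement that the Henderson/Quaas A⁻¹ assembled from
these d terms satisfies A⁻¹A = I to 1e−8 against the tabular A on pedigrees
with randomly masked parents.

**Recent inbreeding F6** is F recomputed on the pedigree truncated six
meioses behind each individual (focal = generation 0).  Truncation is
per-individual and meiosis-based, matching the per-animal "up to the sixth
generation" definition used by studbook software; a global
truncation-by-birth-cohort interpretation was considered and rejected.
When an ancestor is reachable at several depths the *minimal* distance
decides whether its parents are retained.  Inbreeding loops that close
beyond six meioses contribute F > 0 but F6 = 0 (the `deep_loop` fixture).

**Ancestral inbreeding F_k** (Kalinowski) is the probability that an
individual is autozygous for an allele that was already IBD in at least one
earlier generation — the part of current inbreeding that has been "tested"
by past homozygosity and is the natural quantity for purging arguments.  It
is estimated by gene dropping: every founder allele gets a unique label,
alleles are transmitted down the pedigree by fair coin flips, an animal is
autozygous when its two copies share a label, and every copy carries an
"IBD happened here" flag set when its carrier was autozygous and inherited
by transmitted copies.  F_k(x) counts replicates where x is autozygous
*and* an inherited copy was flagged in a strict ancestor; the focal
animal's own autozygosity flags its copies only for descendants.  The
strict-ancestor convention is declared (the flag-propagation variant is not
uniquely standardised).  Default 100,000 replicates, binomial standard
errors, replicate-chunked so memory stays bounded; the estimator is checked
against exhaustive enumeration of all Mendelian transmission patterns on
≤8-meiosis pedigrees.

## Partial inbreeding F_ij

The same LDL′ identity decomposes each animal's F exactly into
per-ancestor terms,

    F_ij = ½ d_j L_{s(i),j} L_{d(i),j},

one for every common ancestor *j* of the two parents — founders through
their founder term, non-founders through their Mendelian-sampling term.
This realises the García-Cortés/Casellas partition deterministically; a
Monte-Carlo alternative was rejected because exact conservation
(Σ_j F_ij = F_i, tested to 1e−10 pre-threshold) is the primary test
surface.  Entries ≤ 1e−5 (the conventional reporting cut) are dropped from
storage but tracked as per-animal discarded mass, so conservation can
always be verified.

## The IDL animal model

Phenotypes follow

    y = f c + X b + W h + R r + Z u + K i + e     (full form, gait traits)
    y = f c + X b + Z u + K i + e                 (reduced form, defects)

with f the per-observation total inbreeding, c the global depression slope,
b fixed effects (dummy coding, first level dropped, intercept always
present) plus covariates, h permanent-environment and r rider effects
(i.i.d. normal), u additive genetic values and i ancestor-specific IDL
effects.  The joint prior is (u, i) ~ N(0, G ⊗ A) with
G = [[σ²_u, σ_ui], [σ_ui, σ²_i]]; both u and i are indexed over *all*
pedigree animals, as the Kronecker prior requires.

IDL effects reach phenotypes through **K = T(I − P)**: T holds the scaled
partial coefficients (each F_ij × `fij_scaling`, default 10, so σ²_i is
referenced to a partial inbreeding of 10%), and P links every animal to its
sire and dam with 0.5.  The (I − P) projection removes the parent-average
(transmissible) part of i, so each ancestor enters through its own
Mendelian-sampling deviation; a non-inbred animal's K row is exactly zero.

**Sampler.**  Single-site Gibbs, numba-compiled.  Fixed effects and c use
improper flat priors; scalar variances use scaled inverse-chi-square full
conditionals with the improper choice ν = −2, scale 0 (flat on the
variance); G uses an inverse Wishart full conditional with scale
[[u′A⁻¹u, u′A⁻¹i], [i′A⁻¹u, i′A⁻¹i]] and the improper ν = −3, zero-scale
prior (flat on G).  Proper priors are configurable for small-n stability.
The sparse A⁻¹ (Henderson/Quaas) makes each (u, i) scalar update touch only
an animal's observations and its A⁻¹ row.  Numerical guards: a 1e−10
relative ridge keeps the Wishart scale positive definite in the first
sweeps; a non-PD G draw is retried (25 attempts) before keeping the
previous value; a residual variance leaving the representable range aborts
with a diagnostic.  Chains are bitwise-reproducible per seed.

**Chain sizes.**  The default desk-scale chain is 50,000 iterations with
5,000 burn-in and thinning 10 — sized so a 600-animal fit runs in seconds
and full recovery studies in minutes on one CPU; production-scale chains
(e.g. 1,000,000/20,000) are a configuration change.  Convergence tooling:
running means, trace access, and a simple autocorrelation-based effective
sample size.

**Posterior summaries.**  Ratios are computed per draw and then
summarised: with σ²_p = σ²_u + σ²_i,ref + (σ²_h + σ²_r when present) +
σ²_e, heritability h² = σ²_u/σ²_p, IDL ratio d² = σ²_i,ref/σ²_p and
repeatability (σ²_u + σ²_h)/σ²_p, where σ²_i,ref = σ²_i · (0.1 ·
fij_scaling)² is the IDL variance on the per-10%-partial-inbreeding
reference.  That conversion (the identity at the default scaling) is what
makes d² invariant to the arbitrary F_ij multiplier, which the tests
verify by refitting at a different scaling.  HPD95 intervals are shortest
sample intervals.  Because a posterior mean of a ratio is not the ratio of
posterior means, summaries assembled from separately summarised components
can differ in the second decimal.

**Ordinal defect scores** (1–3) are fitted as Gaussian on the observed
scale, exactly like the continuous traits; a threshold-model variant is out
of scope.  Variance components for such traits are attenuated relative to
the latent scale, which the recovery tests on ordinal traits make visible.

## Screening regressions

Before the animal model, each trait is regressed on each inbreeding
coefficient alone: OLS with a two-sided t test for continuous traits;
proportional-odds logistic regression (statsmodels' ordered logit, the
`polr` parameterisation P(Y ≤ k) = logistic(ζ_k − b·f)) with an asymptotic
z test for ordinal scores.  Positive b means inbreeding shifts mass toward
worse defect classes.  Inbreeding is on the proportion scale (0–1)
throughout.  No covariate adjustment — these are single-predictor screens.
When the IDL variance dominates, ancestor-specific loads of either sign
inflate the residual around the global slope, so these screens can be
underpowered relative to the animal model; the synthetic study shows this.

## IDL diagnostics

The favourable-animal rule regresses posterior-mean IDL on F and evaluates
the fitted line at a reference inbreeding of 10%; animals strictly beyond
that threshold in the trait's favourable direction (higher IDL for
dressage-like traits, lower for defects — configuration, never inferred
from data) count as favourable.  The threshold rule is pluggable because
the reference-level construction can reasonably be defined in more than one
way; the regression-line evaluation is the default.  Cross-trait Pearson
correlations use animals with both traits defined; coincidence counts
animals favourable in both traits of a pair.  Cohort trends are plain
birth-year (or binned) means emitted as a tidy table.

## Selection indices

Hazel–Lush machinery on a unit genetic scale with heritability-based
accuracy ρ = √h² (own-performance accuracy — the choice that reproduces
intensity·√h² for the EBV-only index).  Estimated criteria have variance
ρ²σ²_g and covariance ρ²σ²_g with their own true value; the cross trait
enters through the EBV–IDL genetic correlation r, which is an *input*
(e.g. the posterior G), because it is generally not published.  Index
weights are b = P⁻¹ G_m p′ and the expected genetic response on the EBV
objective is i·(G_m′b)/√(b′Pb).  In this parameterisation P = G_m over the
criteria, so b reduces to the economic weights; Index 2 places all
selection emphasis on the IDL criterion, making its EBV response
i·ρ·r — negative when EBV and IDL are negatively correlated, which is the
policy-relevant case.  Relative responses are signed percent differences
with Index 1 fixed at 100%.

## Synthetic data

`simulate_pedigree` builds a generation-structured pedigree in which each
mating is, with configurable probability, between full or half sibs —
creating the recent and ancestral inbreeding a closed studbook accumulates.
Default study conditions (60–80 founders, 5–6 generations, close-mating
probability 0.4) give roughly half the population inbred with mean F among
inbred animals around 0.06–0.12, in the range a closed horse studbook
shows.  `simulate_phenotypes` is the forward model: (u, i) are sampled
jointly down the pedigree by bivariate Mendelian sampling (founders
~ N(0, G); non-founders = parent mean + N(0, d_x G)), which is exact for
the G ⊗ A structure and O(n); records then add fixed effects, rider and
permanent-environment draws, the global slope c·F, the IDL contribution
K i and residual noise.  Default truth (σ²_u = 0.3, σ²_i = 2.0 on the 10%
reference, σ²_e = 0.5, c = −0.7) puts most genetic variance in the IDL
term, the regime the model exists for.  Ordinal thresholds default to a
majority-class-1 mix for the defect-like trait.

What the generator does *not* emulate: founder imbalance and historical
bottlenecks of a real studbook, selection (matings are random given the
close-mating rule), judge/venue network structure, missing-data patterns,
and genotype-level processes (true loci, dominance).  Passing recovery
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to their violation.

## Known limitations

* Fitting ordinal scores as Gaussian biases components toward the observed
  scale; only the latent-scale generator truth is attenuated, not wrong.
* The global slope c is weakly identified when few phenotyped animals are
  inbred (its posterior is honest about this — wide).
* Single-site Gibbs mixes slowly for the confounded (h, u) pair with few
  repeated records; the desk-scale defaults were chosen with thinning 10 so
  stored draws are close to independent for the variance components.
* No phantom-parent grouping, no genomic relationships, no multi-trait
  joint model (traits are fitted separately), no REML alternative.
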