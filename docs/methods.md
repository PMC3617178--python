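# Methods

`twinfam` implements a bivariate nuclear twin family (NTF) model for two
standardized traits — trait1 is IQ-like, trait2 is height-like throughout —
observed on monozygotic (MZ) and dizygotic (DZ) twins, their non-twin
siblings, and their parents, with assortative mating modelled explicitly.

## The structural model

Each individual's trait vector is a sum of latent 2-vectors, each entering
through a 2×2 lower-triangular path matrix (the Cholesky factor of that
component's contribution):

    P = a_x A + b B (males only) + d_x D + s_x S + t_x T + e_x E
        (+ F under vertical transmission, + c_x C under social homogamy)

- **A** — additive genetic factors shared between the sexes, latent
  covariance `q` (identity under random mating);
- **B** — male-specific additive genetic factors (qualitative sex
  limitation of A), latent covariance `q_b`;
- **D** — dominance (non-additive) genetic deviations, shared 1 by MZ
  co-twins and ¼ by other full siblings;
- **S** — sibling environment, shared by all siblings but not parents;
- **T** — twin environment, shared only by co-twins;
- **E** — unique environment, independent across individuals;
- **F** — environment transmitted from parental phenotypes,
  `F_offspring = v_fs P_father + v_ms P_mother` (daughters analogous), with
  no residual — which is exactly why S and F are not jointly identified and
  only one may be active (mode ABDSTE vs ABDFTE);
- **C** — family environment shared by *every* member including spouses,
  used by the social-homogamy variant (ABDCTE), where the copath matrix is
  inactive.

Quantitative sex limitation is expressed through sex-specific path matrices
(`a_m` vs `a_f`, …); qualitative sex limitation through B and through
cross-sex correlations `r_D, r_S, r_T ∈ [−1, 1]` applied to opposite-sex
pairs' shared D/S/T factors.

### Assortative mating and the copath rule

Primary phenotypic assortment is a 2×2 copath matrix `mu` between spouse
phenotypes; rows index the husband's traits, columns the wife's, so
`mu[0,1]` is the (male trait1) × (female trait2) copath. A single transpose
switches the convention; it is deliberately not configurable. The copath
tracing rule — for X on the husband's side and Y on the wife's,
`cov(X, Y) = cov(X, P_h) · mu · cov(P_w, Y)` — induces spousal covariance
between every latent pair and, through inheritance, gametic phase
disequilibrium: the equilibrium `q` exceeds the identity.

### Equilibrium

`solve_equilibrium` iterates the one-generation moment recursion over the
stacked latent covariance (A, B, F per sex; 6×6 per sex): spousal
cross-moments from the copath rule, offspring additive moments from
midparent averaging plus segregation variance ½·I (infinitesimal model,
unaffected by assortment; also applied to B), and the vertical-transmission
construction for F. Defaults: damping 0.5, tolerance 1e−12 on the max-norm
residual, at most 10,000 iterations, started from identity latent
variances. The fitting routine first attempts the undamped recursion (the
generational map itself; about twice as fast and with an identical fixed
point) and falls back to the damped solve. In the univariate special case
the fixed point has the closed form `q = 2 / (1 + sqrt(1 − 4 a² mu))`,
which the solver reproduces to 1e−8 and which anchors the simulator checks.

Parameter sets for which the recursion diverges or produces a non-PSD `q`
or phenotypic covariance are *inadmissible*: the solver raises a structured
error and the optimizer treats such points as effectively infinite cost
(with a mild slope so line searches can back out). Nothing is clamped.
Note that copaths on the spousal-correlation scale that look innocuous
univariately (e.g. matching the raw spousal correlations elementwise) can
make the joint bivariate system diverge; the bundled truth calibrates `mu`
self-consistently instead.

### The q off-diagonal constraint

The gametic-phase-disequilibrium test constrains the *stationary* q to be
diagonal. This is a nonlinear constraint on the parameters, enforced in the
fitting objective by a stiff quadratic penalty (`1e7 · q₁₂²`; residual
violation ~1e−4, and the reported −2lnL is recomputed without the penalty).
Projecting q₁₂ to zero inside the fixed point instead would let the model
reroute the genetic cross-covariance through the Cholesky cross paths and
make the test vacuous — we verified the likelihood difference is then
exactly zero at 20,000 families. One constraint counts as one df.

## FIML likelihood

Each family contributes the multivariate-normal −2 log density of its
observed entries under the joint moments of its configuration (up to 12×12
for two parents, two twins, two siblings), with missing entries removed by
row/column deletion. Families are grouped by (configuration, missingness
pattern) so each Cholesky factorisation is done once per group; the result
is provably independent of grouping (the suite asserts additivity). Means
default to free per-sex × trait parameters (adjusted scores are
standardized residuals, so these sit near zero but absorb residual
structure); per-relative-type means are a straightforward extension and
deliberately out of scope.

Optimisation is L-BFGS-B on the per-family deviance scale with box
constraints (path diagonals ≥ 0, correlations in [−1,1], copaths in
[−0.9, 0.9]) and an explicit forward-difference jacobian (step 1e−6).
Two numerical notes: (1) scipy 1.17's internal bounded finite differences
stall the line search on this surface, hence the explicit jacobian;
(2) starts whose line search dies within three iterations are treated as
stalls and retried from jittered values (at most twice). Multi-start
(default 5 jittered starts) is available; the simulation studies use single
starts from neutral or truth-adjacent values to stay within their compute
budget.

LRT p-values use the plain chi-square upper tail, as the published tests
imply; at variance-path boundaries this is mildly conservative (a
boundary-adjusted mixture reference would give smaller p-values), which we
accept and do not correct. Negative chi-square within 1e−2 — the
reproducibility of quasi-Newton optima at our tolerances — is clamped to
zero with a flag; anything larger raises, signalling an unconverged full
model. AIC is −2lnL + 2k with k the number of free parameter groups minus
active constraints. Inside the selection ladder, where single-start fits
occasionally stall a few tenths of a unit short of the optimum, a reduced
model that fits *better* by less than one unit is treated as zero evidence
against the reduction (chi² = 0, p = 1, flagged) rather than an error.

## The simulator as oracle

`twinfam.simulate` implements the *same* structural equations as update
rules, so analytic and simulated moments must agree up to Monte-Carlo
error; this is the package's central correctness argument, exercised at
200,000 families per configuration with a 4-MC-SE criterion.

Mate matching couples the male and female pools by a Gaussian-copula
construction: whiten both pools, rotate to canonical coordinates (SVD of
the whitened copath target), draw each male a simulated "spouse score" from
the exact conditional Gaussian, and assign real females to those scores by
a bucketed two-dimensional rank sort (≈√n quantile buckets on the first
coordinate, sorted on the second within bucket), iterating a small
correction to the working cross-correlation until the achieved spousal
covariance hits the target `vp_m · mu · vp_f` (computed from the current
pools' empirical covariances, so the copath rule holds generation by
generation, including transients). A target with a canonical correlation
above 1 is rejected as unattainable. Under social homogamy there is no
phenotypic matching; the family environment C is drawn at family formation
and added to every member, parents included.

Defaults encode the stated world of the synthetic fixture: 15 generations,
20,000 pairs per generation (200,000+ for the oracle tests), one son and
one daughter per pair. The family designs mirror the four-sample layout of
the study this model class was built for: a twins+siblings+parents sample,
two twins+siblings samples without parental rows, and a siblings+parents
sample, ~2,936 families in total at scale 1. The observation model adds
uniform ages per role class (twins 12–28, siblings 10–35, parents 29–78),
sex/age/age² effects, instrument-specific raw scales (IQ-like means ~100
or ~10 by sample; height in cm), 2% item missingness, and gross outliers
displaced ≥4.8 SD.

### The bundled truth

`default_truth()` is an ABDSTE parameter set with the reduced structure the
analysis tends to select (no twin-specific environment, no male-specific
factor, cross-sex correlations 1, sibling environment mostly on trait1).
Paths were chosen once at published-magnitude values; the copath matrix was
then solved by an outer fixed point so the implied spousal correlations are
exactly [[.35, .11], [.18, .20]], and frozen. The implied world has MZ
correlations .83–.86, DZ/sib .43–.52, within-person cross-trait r .16/.19,
narrow heritabilities .62–.78, and additive-genetic inflation of ~30%/18%
(trait1/trait2) over random mating. Variants: `sex_equal` averages the two
sexes' paths (used by the scaled-down selection studies);
`pleiotropy_only` solves for the copath off-diagonal that makes the
stationary q exactly diagonal (pure shared-genes world — note that simply
zeroing the copath off-diagonals is *not* enough, because within-trait
assortment on cross-correlated phenotypes still builds cross-trait
disequilibrium); `assortment_only` zeroes the Cholesky cross paths.
`homogamy_truth()` is the ABDCTE counterpart with C calibrated to similar
spousal correlations and q = I.

### What a green test does not establish

The generator draws exactly multivariate-normal latents, enforces exact
equilibrium sampling, uses the model's own sharing coefficients, and
injects covariate effects linearly. Green oracle and recovery tests
therefore validate the algebra and the estimator under the model's own
assumptions; they say nothing about robustness to non-normality, age- or
cohort-varying architecture, epistasis or gene–environment interaction,
selective participation, or disequilibrium (non-stationary) assortment —
all explicitly outside the model.

## The analysis pipeline

1. **Adjustment** — per trait and sample: OLS on [1, male, age−25,
   (age−25)²]; residual z-scores beyond 4 SD set to missing (counted by
   sign), the regression re-fit without them; per-sample standardized
   residuals re-standardized to overall mean 0 / variance 1 (within-sex
   variances left free). Degenerate designs fall back to mean-centering
   with a logged warning.
2. **Mating-model comparison** — the three full models (ABDSTE, ABDFTE,
   ABDCTE) are non-nested and ranked by AIC.
3. **Sequential reduction** — candidate edits, least influential first:
   drop T and B (ordered by their current summed share of both traits'
   phenotypic variance across sexes — the ladder's ordering metric), fix
   r_S/r_D/r_T to 1, attempt dropping D and S (or F), equate the copath
   off-diagonals, drop mu. An edit is kept when its LRT p exceeds the
   threshold (default .10, the published convention); tests are sequential
   with no multiplicity correction, mirroring the source procedure. E is
   never a candidate. The exact order beyond "least variance first" is a
   documented choice.
4. **Decomposition** — per-sex narrow/broad heritabilities, the additive
   genetic correlation r_A = V_A[1,2] / √(V_A[1,1] V_A[2,2]), LRTs for
   r_A = 0 (cross paths + q constraint jointly), pleiotropy (cross paths
   only) and gametic phase disequilibrium (q constraint only), and
   assortment-inflation percentages, 100·(observed − counterfactual)/
   counterfactual with the counterfactual evaluated at q = I.

## Known limitations

- Two traits only; trait order is fixed and Cholesky-order sensitivity is
  acknowledged, not explored.
- No standard errors beyond LRTs; no boundary-corrected reference
  distributions.
- The ABDFTE equilibrium is validated against the simulator rather than
  hand-derived closed forms.
- Printed fit indices of the motivating study (its AICs, point estimates)
  depend on undeposited raw data and are not reproduction targets; only
  its printed statistic→p conversions and arithmetic are.
- The preliminary saturated-model equality testing of means/variances
  across relative types is simplified to the per-sex means model.
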