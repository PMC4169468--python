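# Methods

This note documents the statistical models implemented in `symbiocomp`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## The scientific setting

A panel of endosymbiont strains (*Wolbachia*) is introduced into a common
host genetic background (*Drosophila*), and each strain's effect on three
kinds of trait is measured: survival after viral challenge (DCV, FHV, or a
Ringer's mock infection), within-host symbiont density and viral titer by
qPCR, and host gene expression (*Drosomycin*, *Diptericin*, *Dnmt2*).  The
comparative question is whether strains vary genetically in the protection
they confer and whether protection covaries with symbiont density — and if
so, whether the covariance is attributable to shared ancestry of the
strains or to strain-specific variation independent of the phylogeny.

## Shared-ancestry matrix (module `phylo`)

From a rooted ultrametric strain phylogeny, `A` has entries
`a_jk = depth(MRCA(j, k)) / depth(root-to-tip)` — the proportion of time
since the root during which strains *j* and *k* shared a lineage.  Under
Brownian trait evolution the phylogenetic effects have covariance
`V_p ⊗ A`.

Choices:

- **Root-depth normalization to `a_jj = 1`.** The matrix is scale-free;
  the magnitude of phylogenetic variance lives entirely in `V_p`.  Whether
  the original analysis rescaled its consensus tree is not recoverable; we
  state our normalization instead of guessing.
- **Ultrametricity tolerance.** Relative leaf-depth spread ≤ 1e-6 accepted;
  larger spread is rejected, because the Brownian `A` presumes
  contemporaneous tips.
- **Polytomies** are allowed and treated as hard polytomies.
  **Zero-length terminal branches** are allowed; tip pairs with `a_jk = 1`
  make `A` singular and are flagged; the sampler handles a singular `A` by
  adding a logged `1e-8` diagonal jitter before inversion.

## Synthetic data (module `simulate`)

The generator's defaults are the study design constants: 19 strains plus a
symbiont-free reference line; per strain × treatment, 12 vials (2 per day
× 6 assay days; the reference line at double replication) of 20 flies; a
25-day daily census; qPCR on 10 pools of 10 flies with 2 technical
replicates.

- **Trees** are standard Kingman coalescent simulations (exponential
  waiting times with rate k(k−1)/2), so branch lengths are in coalescent
  units like the motivating tree.
- **Strain effects** are drawn as a phylogenetic component (matrix-normal
  with row covariance `A`, column covariance `V_p`) plus an independent
  strain component (`V_s`), recorded separately as ground truth.
- **Survival times** are continuous exponentials under hazard
  `baseline × exp(strain_log_hr + vial_frailty)`, discretized to whole
  days by ceiling — the daily census produces exactly the heavy ties the
  Cox machinery must face.  Default per-day baseline hazards are 0.10
  (DCV), 0.08 (FHV) and 0.01 (mock), giving realistic mortality ranges
  over 25 days; vial frailty is Gaussian on the log hazard (sd 0.2).  An
  additional day-1 Bernoulli death (rate 0.03) emulates stabbing-injury
  mortality so the day-1 exclusion rule is exercised; the true rate is
  unknowable from the published design, so it is a parameter, not a claim.
- **qPCR** noise is additive Gaussian on Ct (equivalently lognormal on
  quantity, the standard model), with a shared Gaussian Ct shift per
  96-well plate and a target-gene efficiency of 1.9 against a reference at
  2.0, so the Pfaffl correction has something to correct.

What the generator does **not** emulate: mechanistic within-host virus
dynamics, non-proportional hazards, heavy-tailed qPCR outliers,
plate-position effects within a plate, or real MLST-based phylogenies.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to every failure mode of real assay data.

## qPCR quantification (module `qpcr`)

Relative quantity: `E_target^(−ct_target) / E_ref^(−ct_ref)` (Pfaffl),
reducing to `2^(ct_ref − ct_target)` at ideal efficiencies.  Efficiency
from a dilution series: `E = 10^(−1/slope)` of the Ct-vs-log10(input)
regression.  Efficiency-corrected Ct: `ct × log2(E)`, which maps a gene
onto the ideal-efficiency scale (`2^(−corrected) = E^(−ct)`).

Choices:

- **Technical replicates are averaged on the Ct scale** (the dominant
  convention; the difference from quantity-scale averaging is second
  order).  A config switch selects quantity-scale averaging.
- **Reference genes are configuration labels** (host actin for density and
  expression, a host mRNA control for titers), not hard-coded names; the
  reference Ct is left uncorrected when its efficiency is 2.
- **Plate normalization** (per-plate z-score, ddof 1) is applied only to
  host-gene expression traits, controlled by config; density and titers
  are not plate-normalized.
- Strains flagged as unstable transmitters can be excluded by a config
  list before trait assembly.
- The original publication's exact algebra for these steps is rendered
  only as figures in the available text; the implementation follows the
  Pfaffl (2001) method and the verbal description of plate normalization.

## Mixed-effect Cox model (module `survival`)

Deaths on day 1 are attributed to stabbing injury and removed (censored
day-1 records are kept).  The model has fixed strain (and treatment)
effects and a Gaussian random effect per vial on the log hazard.  Fitting
maximizes the **Efron-tied partial likelihood penalized by
`b'b/(2σ²)`** (Newton with step-halving; ≤ 25 distinct event days keep the
risk-set accounting cheap), and the frailty variance is chosen to maximize
the **Laplace-approximate integrated likelihood**
`ℓ_pen(β̂, b̂) − (q/2)·log σ² − ½·log det(H_bb + I/σ²)`, optimized as a
bounded scalar search over log σ² (tolerance 1e-6 on log σ², warm-started
inner Newton, zero-boundary estimates reported as 0).

- **Ties:** Efron by default (daily censuses produce heavy ties; Efron is
  the accepted default of the model family used for such data); Breslow
  available via argument.
- **Per-vial protection traits** are `−(β_strain + b_vial)` from a fit
  within each treatment — fixed strain effect plus predicted vial effect.
  How the original per-vial hazard ratios were constructed is not stated
  in the source; fitting vials as fixed effects is possible through the
  same design machinery, but the random-effect prediction is the default
  and the tested path.
- **LRTs** compare nested fixed-effect structures on the integrated
  likelihood (equal to the partial likelihood when no frailty is fitted);
  negative statistics from outer-optimization noise are clipped at 0 with
  a warning.  No p-value is ever reported for the frailty variance itself
  (boundary problem).
- **Wald SEs** come from the inverse penalized Hessian; coefficients with
  |log HR| > 10 are flagged non-identified and reported with infinite SE
  (p = 1 in the per-strain control comparisons).
- The day-of-assay block is deliberately not modelled (the motivating
  model statement lists only the vial effect); day remains metadata.

## Multi-response (phylogenetic) mixed model (module `comparative`)

For observation *i* of trait *t* on strain *w*:
`y_twi = β_t + u_s:tw [+ u_p:tw] + e_twi`, with `u_s ~ N(0, V_s ⊗ I)`,
`u_p ~ N(0, V_p ⊗ A)` and per-trait residual variances (traits are
measured on different biological replicates, so residuals are independent
across traits and missing (strain, trait) cells drop out of the
likelihood).

Estimation is a **blocked Gibbs sampler**: (i) fixed effects and all
stacked random effects jointly from their Gaussian full conditional
(per-trait sufficient statistics make the precision assembly O(cells));
(ii) `V_s` from an inverse-Wishart full conditional over strain-effect
outer products; (iii) `V_p` likewise with the `A⁻¹`-weighted quadratic
form; (iv) residual variances from scaled inverse-chi-square conditionals.
Covariance draws failing a Cholesky check are resampled (counted and
logged).

Priors: trait intercepts `N(0, 1e10)`; covariances from one of three
families — **parameter-expanded** (the default: redundant per-trait
working scales `α_t` with `N(0, 1)` priors around a working covariance
with an identity-scale inverse-Wishart prior, giving a half-t-like
marginal on effect standard deviations), **inverse-Wishart**
(df = dimension + 1, scale 0.01·I), or **flat** (requires more strains
than twice the trait count).  Residual variances get a weak scaled
inverse-chi-square (ν = 0.002, s² = 1).  On well-identified data the three
families give genetic-correlation posteriors within 0.05 of each other
(tested); the working-parameter hyperparameters are our defaults, not
values recoverable from the source.

Schedules: the desk default is 50k iterations / 10k burn-in / thin 10;
tests and the acceptance script use shorter, stated schedules (3.5k–24k
iterations) chosen so each check completes in seconds to a few minutes at
the problem sizes given in the test docstrings.  The production schedule
of the motivating study (13M / 3M) is available by overriding the config.

Summaries: genetic correlations per draw from the chosen component
(strain, phylogenetic, or their sum), posterior means with **95% HPD
intervals by the shortest-sorted-window rule** (`⌈mass·n⌉` samples, ties
toward the lower start; ≥ 100 samples required).  Convergence reporting
follows the study's rule: lag-1 autocorrelation of every scalar chain
below 0.1, plus effective sample sizes; constant chains are flagged
degenerate.  Phylogenetic effects are reported with a weak-identifiability
warning when both components are fitted with few strains, rather than
suppressed.

The **component regression comparison** computes, per draw,
`b_c = σ_c:resp,pred / σ²_c:pred` for the phylogenetic and strain
components and summarizes `b_phylo − b_strain`; an HPD containing 0 is
read as "no evidence the regression differs between components".  Draws
with numerically zero predictor variance are skipped and counted.  This
ratio is only well-defined when both components retain appreciable
predictor variance; the partition is weakly identified on shallow trees
(tested demonstrations use a coalescent tree of typical depth, and the
two-component analysis uses the inverse-Wishart prior, which mixes better
than parameter expansion in this weakly-identified variant).

## Univariate companions (module `group_stats`)

ANOVA on ln-transformed quantities; Dunnett many-to-one tests against the
symbiont-free control (two-sided by default — sidedness is not stated in
the source — via the correlated multivariate-t max-statistic
distribution); Tukey HSD with a compact letter display
(split-and-absorb).  Time-course titers are modelled by polynomial
regression in day (default max degree 3) with strain interactions,
simplified by backward elimination of the least significant removable term
at α = 0.05 per term, never removing a term while a higher-order term
containing it remains (marginality).

## Pipeline (module `pipeline`)

One global seed is expanded into per-stage seeds with
`numpy.random.SeedSequence.spawn`, so stages rerun independently yet
reproducibly; every run writes a manifest with the config hash, stage
seeds and output files.  All tabular I/O is TSV with a one-line header.
The command-line interface is a thin wrapper over these library functions.

## Known limitations

- The Laplace-approximate integrated likelihood for the frailty variance
  is an approximation; for very small vials or very heavy ties its LRT
  calibration is only asymptotic (the null calibration test covers the
  study-like regime).
- The phylogenetic/strain variance partition is weakly identified at
  ~20 strains; the package warns rather than refusing, matching how such
  models are used in practice (phylogeny-only variants are first-class).
- Backward selection p-values are conditional on the selection path; they
  are reported as in the motivating analysis, not corrected for selection.
- qPCR quantities are treated as exact ratios; fluorescence-curve
  processing and Ct calling are upstream of this package.
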