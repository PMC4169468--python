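# symbiocomp

Comparative analysis of symbiont-conferred antiviral protection.

Facultative endosymbionts such as *Wolbachia* can protect their insect
hosts against RNA viruses, and different bacterial strains protect to very
different degrees. `symbiocomp` implements the statistical pipeline used to
ask whether such strain differences are heritable traits of the symbiont,
whether protection is genetically correlated with within-host bacterial
density (and with viral titer — distinguishing *resistance* from
*tolerance*), and how much of the between-strain covariance is explained
by the strains' shared ancestry. It is aimed at researchers analysing
strain-panel infection experiments: survival assays scored daily per vial,
qPCR quantification of symbiont density / viral titer / host gene
expression, and a strain phylogeny.

## The models at the core

**Per-vial protection traits.** Survival after viral challenge is
modelled with a mixed-effect Cox proportional-hazards model: strain (and
treatment) as fixed effects, each vial of ~20 flies as a Gaussian random
effect on the log hazard (a log-normal frailty), ties handled by the Efron
approximation, deaths on the day after infection excluded as stabbing
injuries, and censoring at day 25. The protection trait of vial *v* of
strain *s* is the negative log hazard ratio versus the symbiont-free
reference, −(β_s + b_v), so larger is more protective.

**Efficiency-corrected qPCR.** Relative quantities follow the Pfaffl
method, E_target^(−Ct_target) / E_ref^(−Ct_ref), with amplification
efficiencies estimated from dilution series (E = 10^(−1/slope)); technical
replicates are averaged on the Ct scale and host-gene expression is
z-scored within 96-well plates.

**Genetic correlations.** Strain-level traits feed a Bayesian
multi-response mixed model,

    y_twi = β_t + u_s:tw + u_p:tw + e_twi,

with a strain random effect (trait covariance **V**_s, independent across
strains), an optional phylogenetic effect (covariance **V**_p ⊗ **A**,
where a_jk is the proportion of time strains *j* and *k* shared ancestry
since the root — Brownian evolution on an ultrametric tree), and a
residual variance per trait. A blocked Gibbs sampler with conjugate
updates (parameter-expanded, inverse-Wishart or flat covariance priors)
yields posteriors of the genetic correlations
r_g = σ_t1,t2 / √(σ²_t1 σ²_t2) with 95% highest-posterior-density
intervals, and of the component-specific regression slopes whose
difference asks whether a trait relationship is phylogenetic or
strain-specific.

A first-class synthetic-data module generates every raw input (coalescent
trees, strain effects with known **V**_s / **V**_p, daily-census survival
tables, qPCR plates with batch effects) so the whole pipeline is testable
against known ground truth. See `docs/methods.md` for model details and
design choices.

## Worked example

Simulate a study-scale panel (19 strains + symbiont-free control, 12
vials of 20 flies per strain per treatment, true protection correlation
0.7 between DCV and FHV), then run survival fits and the comparative
model:

```python
import numpy as np
from symbiocomp import pipeline
from symbiocomp.simulate import SimulationConfig

V = np.array([[0.5, 0.35], [0.35, 0.5]])   # true r_g = 0.7
cfg = pipeline.RunConfig(
    outdir="run", seed=7,
    sim=SimulationConfig(n_strains=19, V_s=V,
                         trait_names=("protection_DCV", "protection_FHV")),
    mcmc_iterations=6000, mcmc_burn_in=1000, mcmc_thin=5,
)
state = pipeline.run_pipeline(cfg)
for entry in state["posterior_summary"]["r_g"]:
    t1, t2 = entry["traits"]
    print(f"r_g({t1}, {t2}) = {entry['mean']:.2f}  "
          f"95% HPD [{entry['hpd'][0]:.2f}, {entry['hpd'][1]:.2f}]")
```

prints

```
r_g(protection_DCV, protection_FHV) = 0.67  95% HPD [0.42, 0.88]
```

— the posterior mean genetic correlation between the two protection
traits, with its credible interval comfortably excluding zero and
covering the generating value of 0.7. The per-treatment Cox fits are in
`state["cox_fits"]`; for example the most protective strains against DCV
(largest negative log-hazard coefficients, i.e. largest −ln HR):

```python
from symbiocomp.survival import strain_vs_control_tests
print(strain_vs_control_tests(state["cox_fits"]["DCV"])
      .sort_values("coef").head(3)[["strain", "coef", "se", "p"]])
```

```
strain      coef       se            p
wSim14 -1.103162 0.123523 4.228353e-19
wSim04 -0.784940 0.117931 2.815244e-11
wSim18 -0.727821 0.117119 5.153084e-10
```

A coefficient of −1.10 means flies with that strain die at
exp(−1.10) ≈ 1/3 the rate of symbiont-free flies; its protection trait is
+1.10. Short narrative scripts for each capability live in `examples/`,
and the same functionality is scriptable from the shell
(`symbiocomp run --outdir run --seed 7`, plus per-stage subcommands).

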