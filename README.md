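# dombayes

An in-silico workbench for **Bayesian dominance GWAS**: how much power
does a multi-marker association model gain by fitting dominance effects
alongside additive ones?

Quantitative traits in livestock (and beyond) carry non-negligible
dominance variance, but the Bayesian variable-selection models commonly
used for multi-marker GWAS — the BayesC family — fit additive effects
only.  `dombayes` implements the whole experimental loop needed to study
this question on simulated data:

1. **Forward Wright-Fisher simulation** of a 1-Morgan chromosome through
   a cattle-like demography (Ne 600 declining to 100, 1051 generations,
   coalescent-equilibrium founders, infinite-sites mutation), yielding a
   final sample of 1500 genotyped individuals with ~7k segregating SNPs
   (MAF > 0.01), thinned to 2k/1k/0.5k marker panels.
2. **Trait simulation** with a realistic joint distribution of additive
   and dominance effects at 15 causative loci: dominance coefficient
   h = d/|a| ~ N(0.2, 0.3²), a|h ~ N(0, exp(3h)), d = h|a|, narrow-sense
   heritability 0.3.  Breeding values, dominance deviations and genetic
   values follow the Falconer decomposition
   (BV = Σ (x−2p)α with α = a + (q−p)d, etc.).
3. **BayesC and BayesD samplers**: y = 1μ + Xã + Wd̃ + E with a
   two-component scale mixture prior (inclusion probability pLD, small
   component scaled by ε = 0.01), folded-t additive effects (2.5 df) and,
   in BayesD, a conditional dominance prior d̃|ã ~ N(μ_h|ã|, σ_h²ã²)
   moment-matched to the simulated variance components and inbreeding
   depression.  Gibbs sampling with a Metropolis-within-Gibbs joint
   (γ, ã) update in BayesD; 20,000 cycles, 10,000 burn-in, thin 100.
4. **Sliding-window WPPA inference**: per stored sample the window
   genomic variance σ̂²_gw = Σ_j H_j α̂_j² + H_j² d̂_j² is compared with its
   expectation under an equal distribution of genetic variance; WPPA is
   the fraction of samples with q_w = σ̂²_gw / E(σ²_gw) > 1.
5. **Evaluation**: QTL mapping at WPPA 0.85/0.95/0.99, power, L-power
   (restricted to loci explaining > 2.5% of genetic variance), and
   mapping precision, replicated over populations and traits.

See `docs/methods.md` for the full model description, defaults, and
design decisions.

## Worked example

```python
import numpy as np
import dombayes as db
from dombayes import bayes_mcmc as bm, evaluation as ev, wppa as wp

pop = db.simulate_population(db.DemographyConfig(seed=1))
trait = db.simulate_trait(pop, rng=np.random.default_rng(2))

panel = db.select_marker_panel(pop, 2000, 0.03, causal_ids=trait.qtl.site_ids)
X = pop.genotypes(panel.snp_indices)
inputs = bm.ModelInputs(y=trait.y, X=X, v_a_in=trait.v_a, v_d_in=trait.v_d,
                        v_e_in=trait.v_e, inb_dep_in=trait.inb_dep)
prior = bm.calibrate_priors(inputs, bm.pld_schedule(3), model="D")
samples = bm.run_bayesd(inputs, prior, bm.MCMCConfig(seed=3))

positions = pop.positions_cm[panel.snp_indices]
scan = wp.scan_windows(samples, positions, trait.v_a, trait.v_d,
                       window_size_cm=0.5)
det, large = ev.detectable_qtl(trait.qtl, positions, samples.freqs,
                               trait.v_a, trait.v_d, 0.5)
tab = ev.power_tables([ev.map_qtl(scan, trait.qtl, detect=det, large=large)])
print(tab[["wppa", "power", "l_power", "precision"]].round(3))
```

Output (about two minutes, most of it the population simulation and the
20,000-cycle chain):

```
segregating sites: 13625; MAF>0.01: 7834
V_A=5.29 V_D=0.19 V_E=12.15 h2=0.30 inb_dep=0.91
 wppa  power  l_power  precision
 0.85  0.333      0.5      0.867
 0.95  0.333      0.5      0.867
 0.99  0.333      0.5      0.867
```

Reading this: the simulated trait has heritability 0.30 with a small
dominance component for this seed.  Of the causative loci whose variance
exceeds the equal-distribution expectation of a 0.5-cM window
("detectable" loci), 33% are mapped by BayesD at WPPA ≥ 0.95 — i.e. some
window within 1 cM of the locus has q_w > 1 in ≥ 95% of stored posterior
samples — rising to 50% among loci explaining > 2.5% of the genetic
variance (L-power).  Mapped loci are localised to significant regions
of ~0.87 cM (precision; lower bound is the 0.5-cM window size).

The same pipeline is scriptable from the shell:

```bash
dombayes simulate-pop --seed 1 --out pop
dombayes simulate-trait --pop pop --seed 2 --out trait
dombayes fit --model bayesd --geno pop --pheno trait.pheno.tsv \
         --config fit.yaml --seed 3 --out samples.h5
dombayes wppa --samples samples.h5 --geno pop --window-cm 0.5 \
         --va 8.18 --vd 0.20 --out scan.tsv
dombayes evaluate --scan scan.tsv --qtl trait.qtl.tsv --va 8.18 --vd 0.20 \
         --out eval.tsv
dombayes experiment --config grid.yaml --seed 0 --out results/
```

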