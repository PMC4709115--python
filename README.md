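# mkdfe

Maximum-likelihood McDonald–Kreitman estimation of the distribution of
fitness effects (DFE) of non-synonymous mutations and of the adaptive
amino-acid substitution rate, from site-frequency spectra and divergence
counts.

## The problem

For a focal species with polymorphism data and a close outgroup, the
classical McDonald–Kreitman logic compares the non-synonymous/synonymous
divergence ratio *d*<sub>N</sub>/*d*<sub>S</sub> with the corresponding
polymorphism pattern: an excess of *d*<sub>N</sub>/*d*<sub>S</sub> over its
nearly-neutral expectation is the footprint of adaptive protein evolution.
Doing this well requires modelling slightly deleterious segregating
mutations (which inflate *p*<sub>N</sub>/*p*<sub>S</sub>) and demographic
distortions of the site-frequency spectrum (SFS). `mkdfe` is aimed at
population geneticists who have, per species pair:

* the unfolded (or folded) synonymous and non-synonymous SFS,
* counts of fixed synonymous/non-synonymous differences
  (*D*<sub>S</sub>, *D*<sub>N</sub>),
* the numbers of synonymous/non-synonymous sites
  (*L*<sub>S</sub>, *L*<sub>N</sub>),

and want estimates of the non-adaptive rate ω<sub>na</sub>, the adaptive
rate ω<sub>a</sub>, and the proportion of adaptive amino-acid substitutions
α, with model comparison and likelihood-based confidence intervals.

## The model

All counts are independent Poisson variables around model expectations.
With θ = 4*N*<sub>e</sub>μ per site, nuisance per-frequency-class
multipliers *r*<sub>i</sub> (*r*<sub>1</sub> = 1) absorbing demography and
other shared SFS distortions, scaled divergence time *T* = μ*t*, and a DFE
Φ(*S*) over *S* = 4*N*<sub>e</sub>*s*:

```
E[P_S[i]] = θ L_S r_i / i
E[P_N[i]] = (θ/2) L_N r_i ∫ Φ(S) G(S, i, n) dS
E[D_S]    = L_S T
E[D_N]    = L_N T ∫ Φ(S) F(S) dS + A
```

where G integrates the diffusion sojourn-time density against binomial
sampling of *i* derived copies among 2*n* chromosomes, F(*S*) =
*S*/(1 − e<sup>−*S*</sup>) is the scaled fixation probability, and *A* ≥ 0
is a divergence excess standing for strongly advantageous substitutions
that leave no polymorphism signature. Available DFE families: `neutral`,
`gamma`, `gammaexpo` (negative Gamma + exponential tail of weakly
advantageous effects), `scaledbeta`, `displgamma`; the `[-A]` variant pins
A = 0 to ask whether the continuous DFE alone explains divergence.

From a fitted model, substitutions with *S* < *S*<sub>adv</sub> (default 5)
count as non-adaptive, giving the expected non-adaptive divergence
*D̂*<sub>Nna</sub> and the printed estimators

```
omega_na = (D̂_Nna / L_N) / (D_S / L_S)
omega_a  = d_N/d_S − omega_na
alpha    = omega_a / (d_N/d_S)
```

Models are compared by AIC and likelihood-ratio tests; α confidence
intervals profile the likelihood (all α whose constrained maximum is
within 2 log-units of the optimum).

## Worked example

Simulate one species pair under a GammaExpo DFE and re-estimate:

```python
import numpy as np
import mkdfe as M

dfe = M.make_dfe("gammaexpo", shape=0.4, mean_del=2000.0,
                 p_pos=0.01, mean_adv=4.0)
truth = M.ModelParams(theta=0.01, r=np.ones(7), T=0.1, A=2000.0, dfe=dfe)
scenario = M.SimScenario(params=truth, n_chrom=8, L_N=1e6, L_S=1e6, seed=42)
print(f"true alpha = {M.true_alpha(scenario):.3f}")

data = M.sample_dataset(scenario, 0)
fit = M.fit(data, "gammaexpo", restarts=3, seed=1)
est = M.adaptive_rates(data, fit.params_hat)
lo, hi, _ = M.profile_ci_alpha(data, fit)
print(f"loglik  = {fit.loglik:.2f}  (AIC {fit.aic:.2f}, {fit.n_free} free params)")
print(f"dN/dS   = {est.dnds:.4f}")
print(f"omega_na= {est.omega_na:.4f}")
print(f"omega_a = {est.omega_a:.4f}")
print(f"alpha   = {est.alpha:.3f}  [{lo:.3f}, {hi:.3f}]")
```

prints

```
true alpha = 0.441
loglik  = -73.79  (AIC 173.57, 13 free params)
dN/dS   = 0.1041
omega_na= 0.0507
omega_a = 0.0533
alpha   = 0.513  [0.232, 0.564]
```

The generating α (0.441) sits inside the 2-log-unit profile interval; the
point estimate fluctuates replicate to replicate (over 10 replicates the
mean α̂ is within ±0.05 of the truth — this is what the validation studies
check). `dN/dS` splits into a non-adaptive part predicted from the fitted
DFE and polymorphism (ω<sub>na</sub>) and the adaptive remainder
(ω<sub>a</sub>).

The same pipeline runs from the shell:

```sh
mkdfe simulate --scenario scenario.txt --out-dir sim/
mkdfe fit --input sim/datasets.tsv --model gammaexpo --ci --out-dir fit/
mkdfe meta --results fit/results.tsv
```

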