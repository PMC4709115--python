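# Methods

## Model

`mkdfe` fits a Poisson random field model of coding-sequence polymorphism
and divergence for one focal species and one outgroup. The data for a
species pair are 4n numbers: the unfolded synonymous and non-synonymous
SFS (2n − 1 classes each, n diploid individuals), and the fixed
synonymous/non-synonymous difference counts D_S and D_N. Synonymous
mutations are assumed neutral; non-synonymous mutations receive a
selection coefficient s (codominant, constant in time) drawn from the DFE.
All 4n observables are treated as independent Poisson counts around the
model expectations given in the README; the log-likelihood uses the
log-Gamma extension of the Poisson density so that fractional "counts"
produced by hypergeometric projection are handled smoothly.

Assumptions worth keeping in mind:

* One panmictic Wright–Fisher population at mutation–selection–drift
  equilibrium, up to the per-class distortion multipliers r_i. The r_i
  absorb any force that affects synonymous and non-synonymous SNPs
  equally (demography, structure, linked selection, mis-orientation,
  genotyping error) but nothing that affects them differentially.
* Free recombination between sites (Poisson independence).
* N_e constant over the divergence period as far as the DFE scaling is
  concerned; older demographic events leave no polymorphism signature and
  are absorbed by T and A.

### Sojourn and fixation kernels

The expected SFS under selection uses H(S, x) =
2(1 − e^(−S(1−x))) / (x(1−x)(1 − e^(−S))), the relative sojourn time of a
mutation with scaled coefficient S = 4·N_e·s at population frequency x,
with the neutral limit H(0, x) = 2/x and S > 0 advantageous. The class
factor G(S, i, n) integrates H against the binomial sampling probability
of seeing i derived copies among 2n sampled chromosomes, and is scaled so
that G(0, i, n) = 2/i exactly: the fully neutral model then reproduces the
classical θ·L/i spectrum, which pins down the otherwise arbitrary
constant in front of the non-synonymous expectation. Fixation uses
F(S) = S/(1 − e^(−S)) (F(0) = 1), the scaled Kimura probability.

### DFE families

| name | parameters | notes |
|---|---|---|
| `neutral` | f_neutral | point mass at S = 0; remainder strongly deleterious |
| `gamma` | shape, mean_del | −S ~ Gamma(shape, mean) |
| `gammaexpo` | shape, mean_del, p_pos, mean_adv | + exponential tail of weak positive effects |
| `scaledbeta` | a, b, w_mild | Beta on [−S_max, S_max], S_max = 25; remainder lethal |
| `displgamma` | shape, mean_del, displacement | negative Gamma shifted right by d ≥ 0 |

"Strongly deleterious" is an absorbing class contributing zero to both
polymorphism and divergence — no numeric S is attached to it, avoiding an
arbitrary large-|S| cutoff. The Gamma is parametrized by (shape, mean),
and the shape is capped at 100 during fitting.

## Numerics

* **Frequency integral**: Gauss–Legendre, 256 nodes on (0, 1). For S = 0
  the integrand is a polynomial of degree < 2n, integrated exactly; for
  S ≠ 0 it is entire in x and converges spectrally (tests assert
  node-doubling stability at 1e−9).
* **DFE integral**: each continuous component is integrated in quantile
  space — with u = CDF(x) the weighted integral becomes a plain integral
  of the integrand over (0, 1), done with 64 Gauss–Legendre nodes per
  branch. This places nodes where the density mass is, which matters for
  heavy-tailed Gammas with shape ≪ 1, and makes truncated integrals
  (S < S_adv) exact in the truncation point. Node counts are arguments
  everywhere.
* **Overflow**: H is evaluated in an expm1 arrangement whose exponents are
  all negative; below S = −500 the closed asymptotic form
  G ≈ 2·C(2n, i)·Γ(i)/|S|^i takes over (the sojourn boundary layer at
  x → 0 is thinner than any fixed node spacing). F underflows gracefully
  to 0 for strongly deleterious S and to S for strongly advantageous S.
* **Zero expectations**: an expected count of 0 with a positive observed
  count yields −inf log-likelihood; 0 observed on 0 expected contributes 0.

## Fitting

Optimization is quasi-Newton (L-BFGS-B) in an unconstrained transformed
space: log for θ, T, r_i, A and positive DFE parameters, logit for
proportions; |transformed value| is capped at 25 and log(shape) at
log(100). The multi-start policy (default 5) takes one start from a
method-of-moments initialization — θ and r from the synonymous SFS, T from
D_S/L_S, the DFE from a small coarse grid — plus seeded random
perturbations; starts landing more than 1e−4 below the best are counted as
failed. The `[-A]` variant removes the A coordinate and pins A = 0; in the
standard variant A = e^a can approach but not exactly reach 0, which is
immaterial for likelihoods at realistic count scales.

Model comparison: AIC (ties toward fewer parameters) plus LRTs for the
nested pairs Neutral⊂Gamma⊂GammaExpo, Gamma⊂DisplacedGamma, and
[-A]⊂standard. Two caveats are deliberate and documented rather than
"fixed": Neutral⊂Gamma nesting holds only as a limiting case (shape → ∞,
mean → 0, plus the lethal mass), and nulls with p_pos = 0 or A = 0 lie on
the parameter boundary — the plain chi-square reference is then
conservative, which the LRT calibration study confirms (observed rejection
far below the nominal 5%).

Confidence intervals for α profile the likelihood directly: the constraint
α(params) = α0 pins T given the DFE (T = (1 − α0)·D_N/(L_N·I_na), with
I_na the sub-threshold fixation integral), so the profile is an ordinary
re-optimization over the remaining parameters on an α grid walked outward
from the ML estimate; the 2-unit crossing is located by linear
interpolation. Such intervals trust the model: the simulator (which
matches the model exactly) gives near-nominal coverage, but on real data
they should be read as lower bounds on uncertainty.

## The simulator

`simulate` draws every SFS class and both divergence counts as Poisson
around the model expectations — the estimator's own sampling distribution.
It adds two real-data features: demographic SFS distortion through r
(presets `flat`, `expansion-like` r_i = i^−0.4, `bottleneck-like`
r_i = i^0.3) and ancestral-state misorientation (each sampled SNP moves to
its mirror class with the given probability; divergence counts are drawn
before misorientation so scenarios differing only in the rate share the
underlying sample). It does **not** simulate linkage, sweeps, background
selection, fluctuating N_e, or genotyping error; passing validation
therefore demonstrates correctness of the estimator at its own
assumptions, not robustness to their violation.

## Validation study conditions

The studies in `mkdfe.validation` (run by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use a typical invertebrate-like setting:
θ = 0.01/site, T = 0.1 (d_S = 0.1), 2n = 8, L_N = L_S = 10^6 sites, flat
r. Per-family generating DFEs give moderate-to-high true α with every
model component active; the displaced-Gamma displacement is set small
(0.1), the regime where that family is empirically distinguishable — at
larger displacements the DFE mass between 0 and S_adv trades off against
A with almost no likelihood cost, and α is genuinely poorly identified.
The LRT calibration runs 100 scaled-down replicates (2n = 6, 10^5 sites);
the π_N/π_S scaling study simulates 12 "species" spanning a 25-fold θ
range with the scaled mean effect proportional to θ (fixed mutational
effects, varying N_e), where theory predicts a log–log slope of 1 − shape.

## Known limitations

* ω_a and α inherit the McDonald–Kreitman sensitivities: the split between
  the A class and continuous positive mass is weakly identified, as is
  (p_pos, mean_adv) jointly; α itself is the stable functional.
* Folded fits halve the number of r parameters and discard orientation
  information; they are the right tool when mis-orientation is suspected
  (folding removes mirror-class swaps exactly).
* α < 0 is a legitimate outcome (observed d_N below the nearly-neutral
  expectation) and is reported unclipped.
* Site counts enter as known constants; uncertainty in L_N/L_S is not
  propagated.
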