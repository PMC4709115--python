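"""Adaptive and non-adaptive substitution rates from a fitted model.

Given fitted parameters, the expected number of *non-adaptive*
non-synonymous substitutions D_Nna restricts the divergence integral to
scaled selection coefficients below a threshold S_adv (default 5): fixed
mutations with S < S_adv are counted as nearly neutral, everything above,
plus the additive excess A, as adaptive.  The printed estimators mix this
expectation with the *observed* divergences:

    omega_na = (D_Nna / Ldiv_N) / (D_S / Ldiv_S)
    omega_a  = d_N / d_S - omega_na
    alpha    = omega_a / (d_N / d_S)

alpha may be negative (observed d_N below the nearly-neutral expectation)
and is reported as such, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dfe import DFEModel
from .expectations import ModelParams, dfe_expectation, fixation_factor, N_S_NODES
from .spectra import PolyDivDataset

DEFAULT_S_ADV = 5.0


@dataclass(frozen=True)
class AdaptiveRateEstimate:
    label: str
    omega_na: float
    omega_a: float
    alpha: float
    dnds: float
    S_adv: float
    ci_alpha: tuple[float, float] | None = None
    alpha_defined: bool = True


def nonadaptive_fixation_integral(
    dfe: DFEModel, S_adv: float = DEFAULT_S_ADV, n_s: int = N_S_NODES
) -> float:
    """E_Phi[F(S); S < S_adv]: the sub-threshold part of the fixation integral."""
    return float(dfe_expectation(dfe, fixation_factor, upper_S=S_adv, n_s=n_s))


def expected_nonadaptive_divergence(
    params: ModelParams,
    Ldiv_N: float,
    S_adv: float = DEFAULT_S_ADV,
    n_s: int = N_S_NODES,
) -> float:
    """Expected count of non-adaptive non-synonymous substitutions.

    D_Nna = Ldiv_N * T * E_Phi[F(S); S < S_adv]; the A class and the DFE
    mass above S_adv are excluded.
    """
    return Ldiv_N * params.T * nonadaptive_fixation_integral(params.dfe, S_adv, n_s)


def adaptive_rates(
    dataset: PolyDivDataset,
    params: ModelParams,
    S_adv: float = DEFAULT_S_ADV,
    ci_alpha: tuple[float, float] | None = None,
    n_s: int = N_S_NODES,
) -> AdaptiveRateEstimate:
    """omega_na, omega_a and alpha for one dataset under fitted parameters."""
    if dataset.D_S <= 0:
        raise ValueError("D_S must be positive to compute substitution rates")
    d_nna = expected_nonadaptive_divergence(params, dataset.Ldiv_N, S_adv, n_s) / dataset.Ldiv_N
    ds = dataset.ds
    dnds = dataset.dn / ds
    omega_na = d_nna / ds
    omega_a = dnds - omega_na
    alpha_defined = dataset.D_N > 0
    alpha = omega_a / dnds if alpha_defined else float("nan")
    return AdaptiveRateEstimate(
        label=dataset.label,
        omega_na=omega_na,
        omega_a=omega_a,
        alpha=alpha,
        dnds=dnds,
        S_adv=S_adv,
        ci_alpha=ci_alpha,
        alpha_defined=alpha_defined,
    )


RESULTS_COLUMNS = (
    "label", "model", "variant", "loglik", "AIC", "theta", "shape", "p_pos",
    "dnds", "omega_na", "omega_a", "alpha", "alpha_low", "alpha_high",
)


def results_row(fit, est: AdaptiveRateEstimate) -> dict:
    """One per-dataset results-table row (fit is an inference.FitResult)."""
    p = fit.params_hat.dfe.params()
    lo, hi = est.ci_alpha if est.ci_alpha is not None else (np.nan, np.nan)
    return {
        "label": est.label,
        "model": fit.family,
        "variant": fit.variant,
        "loglik": fit.loglik,
        "AIC": fit.aic,
        "theta": fit.params_hat.theta,
        "shape": p.get("shape", np.nan),
        "p_pos": p.get("p_pos", np.nan),
        "dnds": est.dnds,
        "omega_na": est.omega_na,
        "omega_a": est.omega_a,
        "alpha": est.alpha,
        "alpha_low": lo,
        "alpha_high": hi,
    }
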