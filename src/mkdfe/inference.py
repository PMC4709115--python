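"""Maximum-likelihood fitting, model comparison, and profile confidence intervals.

Fits are local quasi-Newton (L-BFGS-B) optimizations in an unconstrained
transformed space: positive parameters (theta, T, r_i, A, Gamma means,
shapes) are log-transformed, proportions (f_neutral, p_pos, w_mild) are
logit-transformed.  The Gamma shape is capped at 100.  A multi-start policy
(one method-of-moments start plus seeded random perturbations) guards
against local optima.

The [-A] variant pins the strong-adaptive divergence excess A at zero and
is available for DFE families with support on S > 0; comparing it to the
standard fit asks whether the continuous DFE alone explains the observed
divergence.  Nested models are compared by likelihood-ratio tests with
plain chi-square reference (conservative at boundary nulls); non-nested
ones by AIC.  Confidence intervals for alpha profile the likelihood
directly: the reported interval is the set of alpha values whose
constrained maximum log-likelihood lies within ``drop`` (default 2) units
of the global maximum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .adaptive_rate import DEFAULT_S_ADV, nonadaptive_fixation_integral
from .dfe import FAMILIES, POSITIVE_EFFECT_FAMILIES, DFEModel, make_dfe
from .expectations import (
    N_S_NODES,
    N_X_NODES,
    DatasetShape,
    ModelParams,
    expected_data,
    log_likelihood,
)
from .spectra import PolyDivDataset

logger = logging.getLogger(__name__)

_BOUND = 25.0           # generic |transformed parameter| bound (overflow guard)
_SHAPE_CAP = 100.0      # maximum allowed Gamma shape
_PENALTY = 1e10

#: nested family pairs (null, alternative) valid for likelihood-ratio tests
NESTED_FAMILIES = {
    ("neutral", "gamma"),
    ("neutral", "gammaexpo"),
    ("gamma", "gammaexpo"),
    ("gamma", "displgamma"),
}


# ---------------------------------------------------------------------------
# Parameter transform
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    p = min(max(p, 1e-10), 1 - 1e-10)
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


class _Transform:
    """Bijection between ModelParams and an unconstrained vector."""

    def __init__(self, family: str, n_classes: int, variant: str):
        self.family = family
        self.n_classes = n_classes
        self.variant = variant
        self.dfe_cls = FAMILIES[family]
        self.dfe_specs = self.dfe_cls.PARAM_SPECS
        self.names = ["theta", "T"]
        self.names += [f"r{i}" for i in range(2, n_classes + 1)]
        if variant == "standard":
            self.names.append("A")
        self.names += [name for name, _ in self.dfe_specs]
        self.n_dim = len(self.names)

    def bounds(self) -> list[tuple[float, float]]:
        bounds = [(-_BOUND, _BOUND)] * self.n_dim
        offset = self.n_dim - len(self.dfe_specs)
        for k, (_, kind) in enumerate(self.dfe_specs):
            if kind == "positive_capped":
                bounds[offset + k] = (-_BOUND, math.log(_SHAPE_CAP))
        return bounds

    def pack(self, params: ModelParams) -> np.ndarray:
        x = [math.log(params.theta), math.log(params.T)]
        x += [math.log(ri) for ri in params.r[1:]]
        if self.variant == "standard":
            x.append(math.log(max(params.A, 1e-10)))
        for name, kind in self.dfe_specs:
            v = params.dfe.params()[name]
            x.append(_logit(v) if kind == "proportion" else math.log(max(v, 1e-10)))
        return np.clip(np.asarray(x), -_BOUND, _BOUND)

    def unpack(self, x: np.ndarray) -> ModelParams:
        pos = 0
        theta = math.exp(x[pos]); pos += 1
        T = math.exp(x[pos]); pos += 1
        r = np.empty(self.n_classes)
        r[0] = 1.0
        for i in range(1, self.n_classes):
            r[i] = math.exp(x[pos]); pos += 1
        A = 0.0
        if self.variant == "standard":
            A = math.exp(x[pos]); pos += 1
        dfe_params = {}
        for name, kind in self.dfe_specs:
            dfe_params[name] = _expit(x[pos]) if kind == "proportion" else math.exp(x[pos])
            pos += 1
        return ModelParams(theta=theta, r=r, T=T, A=A, dfe=self.dfe_cls(**dfe_params))


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    params_hat: ModelParams
    loglik: float
    aic: float
    n_free: int
    converged: bool
    n_restarts_used: int
    variant: str
    family: str

    def to_text(self) -> str:
        """Structured key=value serialization."""
        lines = [
            f"family={self.family}",
            f"variant={self.variant}",
            f"loglik={self.loglik!r}",
            f"aic={self.aic!r}",
            f"n_free={self.n_free}",
            f"converged={self.converged}",
            f"n_restarts_used={self.n_restarts_used}",
            f"theta={self.params_hat.theta!r}",
            f"T={self.params_hat.T!r}",
            f"A={self.params_hat.A!r}",
            "r=" + ",".join(repr(float(v)) for v in self.params_hat.r),
        ]
        for name, value in self.params_hat.dfe.params().items():
            lines.append(f"dfe.{name}={value!r}")
        return "\n".join(lines) + "\n"


def n_free_params(family: str, n_classes: int, variant: str) -> int:
    base = 2 + (n_classes - 1) + len(FAMILIES[family].PARAM_SPECS)
    return base + (1 if variant == "standard" else 0)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

_DFE_GRIDS: dict[str, list[dict]] = {
    "neutral": [{"f_neutral": f} for f in (0.2, 0.5, 0.8)],
    "gamma": [
        {"shape": b, "mean_del": m} for b in (0.2, 1.0) for m in (10.0, 1000.0)
    ],
    "gammaexpo": [
        {"shape": b, "mean_del": m, "p_pos": 0.02, "mean_adv": 2.0}
        for b in (0.2, 1.0) for m in (10.0, 1000.0)
    ],
    "scaledbeta": [
        {"a": a, "b": b, "w_mild": w}
        for (a, b) in ((1.0, 1.0), (0.5, 2.0)) for w in (0.3, 0.7)
    ],
    "displgamma": [
        {"shape": b, "mean_del": m, "displacement": 0.01}
        for b in (0.2, 1.0) for m in (10.0, 1000.0)
    ],
}


def _neutral_syn_shape(shape: DatasetShape) -> np.ndarray:
    """Expected synonymous SFS shape per unit theta*L_S (r = 1)."""
    probe = ModelParams(
        theta=1.0, r=np.ones(shape.n_classes), T=1.0, A=0.0,
        dfe=make_dfe("neutral", f_neutral=1.0),
    )
    return expected_data(probe, shape, n_x=8, n_s=4).exp_PS / shape.L_S


def _moment_start(
    dataset: PolyDivDataset, family: str, variant: str,
    n_x: int, n_s: int,
) -> ModelParams:
    """Method-of-moments initialization: theta and r from the synonymous
    SFS, T from D_S, the DFE from a coarse grid."""
    shape = DatasetShape.of(dataset)
    c = _neutral_syn_shape(shape)
    ps = dataset.sfs_syn.counts
    theta0 = ps[0] / (dataset.L_S * c[0]) if ps[0] > 0 else \
        max(ps.sum(), 1.0) / (dataset.L_S * c.sum())
    theta0 = max(theta0, 1e-8)
    with np.errstate(divide="ignore"):
        r0 = ps / (theta0 * dataset.L_S * c)
    r0 = np.clip(np.nan_to_num(r0, nan=1.0, posinf=10.0), 0.1, 10.0)
    r0[0] = 1.0
    T0 = max(dataset.D_S / dataset.Ldiv_S, 1e-8)
    A0 = max(0.01 * dataset.D_N, 0.1) if variant == "standard" else 0.0

    best, best_ll = None, -np.inf
    for dfe_kwargs in _DFE_GRIDS[family]:
        cand = ModelParams(theta=theta0, r=r0, T=T0, A=A0,
                           dfe=make_dfe(family, **dfe_kwargs))
        ll = log_likelihood(dataset, cand, n_x=n_x, n_s=n_s)
        if ll > best_ll:
            best, best_ll = cand, ll
    return best


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _negloglik(x: np.ndarray, transform: _Transform, dataset: PolyDivDataset,
               n_x: int, n_s: int, T_override=None) -> float:
    try:
        params = transform.unpack(x)
        if T_override is not None:
            T = T_override(params)
            if not np.isfinite(T) or T <= 0:
                return _PENALTY
            params = replace(params, T=T)
        ll = log_likelihood(dataset, params, n_x=n_x, n_s=n_s)
    except (ValueError, FloatingPointError, OverflowError):
        return _PENALTY
    if not np.isfinite(ll):
        return _PENALTY
    return -ll


def fit(
    dataset: PolyDivDataset,
    dfe_family: str,
    variant: str = "standard",
    restarts: int = 5,
    seed: int = 0,
    n_x: int = N_X_NODES,
    n_s: int = N_S_NODES,
    ftol: float = 1e-10,
    gtol: float = 1e-7,
    max_iter: int = 1000,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one DFE family to one dataset.

    ``variant="minus_A"`` pins A = 0 (only for families with positive-effect
    support).  The best of ``restarts`` local optimizations is returned;
    results are deterministic given ``seed``.
    """
    family = dfe_family.lower()
    if family not in FAMILIES:
        raise ValueError(f"unknown DFE family {dfe_family!r}")
    if variant not in ("standard", "minus_A"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "minus_A" and family not in POSITIVE_EFFECT_FAMILIES:
        raise ValueError(
            f"the [-A] variant requires a DFE family with positive-effect "
            f"support, not {family!r}"
        )
    shape = DatasetShape.of(dataset)
    if shape.n_classes < 2:
        raise ValueError("at least 2 SFS classes are required")
    transform = _Transform(family, shape.n_classes, variant)
    bounds = transform.bounds()
    rng = np.random.default_rng(seed)

    if x0 is None:
        x0 = transform.pack(_moment_start(dataset, family, variant, n_x, n_s))
    starts = [x0]
    for _ in range(restarts - 1):
        jitter = rng.normal(0.0, 0.4, size=transform.n_dim)
        # shake DFE coordinates harder than the well-initialized nuisance ones
        jitter[-len(transform.dfe_specs):] *= 3.0
        starts.append(np.clip(x0 + jitter, [b[0] for b in bounds],
                              [b[1] for b in bounds]))

    results = []
    for start in starts:
        res = optimize.minimize(
            _negloglik, start, args=(transform, dataset, n_x, n_s),
            method="L-BFGS-B", bounds=bounds,
            options={"ftol": ftol, "gtol": gtol, "maxiter": max_iter},
        )
        results.append(res)
    best = min(results, key=lambda r: r.fun)
    n_used = sum(1 for r in results if r.fun <= best.fun + 1e-4)
    params_hat = transform.unpack(best.x)
    loglik = -best.fun
    nf = n_free_params(family, shape.n_classes, variant)
    converged = bool(best.success) and best.fun < _PENALTY / 2
    if not converged:
        logger.warning("fit %s/%s did not converge: %s", family, variant, best.message)
    return FitResult(
        params_hat=params_hat, loglik=loglik, aic=2.0 * nf - 2.0 * loglik,
        n_free=nf, converged=converged, n_restarts_used=n_used,
        variant=variant, family=family,
    )


def fit_minus_A(dataset: PolyDivDataset, dfe_family: str, **options) -> FitResult:
    """Fit with the strong-adaptive divergence excess A pinned to zero."""
    return fit(dataset, dfe_family, variant="minus_A", **options)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def lrt(null: FitResult, alt: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested pair: (statistic, df, p-value)."""
    same_family_variants = (
        null.family == alt.family
        and null.variant == "minus_A" and alt.variant == "standard"
    )
    nested_families = (
        null.variant == alt.variant
        and (null.family, alt.family) in NESTED_FAMILIES
    )
    if not (same_family_variants or nested_families):
        raise ValueError(
            f"({null.family},{null.variant}) is not nested in "
            f"({alt.family},{alt.variant})"
        )
    df = alt.n_free - null.n_free
    if df < 1:
        raise ValueError("alternative must have more free parameters")
    statistic = max(0.0, 2.0 * (alt.loglik - null.loglik))
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def model_scan(
    dataset: PolyDivDataset,
    families: Sequence[str] = ("neutral", "gamma", "gammaexpo", "scaledbeta"),
    **options,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit several DFE families and rank them by AIC.

    Returns the ranking table (AIC ascending, ties broken toward fewer
    parameters) plus the fits; nested pairs get pairwise LRT p-values.
    """
    fits = {fam: fit(dataset, fam, **options) for fam in families}
    rows = []
    for fam, fr in fits.items():
        rows.append({
            "family": fam, "variant": fr.variant, "loglik": fr.loglik,
            "n_free": fr.n_free, "AIC": fr.aic, "converged": fr.converged,
        })
    table = pd.DataFrame(rows).sort_values(
        ["AIC", "n_free"], kind="mergesort").reset_index(drop=True)
    table["delta_AIC"] = table["AIC"] - table["AIC"].iloc[0]
    lrt_rows = []
    for (n_fam, a_fam) in NESTED_FAMILIES:
        if n_fam in fits and a_fam in fits:
            st, df, p = lrt(fits[n_fam], fits[a_fam])
            lrt_rows.append({"null": n_fam, "alt": a_fam,
                             "statistic": st, "df": df, "p": p})
    table.attrs["lrt"] = pd.DataFrame(lrt_rows)
    return table, fits


# ---------------------------------------------------------------------------
# Profile-likelihood confidence interval for alpha
# ---------------------------------------------------------------------------

def _alpha_of(params: ModelParams, dataset: PolyDivDataset,
              S_adv: float, n_s: int) -> float:
    from .adaptive_rate import expected_nonadaptive_divergence
    dnna = expected_nonadaptive_divergence(params, dataset.Ldiv_N, S_adv, n_s)
    return 1.0 - dnna / dataset.D_N


def profile_ci_alpha(
    dataset: PolyDivDataset,
    fit_result: FitResult,
    drop: float = 2.0,
    S_adv: float = DEFAULT_S_ADV,
    step: float = 0.02,
    max_steps: int = 100,
    n_x: int = N_X_NODES,
    n_s: int = N_S_NODES,
    ftol: float = 1e-10,
) -> tuple[float, float, bool]:
    """Profile-likelihood interval for alpha.

    Walks an alpha grid outward from the ML estimate; at each grid point the
    likelihood is re-maximized subject to alpha(params) = alpha0 (the
    constraint is eliminated analytically: it pins T given the DFE).  The
    bound is where the profile crosses ``loglik_max - drop``, located by
    linear interpolation.  Returns (low, high, clipped): ``clipped`` is True
    when a bound hit the feasible-range edge (alpha -> 1).
    """
    if dataset.D_N <= 0:
        raise ValueError("alpha is undefined for D_N = 0")
    alpha_hat = _alpha_of(fit_result.params_hat, dataset, S_adv, n_s)
    if drop <= 0:
        return alpha_hat, alpha_hat, False
    transform = _Transform(fit_result.family, DatasetShape.of(dataset).n_classes,
                           fit_result.variant)
    bounds = transform.bounds()
    # freeze the T coordinate: it is determined by the alpha constraint
    t_index = transform.names.index("T")
    x_hat = transform.pack(fit_result.params_hat)
    bounds[t_index] = (x_hat[t_index], x_hat[t_index])
    ll_max = fit_result.loglik
    threshold = ll_max - drop

    def profile_at(alpha0: float, x_start: np.ndarray) -> tuple[float, np.ndarray]:
        def t_override(params: ModelParams) -> float:
            i_na = nonadaptive_fixation_integral(params.dfe, S_adv, n_s)
            if i_na <= 0:
                return float("nan")
            return (1.0 - alpha0) * dataset.D_N / (dataset.Ldiv_N * i_na)

        res = optimize.minimize(
            _negloglik, x_start, args=(transform, dataset, n_x, n_s, t_override),
            method="L-BFGS-B", bounds=bounds, options={"ftol": ftol, "maxiter": 500},
        )
        return -res.fun, res.x

    clipped = False

    def walk(direction: int) -> float:
        nonlocal clipped
        alpha_prev, ll_prev, x_prev = alpha_hat, ll_max, x_hat.copy()
        for k in range(1, max_steps + 1):
            alpha0 = alpha_hat + direction * k * step
            if alpha0 >= 1.0 - 1e-9:
                clipped = True
                return 1.0
            ll, x_prev = profile_at(alpha0, x_prev)
            if ll < threshold:
                # crossing between alpha_prev and alpha0
                frac = (ll_prev - threshold) / max(ll_prev - ll, 1e-12)
                return alpha_prev + frac * (alpha0 - alpha_prev)
            alpha_prev, ll_prev = alpha0, ll
        clipped = True
        return alpha_prev

    high = walk(+1)
    low = walk(-1)
    return low, high, clipped
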