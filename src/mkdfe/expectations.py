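"""Expected polymorphism and divergence under a DFE, and the Poisson likelihood.

The model follows the Poisson random field tradition.  With theta = 4*Ne*mu
per site, nuisance SFS-distortion multipliers r_i (r_1 = 1), scaled
divergence time T = mu*t and a DFE Phi(S) over S = 4*Ne*s:

* synonymous SNPs in derived-allele class i:   E[P_S[i]] = theta * L_S * r_i / i
* non-synonymous:  E[P_N[i]] = (theta/2) * L_N * r_i * E_Phi[ G(S, i, n) ]
* synonymous substitutions:                    E[D_S] = Ldiv_S * T
* non-synonymous:  E[D_N] = Ldiv_N * T * E_Phi[ F(S) ] + A

G(S, i, n) integrates the diffusion sojourn-time density H(S, x) against the
binomial sampling probability of observing i derived copies among 2n
chromosomes; it is scaled so that G(0, i, n) = 2/i, which makes the fully
neutral non-synonymous expectation collapse to theta * L_N * r_i / i.
F(S) = S / (1 - exp(-S)) is the scaled fixation probability (F(0) = 1).
A >= 0 is an additive divergence excess standing for strongly advantageous
substitutions that leave no polymorphism footprint.

All counts (SFS classes, D_N, D_S) are modelled as independent Poisson
draws; fractional observed counts (from hypergeometric projection) are
handled by the log-Gamma extension of the Poisson log-density.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy.special import gammaln

from .dfe import DFEModel, LETHAL
from .spectra import PolyDivDataset

# Quadrature defaults: Gauss-Legendre node counts for the allele-frequency
# integral (x in (0,1)) and for each continuous DFE branch (quantile space).
N_X_NODES = 256
N_S_NODES = 64

# Beyond this, H and F switch to their asymptotic forms (exp overflow guard).
_S_ASYMPTOTIC = 500.0


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Full free-parameter set of the likelihood.

    ``r`` has one entry per SFS class of the dataset being fitted
    (2n - 1 unfolded, n folded) with ``r[0] = 1`` fixed.
    """

    theta: float
    r: np.ndarray
    T: float
    A: float
    dfe: DFEModel

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        if self.theta <= 0 or self.T <= 0:
            raise ValueError("theta and T must be positive")
        if self.A < 0:
            raise ValueError("A must be non-negative")
        if r.ndim != 1 or len(r) < 1:
            raise ValueError("r must be a non-empty vector")
        if abs(r[0] - 1.0) > 1e-12:
            raise ValueError("r[0] (the class-1 multiplier) must equal 1")
        if np.any(r <= 0):
            raise ValueError("all r entries must be positive")


@dataclass(frozen=True)
class DatasetShape:
    """Geometry of a dataset: what expected_data needs besides parameters."""

    n_chrom: int
    folded: bool
    L_N: float
    L_S: float
    Ldiv_N: float
    Ldiv_S: float

    @classmethod
    def of(cls, ds: PolyDivDataset) -> "DatasetShape":
        return cls(ds.n_chrom, ds.folded, ds.L_N, ds.L_S, ds.Ldiv_N, ds.Ldiv_S)

    @property
    def n_classes(self) -> int:
        return self.n_chrom // 2 if self.folded else self.n_chrom - 1


@dataclass(frozen=True)
class ExpectedData:
    exp_PN: np.ndarray
    exp_PS: np.ndarray
    exp_DN: float
    exp_DS: float


# ---------------------------------------------------------------------------
# Diffusion kernels
# ---------------------------------------------------------------------------

def sojourn_density(S, x):
    """Relative sojourn time H(S, x) of a mutation with scaled effect S.

    H(S, x) = 2 (1 - exp(-S(1-x))) / (x (1-x) (1 - exp(-S))), with the
    neutral limit H(0, x) = 2/x.  S > 0 is advantageous.  Broadcasts over
    numpy inputs.
    """
    S = np.asarray(S, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("x must lie strictly in (0, 1)")
    S, x = np.broadcast_arrays(S, x)
    out = np.empty_like(x)

    neutral = np.abs(S) < 1e-8
    out[neutral] = 2.0 / x[neutral]

    pos = ~neutral & (S > 0)
    # arguments are <= 0: no overflow for any positive S
    out[pos] = 2.0 * np.expm1(-S[pos] * (1 - x[pos])) / (
        x[pos] * (1 - x[pos]) * np.expm1(-S[pos]))

    neg = ~neutral & (S < 0)
    # rearranged so every exponent is negative: 2 e^{Sx} expm1(S(1-x)) /
    # (x(1-x) expm1(S)); exact, overflow-free for arbitrarily negative S
    Sn, xn = S[neg], x[neg]
    out[neg] = 2.0 * np.exp(Sn * xn) * np.expm1(Sn * (1 - xn)) / (
        xn * (1 - xn) * np.expm1(Sn))
    return out if out.ndim else float(out)


def sampling_prob(i, n_chrom: int, x):
    """Binomial probability of observing i derived copies among 2n draws."""
    i = np.asarray(i)
    x = np.asarray(x, dtype=float)
    logc = gammaln(n_chrom + 1) - gammaln(i + 1) - gammaln(n_chrom - i + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = logc + i * np.log(x) + (n_chrom - i) * np.log1p(-x)
    out = np.exp(logp)
    return out if np.ndim(out) else float(out)


@lru_cache(maxsize=16)
def _leggauss01(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights mapped from (-1,1) to (0,1)."""
    nodes, weights = np.polynomial.legendre.leggauss(n)
    return 0.5 * (nodes + 1.0), 0.5 * weights


@lru_cache(maxsize=64)
def _binom_matrix(n_chrom: int, n_x: int) -> np.ndarray:
    """Matrix Q[k, i-1] = q(i, n, x_k) for the x-quadrature nodes."""
    x, _ = _leggauss01(n_x)
    i = np.arange(1, n_chrom)
    return sampling_prob(i[None, :], n_chrom, x[:, None])


def _seg_factor_asymptotic(S: np.ndarray, n_chrom: int) -> np.ndarray:
    """G for strongly deleterious S: 2 C(2n,i) Gamma(i) / |S|^i per class."""
    i = np.arange(1, n_chrom)
    logc = gammaln(n_chrom + 1) - gammaln(i + 1) - gammaln(n_chrom - i + 1)
    logg = np.log(2.0) + logc + gammaln(i) - i[None, :] * np.log(np.abs(S))[:, None]
    return np.exp(logg)


def seg_factor_vector(S, n_chrom: int, n_x: int = N_X_NODES) -> np.ndarray:
    """G(S, i, n) for all classes i = 1..2n-1 at once; shape (len(S), 2n-1).

    Numeric Gauss-Legendre quadrature of H(S, x) * q(i, n, x) over x in
    (0, 1); for S below the overflow threshold the closed asymptotic form
    (sharp boundary layer at x -> 0) is used instead.
    """
    S = np.atleast_1d(np.asarray(S, dtype=float))
    x, w = _leggauss01(n_x)
    Q = _binom_matrix(n_chrom, n_x)
    out = np.empty((len(S), n_chrom - 1))
    safe = S > -_S_ASYMPTOTIC
    if np.any(safe):
        H = sojourn_density(S[safe, None], x[None, :])
        out[safe] = (H * w[None, :]) @ Q
    if np.any(~safe):
        out[~safe] = _seg_factor_asymptotic(S[~safe], n_chrom)
    return out


def seg_factor(S: float, i: int, n_chrom: int, n_x: int = N_X_NODES) -> float:
    """G(S, i, n) for one class; G(0, i, n) = 2/i."""
    if not 1 <= i <= n_chrom - 1:
        raise ValueError(f"class i={i} outside 1..{n_chrom - 1}")
    return float(seg_factor_vector(np.array([S]), n_chrom, n_x)[0, i - 1])


def fixation_factor(S):
    """Scaled fixation probability F(S) = S / (1 - exp(-S)); F(0) = 1."""
    S = np.asarray(S, dtype=float)
    Sc = np.clip(S, -_S_ASYMPTOTIC - 200.0, None)
    with np.errstate(over="ignore"):
        out = np.where(np.abs(Sc) < 1e-12, 1.0, -Sc / np.expm1(-np.where(np.abs(Sc) < 1e-12, 1.0, Sc)))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# DFE expectations (quantile-transform quadrature over branches)
# ---------------------------------------------------------------------------

def dfe_expectation(
    model: DFEModel,
    func: Callable[[np.ndarray], np.ndarray],
    upper_S: float | None = None,
    n_s: int = N_S_NODES,
):
    """E_Phi[func(S)], optionally restricted to S < upper_S.

    ``func`` maps an array of S values to an array of values (extra trailing
    axes allowed).  Point masses are included (the lethal class contributes
    zero); each continuous branch is integrated in quantile space -- the
    change of variable u = CDF(x) turns the weighted integral into a plain
    integral of func over (0, 1), handled by Gauss-Legendre nodes.
    """
    u, w = _leggauss01(n_s)
    total = 0.0
    for mass_loc, mass in model.point_masses():
        if mass_loc == LETHAL or mass == 0.0:
            continue
        if upper_S is not None and mass_loc >= upper_S:
            continue
        total = total + mass * np.asarray(func(np.array([float(mass_loc)])))[0]
    for br in model.branches():
        if br.weight == 0.0:
            continue
        u0, u1 = 0.0, 1.0
        if upper_S is not None:
            # S = loc + sign * X <= upper_S
            if br.sign > 0:
                hi = upper_S - br.loc
                if hi <= 0:
                    continue
                u1 = float(br.cdf(hi))
            else:
                lo = br.loc - upper_S
                if lo > 0:
                    u0 = float(br.cdf(lo))
        if u1 <= u0:
            continue
        uu = u0 + (u1 - u0) * u
        X = br.ppf(uu)
        S = br.loc + br.sign * X
        vals = np.asarray(func(S))
        total = total + br.weight * (u1 - u0) * np.tensordot(w, vals, axes=(0, 0))
    return total


# ---------------------------------------------------------------------------
# Expected data and likelihood
# ---------------------------------------------------------------------------

def _fold_vector(v: np.ndarray, n_chrom: int) -> np.ndarray:
    n = n_chrom // 2
    out = np.empty(n)
    out[: n - 1] = v[: n - 1] + v[: n - 1 : -1]
    out[n - 1] = v[n - 1]
    return out


def expected_data(
    params: ModelParams,
    shape: DatasetShape | PolyDivDataset,
    n_x: int = N_X_NODES,
    n_s: int = N_S_NODES,
) -> ExpectedData:
    """Expected SFS vectors and divergence counts under ``params``.

    Folded expectations are the sums of the corresponding unfolded mirror
    classes, with the per-class multipliers r applied after folding.
    """
    if isinstance(shape, PolyDivDataset):
        shape = DatasetShape.of(shape)
    if len(params.r) != shape.n_classes:
        raise ValueError(
            f"r has {len(params.r)} entries, dataset has {shape.n_classes} classes"
        )
    two_n = shape.n_chrom
    i = np.arange(1, two_n)

    base_s = params.theta * shape.L_S / i
    g_bar = dfe_expectation(
        params.dfe, lambda S: seg_factor_vector(S, two_n, n_x), n_s=n_s
    )
    base_n = 0.5 * params.theta * shape.L_N * np.asarray(g_bar)

    if shape.folded:
        base_s = _fold_vector(base_s, two_n)
        base_n = _fold_vector(base_n, two_n)
    exp_PS = base_s * params.r
    exp_PN = base_n * params.r

    exp_DS = shape.Ldiv_S * params.T
    f_bar = float(dfe_expectation(params.dfe, fixation_factor, n_s=n_s))
    exp_DN = shape.Ldiv_N * params.T * f_bar + params.A
    return ExpectedData(exp_PN=exp_PN, exp_PS=exp_PS, exp_DN=exp_DN, exp_DS=exp_DS)


def _poisson_terms(observed: np.ndarray, expected: np.ndarray) -> float:
    """Sum of Poisson log-densities, log-Gamma extended to real counts."""
    a = np.asarray(observed, dtype=float)
    b = np.asarray(expected, dtype=float)
    if np.any((b <= 0) & (a > 0)):
        return -np.inf
    ok = b > 0
    terms = -b[ok] + a[ok] * np.log(b[ok]) - gammaln(a[ok] + 1.0)
    return float(terms.sum())


def log_likelihood(
    dataset: PolyDivDataset,
    params: ModelParams,
    n_x: int = N_X_NODES,
    n_s: int = N_S_NODES,
) -> float:
    """Poisson log-likelihood of one dataset under ``params``."""
    exp = expected_data(params, DatasetShape.of(dataset), n_x=n_x, n_s=n_s)
    ll = _poisson_terms(dataset.sfs_nonsyn.counts, exp.exp_PN)
    ll += _poisson_terms(dataset.sfs_syn.counts, exp.exp_PS)
    ll += _poisson_terms(np.array([dataset.D_N]), np.array([exp.exp_DN]))
    ll += _poisson_terms(np.array([dataset.D_S]), np.array([exp.exp_DS]))
    return ll
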