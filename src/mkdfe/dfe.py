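"""Distributions of fitness effects (DFE) over scaled selection coefficients.

A DFE is a distribution Phi(S) over S = 4*Ne*s, the population-scaled
selection coefficient of a new non-synonymous mutation.  Families mix a
continuous density with optional point masses: a neutral class at S = 0
and a "strongly deleterious" (lethal) class that contributes nothing to
either polymorphism or divergence.

Families
--------
neutral
    Discrete: mass ``f_neutral`` at S = 0, the rest strongly deleterious.
gamma
    -S ~ Gamma(shape, mean): purely deleterious continuous effects.
gammaexpo
    Mixture of a negative Gamma (weight 1 - p_pos) and a positive
    Exponential(mean_adv) (weight p_pos): weakly advantageous mutations.
scaledbeta
    Weight ``w_mild`` of mild effects with S/(2*S_max) + 0.5 ~ Beta(a, b)
    on [-S_max, S_max] (S_max = 25 by default); the rest strongly
    deleterious.
displgamma
    (d - S) ~ Gamma(shape, mean): a negative Gamma displaced by d >= 0, so
    effects up to S = d are possible.

Each continuous component is exposed as a *branch* with S = loc + sign * X,
where X >= 0 follows a Gamma, Exponential or scaled Beta law.  Downstream
quadrature integrates expectations over branches through the quantile
function (exact importance sampling of the density), which handles
heavy-tailed Gammas with small shape gracefully.  Branches evaluate their
ppf/cdf/pdf through scipy.special primitives directly -- constructing
frozen scipy distributions inside the likelihood loop is far too slow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import ClassVar

import numpy as np
from scipy import special

LETHAL = "lethal"


class Branch:
    """One continuous DFE component: S = loc + sign * X with X >= 0."""

    __slots__ = ("weight", "sign", "loc")

    def __init__(self, weight: float, sign: int, loc: float):
        self.weight = weight
        self.sign = sign
        self.loc = loc

    def ppf(self, u):          # quantile of X
        raise NotImplementedError

    def cdf(self, x):          # CDF of X
        raise NotImplementedError

    def pdf(self, x):          # density of X
        raise NotImplementedError


class GammaBranch(Branch):
    __slots__ = ("shape", "scale")

    def __init__(self, weight, sign, loc, shape, scale):
        super().__init__(weight, sign, loc)
        self.shape = shape
        self.scale = scale

    def ppf(self, u):
        return self.scale * special.gammaincinv(self.shape, u)

    def cdf(self, x):
        return special.gammainc(self.shape, np.asarray(x) / self.scale)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = ((self.shape - 1) * np.log(x) - x / self.scale
                    - special.gammaln(self.shape) - self.shape * np.log(self.scale))
        return np.where(x > 0, np.exp(logp),
                        np.where((x == 0) & (self.shape >= 1),
                                 0.0 if self.shape > 1 else 1.0 / self.scale, 0.0))


class ExponBranch(Branch):
    __slots__ = ("mean",)

    def __init__(self, weight, sign, loc, mean):
        super().__init__(weight, sign, loc)
        self.mean = mean

    def ppf(self, u):
        return -self.mean * np.log1p(-np.asarray(u))

    def cdf(self, x):
        return -np.expm1(-np.asarray(x) / self.mean)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x >= 0, np.exp(-x / self.mean) / self.mean, 0.0)


class BetaBranch(Branch):
    """X = scale * B with B ~ Beta(a, b)."""

    __slots__ = ("a", "b", "scale")

    def __init__(self, weight, sign, loc, a, b, scale):
        super().__init__(weight, sign, loc)
        self.a = a
        self.b = b
        self.scale = scale

    def ppf(self, u):
        return self.scale * special.betaincinv(self.a, self.b, u)

    def cdf(self, x):
        z = np.clip(np.asarray(x, dtype=float) / self.scale, 0.0, 1.0)
        return special.betainc(self.a, self.b, z)

    def pdf(self, x):
        z = np.asarray(x, dtype=float) / self.scale
        inside = (z > 0) & (z < 1)
        zc = np.where(inside, z, 0.5)
        logp = ((self.a - 1) * np.log(zc) + (self.b - 1) * np.log1p(-zc)
                - special.betaln(self.a, self.b)) - np.log(self.scale)
        return np.where(inside, np.exp(logp), 0.0)


def _check_proportion(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class DFEModel:
    """Base class; use the concrete families or :func:`make_dfe`."""

    #: parameter metadata: (name, kind) with kind in
    #: {"proportion", "positive", "positive_capped", "nonneg"}
    PARAM_SPECS: ClassVar[tuple[tuple[str, str], ...]] = ()
    family: ClassVar[str] = ""

    def params(self) -> dict[str, float]:
        return {name: getattr(self, name) for name, _ in self.PARAM_SPECS}

    def n_free_params(self) -> int:
        return len(self.PARAM_SPECS)

    def branches(self) -> list[Branch]:
        """Continuous components as quantile-integrable branches."""
        raise NotImplementedError

    def point_masses(self) -> list[tuple[float | str, float]]:
        """(S-location or "lethal", mass) pairs for the discrete part."""
        return []

    def density(self, S) -> np.ndarray:
        """Continuous-part density at S (point masses reported separately)."""
        S = np.asarray(S, dtype=float)
        out = np.zeros_like(S)
        for br in self.branches():
            x = br.sign * (S - br.loc)
            out = out + br.weight * np.where(x >= 0, br.pdf(np.maximum(x, 0.0)), 0.0)
        return out

    def continuous_mass(self) -> float:
        return sum(br.weight for br in self.branches())

    def with_params(self, **updates) -> "DFEModel":
        merged = {**self.params(), **updates}
        return type(self)(**merged)


@dataclass(frozen=True)
class Neutral(DFEModel):
    """Neutral + strongly deleterious discrete DFE."""

    f_neutral: float = 0.5

    PARAM_SPECS: ClassVar = (("f_neutral", "proportion"),)
    family: ClassVar[str] = "neutral"

    def __post_init__(self) -> None:
        _check_proportion("f_neutral", self.f_neutral)

    def branches(self) -> list[Branch]:
        return []

    def point_masses(self):
        return [(0.0, self.f_neutral), (LETHAL, 1.0 - self.f_neutral)]


@dataclass(frozen=True)
class Gamma(DFEModel):
    """Purely deleterious: -S ~ Gamma(shape, mean)."""

    shape: float = 0.3
    mean_del: float = 1000.0

    PARAM_SPECS: ClassVar = (("shape", "positive_capped"), ("mean_del", "positive"))
    family: ClassVar[str] = "gamma"

    def __post_init__(self) -> None:
        _check_positive("shape", self.shape)
        _check_positive("mean_del", self.mean_del)

    def branches(self) -> list[Branch]:
        return [GammaBranch(1.0, -1, 0.0, self.shape, self.mean_del / self.shape)]


@dataclass(frozen=True)
class GammaExpo(Gamma):
    """Negative Gamma plus an exponential tail of weak positive effects."""

    p_pos: float = 0.01
    mean_adv: float = 1.0

    PARAM_SPECS: ClassVar = (
        ("shape", "positive_capped"),
        ("mean_del", "positive"),
        ("p_pos", "proportion"),
        ("mean_adv", "positive"),
    )
    family: ClassVar[str] = "gammaexpo"

    def __post_init__(self) -> None:
        super().__post_init__()
        _check_proportion("p_pos", self.p_pos)
        _check_positive("mean_adv", self.mean_adv)

    def branches(self) -> list[Branch]:
        return [
            GammaBranch(1.0 - self.p_pos, -1, 0.0, self.shape,
                        self.mean_del / self.shape),
            ExponBranch(self.p_pos, +1, 0.0, self.mean_adv),
        ]


@dataclass(frozen=True)
class ScaledBeta(DFEModel):
    """Beta-shaped mild effects on [-S_max, S_max] plus a lethal class."""

    a: float = 1.0
    b: float = 1.0
    w_mild: float = 0.5
    S_max: float = 25.0

    PARAM_SPECS: ClassVar = (
        ("a", "positive"),
        ("b", "positive"),
        ("w_mild", "proportion"),
    )
    family: ClassVar[str] = "scaledbeta"

    def __post_init__(self) -> None:
        _check_positive("a", self.a)
        _check_positive("b", self.b)
        _check_proportion("w_mild", self.w_mild)
        _check_positive("S_max", self.S_max)

    def branches(self) -> list[Branch]:
        return [BetaBranch(self.w_mild, +1, -self.S_max,
                           self.a, self.b, 2.0 * self.S_max)]

    def point_masses(self):
        return [(LETHAL, 1.0 - self.w_mild)]

    def with_params(self, **updates) -> "ScaledBeta":
        merged = {**self.params(), **updates}
        return ScaledBeta(S_max=self.S_max, **merged)


@dataclass(frozen=True)
class DisplacedGamma(DFEModel):
    """(d - S) ~ Gamma(shape, mean): negative Gamma shifted right by d."""

    shape: float = 0.3
    mean_del: float = 1000.0
    displacement: float = 0.0

    PARAM_SPECS: ClassVar = (
        ("shape", "positive_capped"),
        ("mean_del", "positive"),
        ("displacement", "nonneg"),
    )
    family: ClassVar[str] = "displgamma"

    def __post_init__(self) -> None:
        _check_positive("shape", self.shape)
        _check_positive("mean_del", self.mean_del)
        if self.displacement < 0:
            raise ValueError(f"displacement must be >= 0, got {self.displacement}")

    def branches(self) -> list[Branch]:
        return [GammaBranch(1.0, -1, self.displacement,
                            self.shape, self.mean_del / self.shape)]


FAMILIES: dict[str, type[DFEModel]] = {
    cls.family: cls for cls in (Neutral, Gamma, GammaExpo, ScaledBeta, DisplacedGamma)
}

#: families with support on S > 0 (eligible for the [-A] variant)
POSITIVE_EFFECT_FAMILIES = ("gammaexpo", "scaledbeta", "displgamma")


def make_dfe(family: str, **params) -> DFEModel:
    """Construct a DFE by family name (``neutral``, ``gamma``, ...)."""
    try:
        cls = FAMILIES[family.lower()]
    except KeyError:
        raise ValueError(
            f"unknown DFE family {family!r}; choose from {sorted(FAMILIES)}"
        ) from None
    return cls(**params)


def density(model: DFEModel, S) -> np.ndarray:
    return model.density(S)


def point_masses(model: DFEModel) -> list[tuple[float | str, float]]:
    return model.point_masses()


def n_free_params(model: DFEModel) -> int:
    return model.n_free_params()
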