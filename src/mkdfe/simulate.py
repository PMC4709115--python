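"""Model-based synthetic data: Poisson sampling from model expectations.

Datasets are simulated at the level the likelihood models them: every SFS
class and both divergence counts are independent Poisson draws around the
expectations implied by a :class:`~mkdfe.expectations.ModelParams`.  This
exercises the estimator exactly at its own assumptions -- demographic
distortion enters through the r vector, ancestral-state misorientation by
multinomial thinning between mirror frequency classes.  Forward population
simulation (linkage, sweeps, fluctuating size) is deliberately out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adaptive_rate import DEFAULT_S_ADV, expected_nonadaptive_divergence
from .expectations import DatasetShape, ExpectedData, ModelParams, expected_data
from .spectra import PolyDivDataset, Spectrum


@dataclass(frozen=True)
class SimScenario:
    """A simulation design: generating parameters plus sampling geometry."""

    params: ModelParams
    n_chrom: int
    L_N: float
    L_S: float
    Ldiv_N: float = 0.0
    Ldiv_S: float = 0.0
    misorientation_rate: float = 0.0
    seed: int = 0
    n_replicates: int = 1
    label: str = "sim"
    S_adv: float = DEFAULT_S_ADV

    def __post_init__(self) -> None:
        if not 0.0 <= self.misorientation_rate < 1.0:
            raise ValueError("misorientation_rate must be in [0, 1)")
        if len(self.params.r) != self.n_chrom - 1:
            raise ValueError(
                "scenario r vector must have 2n-1 entries (unfolded classes)"
            )
        if self.Ldiv_N <= 0:
            object.__setattr__(self, "Ldiv_N", self.L_N)
        if self.Ldiv_S <= 0:
            object.__setattr__(self, "Ldiv_S", self.L_S)

    @property
    def shape(self) -> DatasetShape:
        return DatasetShape(self.n_chrom, False, self.L_N, self.L_S,
                            self.Ldiv_N, self.Ldiv_S)


def scenario_expectations(scenario: SimScenario) -> ExpectedData:
    return expected_data(scenario.params, scenario.shape)


def true_alpha(scenario: SimScenario) -> float:
    """alpha implied by the generating model, free of sampling noise.

    (E[D_N] - E[D_Nna]) / E[D_N], where E[D_N] includes the A excess and
    E[D_Nna] integrates the DFE below S_adv.
    """
    exp = scenario_expectations(scenario)
    dnna = expected_nonadaptive_divergence(
        scenario.params, scenario.Ldiv_N, scenario.S_adv)
    return (exp.exp_DN - dnna) / exp.exp_DN


def true_omega_a(scenario: SimScenario) -> float:
    """Expected adaptive rate (E[d_N] - E[d_Nna]) / E[d_S]."""
    exp = scenario_expectations(scenario)
    dnna = expected_nonadaptive_divergence(
        scenario.params, scenario.Ldiv_N, scenario.S_adv)
    return ((exp.exp_DN - dnna) / scenario.Ldiv_N) / (exp.exp_DS / scenario.Ldiv_S)


def _misorient(counts: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Move each SNP from class i to class 2n-i with probability ``rate``."""
    if rate == 0.0:
        return counts
    moved = rng.binomial(counts.astype(np.int64), rate)
    return counts - moved + moved[::-1]


def sample_dataset(scenario: SimScenario, replicate_index: int = 0) -> PolyDivDataset:
    """Draw one replicate dataset (deterministic in (scenario.seed, index))."""
    rng = np.random.default_rng([scenario.seed, replicate_index])
    exp = scenario_expectations(scenario)
    pn = rng.poisson(exp.exp_PN).astype(float)
    ps = rng.poisson(exp.exp_PS).astype(float)
    dn = float(rng.poisson(exp.exp_DN))
    ds = float(rng.poisson(exp.exp_DS))
    # misorientation last: scenarios differing only in the rate share the
    # same underlying sample, enabling paired folded/unfolded comparisons
    pn = _misorient(pn, scenario.misorientation_rate, rng).astype(float)
    ps = _misorient(ps, scenario.misorientation_rate, rng).astype(float)
    return PolyDivDataset(
        label=f"{scenario.label}_{replicate_index}",
        sfs_nonsyn=Spectrum(pn, scenario.n_chrom, False),
        sfs_syn=Spectrum(ps, scenario.n_chrom, False),
        D_N=dn, D_S=ds, L_N=scenario.L_N, L_S=scenario.L_S,
        Ldiv_N=scenario.Ldiv_N, Ldiv_S=scenario.Ldiv_S,
    )


def sample_replicates(scenario: SimScenario) -> list[PolyDivDataset]:
    return [sample_dataset(scenario, k) for k in range(scenario.n_replicates)]


def distortion_presets(name: str, n_chrom: int) -> np.ndarray:
    """Named r-vector generators for unfolded spectra (2n - 1 entries).

    ``flat``: all ones.  ``expansion-like``: r_i = i**-0.4 -- relative excess
    of rare variants once r_1 is normalized to 1, as after population
    growth.  ``bottleneck-like``: r_i = i**0.3 -- relative excess of
    intermediate/high-frequency variants.
    """
    i = np.arange(1, n_chrom, dtype=float)
    if name == "flat":
        return np.ones(n_chrom - 1)
    if name == "expansion-like":
        return i ** -0.4
    if name == "bottleneck-like":
        return i ** 0.3
    raise ValueError(f"unknown distortion preset {name!r}")


# ---------------------------------------------------------------------------
# Scenario files (key=value text)
# ---------------------------------------------------------------------------

def write_scenario(scenario: SimScenario, path) -> None:
    p = scenario.params
    lines = [
        f"label={scenario.label}",
        f"n_chrom={scenario.n_chrom}",
        f"L_N={scenario.L_N!r}", f"L_S={scenario.L_S!r}",
        f"Ldiv_N={scenario.Ldiv_N!r}", f"Ldiv_S={scenario.Ldiv_S!r}",
        f"misorientation_rate={scenario.misorientation_rate!r}",
        f"seed={scenario.seed}", f"n_replicates={scenario.n_replicates}",
        f"S_adv={scenario.S_adv!r}",
        f"theta={p.theta!r}", f"T={p.T!r}", f"A={p.A!r}",
        "r=" + ",".join(repr(float(v)) for v in p.r),
        f"dfe_family={p.dfe.family}",
    ]
    for name, value in p.dfe.params().items():
        lines.append(f"dfe.{name}={value!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_scenario(path) -> SimScenario:
    from .dfe import make_dfe

    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
    n_chrom = int(kv["n_chrom"])
    r_spec = kv.get("r", "flat")
    if r_spec in ("flat", "expansion-like", "bottleneck-like"):
        r = distortion_presets(r_spec, n_chrom)
    else:
        r = np.array([float(v) for v in r_spec.split(",")])
    dfe_params = {k[4:]: float(v) for k, v in kv.items() if k.startswith("dfe.")}
    params = ModelParams(
        theta=float(kv["theta"]), r=r, T=float(kv["T"]),
        A=float(kv.get("A", "0")), dfe=make_dfe(kv["dfe_family"], **dfe_params),
    )
    return SimScenario(
        params=params, n_chrom=n_chrom,
        L_N=float(kv["L_N"]), L_S=float(kv["L_S"]),
        Ldiv_N=float(kv.get("Ldiv_N", "0")), Ldiv_S=float(kv.get("Ldiv_S", "0")),
        misorientation_rate=float(kv.get("misorientation_rate", "0")),
        seed=int(kv.get("seed", "0")),
        n_replicates=int(kv.get("n_replicates", "1")),
        label=kv.get("label", "sim"), S_adv=float(kv.get("S_adv", DEFAULT_S_ADV)),
    )
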