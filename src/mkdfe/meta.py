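"""Cross-species comparative layer.

Collects per-species adaptive-rate estimates into a summary table and
regresses them against the synonymous diversity pi_S (the usual proxy for
effective population size) or arbitrary life-history covariates.  Also
provides the pi_N / pi_S log-log slope: under a Gamma DFE of shape beta the
slope of log(pi_N) on log(pi_S) across species is 1 - beta, so the
regression yields a cross-species DFE-shape estimate independent of any
single SFS fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SpeciesSummary:
    label: str
    pi_S: float
    pi_N: float
    dnds: float
    omega_na: float
    omega_a: float
    alpha: float
    covariates: dict[str, float] = field(default_factory=dict)


class CorrelationResult(NamedTuple):
    r: float
    r2: float
    p: float
    slope: float
    intercept: float
    n: int
    ok: bool


def _as_frame(table: Sequence[SpeciesSummary] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    rows = []
    for s in table:
        row = {"label": s.label, "pi_S": s.pi_S, "pi_N": s.pi_N,
               "dnds": s.dnds, "omega_na": s.omega_na,
               "omega_a": s.omega_a, "alpha": s.alpha}
        row.update(s.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def correlate(
    table: Sequence[SpeciesSummary] | pd.DataFrame,
    y: str,
    x: str,
    log_x: bool = False,
) -> CorrelationResult:
    """Pearson correlation and least-squares line of y on (log-)x.

    Natural logs are used when ``log_x``; rows with missing values are
    dropped.  Zero variance in either variable yields ``ok=False`` with
    NaN statistics rather than an exception.
    """
    df = _as_frame(table)[[x, y]].dropna()
    if len(df) < 3:
        raise ValueError(f"need at least 3 complete rows, got {len(df)}")
    xv = df[x].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    if log_x:
        if np.any(xv <= 0):
            raise ValueError(f"log_x requires strictly positive {x}")
        xv = np.log(xv)
    if np.std(xv) == 0 or np.std(yv) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                 len(df), False)
    lr = stats.linregress(xv, yv)
    return CorrelationResult(
        r=float(lr.rvalue), r2=float(lr.rvalue**2), p=float(lr.pvalue),
        slope=float(lr.slope), intercept=float(lr.intercept),
        n=len(df), ok=True,
    )


def pinpis_slope(table: Sequence[SpeciesSummary] | pd.DataFrame) -> tuple[float, float]:
    """Slope of log(pi_N) on log(pi_S) and the implied Gamma shape 1 - slope."""
    df = _as_frame(table)[["pi_S", "pi_N"]].dropna()
    if np.any(df.to_numpy() <= 0):
        raise ValueError("pinpis_slope requires strictly positive pi_N and pi_S")
    lr = stats.linregress(np.log(df["pi_S"]), np.log(df["pi_N"]))
    return float(lr.slope), 1.0 - float(lr.slope)


def regression_report(
    table: Sequence[SpeciesSummary] | pd.DataFrame,
    responses: Sequence[str] = ("alpha", "dnds", "omega_na", "omega_a"),
    predictor: str = "pi_S",
    log_x: bool = True,
) -> pd.DataFrame:
    """The standard comparative regressions: each response vs (log) pi_S."""
    rows = []
    for y in responses:
        res = correlate(table, y, predictor, log_x=log_x)
        rows.append({"response": y, "predictor": predictor, "log_x": log_x,
                     **res._asdict()})
    return pd.DataFrame(rows)


def load_covariates(path) -> pd.DataFrame:
    """Tab-separated covariate table keyed by a ``label`` column."""
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise ValueError("covariate table must have a 'label' column")
    return df
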