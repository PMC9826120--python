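"""The temperature-by-sex-ratio reaction norm.

In crocodilians the proportion of male hatchlings is a unimodal function of
constant incubation temperature (female - male - female).  The norm is
modelled as grouped-binomial logistic regression with a quadratic
temperature term,

    logit P(male | T) = b0 + b1 * T + b2 * T^2,

fitted by IRLS (statsmodels GLM).  Temperature is centered internally for
numerical stability and coefficients are reported on the raw-Celsius scale.
The vertex -b1 / (2 b2) estimates the male-maximizing temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class SexRatioRecord:
    """Hatchling sex ratio from one constant-temperature incubation."""

    temperature: float
    n_male: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not (0 <= self.n_male <= self.n_total):
            raise ValueError("require 0 <= n_male <= n_total")

    @property
    def weight(self) -> int:
        return self.n_total


def observed_sex_ratio(n_male: int, n_total: int) -> float:
    """Percent male, one decimal (e.g. 16/20 -> 80.0)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_male <= n_total):
        raise ValueError("require 0 <= n_male <= n_total")
    return round(100.0 * n_male / n_total, 1)


@dataclass
class ReactionNormFit:
    """Quadratic-logistic fit on the raw temperature scale."""

    b0: float
    b1: float
    b2: float
    cov: np.ndarray  # covariance of (b0, b1, b2), raw scale
    center: float
    separation_flagged: bool = False
    _centered_params: np.ndarray = field(default=None, repr=False)

    @property
    def vertex_temperature(self) -> float:
        """Temperature at the extremum of the fitted curve, -b1/(2 b2)."""
        if self.b2 == 0:
            return float("nan")
        return -self.b1 / (2.0 * self.b2)

    def predict(self, temperature: Sequence[float]) -> np.ndarray:
        t = np.asarray(temperature, dtype=float)
        eta = self.b0 + self.b1 * t + self.b2 * t * t
        return 1.0 / (1.0 + np.exp(-eta))

    def confidence_band(
        self, temperature: Sequence[float], level: float = 0.95
    ) -> pd.DataFrame:
        """Wald band on the link scale, inverse-linked to probabilities."""
        from scipy import stats as _st

        t = np.asarray(temperature, dtype=float)
        X = np.column_stack([np.ones_like(t), t, t * t])
        eta = X @ np.array([self.b0, self.b1, self.b2])
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, self.cov, X))
        z = _st.norm.ppf(0.5 + level / 2.0)
        inv = lambda x: 1.0 / (1.0 + np.exp(-x))
        return pd.DataFrame(
            {
                "temperature": t,
                "p_male": inv(eta),
                "lower": inv(eta - z * se),
                "upper": inv(eta + z * se),
            }
        )


def fit_reaction_norm(records: Sequence[SexRatioRecord]) -> ReactionNormFit:
    """Fit the quadratic-logistic reaction norm to grouped sex-ratio data.

    Requires at least three distinct temperatures.  Perfect or near-perfect
    separation (all fitted probabilities at the boundary) is flagged rather
    than raised, and the coefficients are still reported.
    """
    temps = np.array([r.temperature for r in records], dtype=float)
    if np.unique(temps).size < 3:
        raise ValueError("need >=3 distinct temperatures to fit a quadratic norm")
    males = np.array([r.n_male for r in records], dtype=float)
    totals = np.array([r.n_total for r in records], dtype=float)

    center = float(temps.mean())
    u = temps - center
    X = np.column_stack([np.ones_like(u), u, u * u])
    endog = np.column_stack([males, totals - males])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)

    a0, a1, a2 = res.params
    cov_c = np.asarray(res.cov_params())
    # back-transform centered coefficients: logit = a0 + a1 u + a2 u^2, u = T - c
    b2 = a2
    b1 = a1 - 2.0 * a2 * center
    b0 = a0 - a1 * center + a2 * center * center
    # delta-method jacobian d(b)/d(a)
    J = np.array(
        [
            [1.0, -center, center * center],
            [0.0, 1.0, -2.0 * center],
            [0.0, 0.0, 1.0],
        ]
    )
    cov = J @ cov_c @ J.T

    fitted = res.fittedvalues
    separated = bool(np.all((fitted < 1e-8) | (fitted > 1 - 1e-8)))
    if separated:
        warnings.warn("reaction-norm fit is degenerate (separation); flagged")
    fit = ReactionNormFit(
        b0=float(b0), b1=float(b1), b2=float(b2), cov=cov, center=center,
        separation_flagged=separated,
    )
    fit._centered_params = np.asarray(res.params)
    return fit


def read_sex_ratio_table(path, sep: str = "\t") -> list[SexRatioRecord]:
    """Read a TSV with columns temperature, n_male, n_total."""
    df = pd.read_csv(path, sep=sep)
    return [
        SexRatioRecord(float(r.temperature), int(r.n_male), int(r.n_total))
        for r in df.itertuples()
    ]
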