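"""Mesothelioma potency prediction and related regressions.

Potency is expressed throughout as R_M, the Hodgson–Darnton mesothelioma
potency factor in percent (excess mesothelioma mortality per unit
cumulative exposure).  Two models are provided:

* an EMPA-linear model, ``R_M = -0.012 + 0.011 * EMPA`` with EMPA in
  percent (0–100); negative outputs are reported verbatim and read as
  negligible potency, and
* a DCC + biosolubility log-linear model,
  ``log10(R_M) = 0.04 + 1.15*log10(Biosolubility) + 2.15*log10(DCC)``,
  with biosolubility the modelled fibre lifetime in years.

Also here: the width that maximises the DCC expression (closed form), the
cytotoxicity link ``log10(HC50) = -1.06 + 17.12*DCC`` (HC50 in fibres
x10^9/ml; higher HC50 = lower per-fibre cytotoxicity), the rat
intrapleural relative-potency link ``1.26 + 0.48*log10(R_M)``, and an OLS
refitting utility for reproducing the printed regressions from table data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metrics import DCCParams, DEFAULT_DCC_PARAMS, DomainError

__all__ = [
    "MineralReference",
    "RegressionFit",
    "potency_empa",
    "potency_dcc",
    "optimal_width",
    "hc50_from_dcc",
    "rat_relative_potency",
    "refit_regression",
]

EMPA_COEFFS = (-0.012, 0.011)
DCC_MODEL_COEFFS = (0.04, 1.15, 2.15)
HC50_COEFFS = (-1.06, 17.12)
RAT_COEFFS = (1.26, 0.48)

#: Biosolubility (years) used for any tremolite population.
TREMOLITE_BIOSOLUBILITY = 49.0


@dataclass(frozen=True)
class MineralReference:
    """Published per-mineral reference values (Hodgson–Darnton R_M in %)."""

    mineral: str
    biosolubility: float  # years
    published_rm: float  # %
    mean_width: float = math.nan  # µm
    mean_sa: float = math.nan  # µm²
    avg_dcc: float = math.nan
    density: float = math.nan  # g/cm³

    def __post_init__(self) -> None:
        if self.biosolubility <= 0:
            raise DomainError("biosolubility must be positive")


@dataclass(frozen=True)
class RegressionFit:
    coefficients: tuple  # (intercept, slope_1, ...)
    r: float
    r_squared: float
    p_value: float
    n: int


def potency_empa(empa_percent: float) -> float:
    """EMPA-linear potency model; EMPA in percent of the main EMP window."""
    e = np.asarray(empa_percent, dtype=float)
    if np.any(e < 0) or np.any(e > 100):
        raise DomainError("EMPA must lie in [0, 100] percent")
    out = np.asarray(EMPA_COEFFS[0] + EMPA_COEFFS[1] * e)
    return out if out.ndim else float(out)


def potency_dcc(avg_dcc: float, biosolubility: float) -> float:
    """DCC + biosolubility potency model, strictly increasing in both."""
    d = np.asarray(avg_dcc, dtype=float)
    b = np.asarray(biosolubility, dtype=float)
    if np.any(d <= 0) or np.any(d >= 1):
        raise DomainError("avg_dcc must lie in (0, 1)")
    if np.any(b <= 0):
        raise DomainError("biosolubility must be positive")
    a0, a1, a2 = DCC_MODEL_COEFFS
    out = np.asarray(10.0 ** (a0 + a1 * np.log10(b) + a2 * np.log10(d)))
    return out if out.ndim else float(out)


def optimal_width(params: DCCParams = DEFAULT_DCC_PARAMS) -> float:
    """Width (µm) maximising ``A*SA**K / (B*W**T + C)`` for compact particles.

    Setting the derivative in W to zero gives
    ``W* = (2KC / (B*(T - 2K)))**(1/T)``; an interior maximum exists only
    for T > 2K.  At the fitted coefficients this is ~0.126 µm, inside the
    0.1–0.2 µm band where width correlates most strongly with mesothelioma
    potency.
    """
    if params.T <= 2 * params.K:
        raise DomainError("no interior maximum: requires T > 2K")
    return float((2 * params.K * params.C / (params.B * (params.T - 2 * params.K))) ** (1 / params.T))


def hc50_from_dcc(avg_dcc: float) -> float:
    """Modelled HC50 (fibres x10^9/ml) from a population's mean DCC."""
    d = np.asarray(avg_dcc, dtype=float)
    if np.any(d < 0) or np.any(d >= 1):
        raise DomainError("avg_dcc must lie in [0, 1)")
    out = np.asarray(10.0 ** (HC50_COEFFS[0] + HC50_COEFFS[1] * d))
    return out if out.ndim else float(out)


def rat_relative_potency(rm_percent: float) -> float:
    """Relative intrapleural potency in rats from the human R_M (%)."""
    r = np.asarray(rm_percent, dtype=float)
    if np.any(r <= 0):
        raise DomainError("R_M must be positive on the log scale")
    out = np.asarray(RAT_COEFFS[0] + RAT_COEFFS[1] * np.log10(r))
    return out if out.ndim else float(out)


def refit_regression(x, y, log10_x=False, log10_y=False) -> RegressionFit:
    """OLS refit with the reporting conventions of the printed regressions.

    ``x`` is one predictor column or a list/2-D array of columns.  R is the
    Pearson correlation for one predictor (signed by the slope) and the
    multiple correlation ``sqrt(R^2)`` otherwise; the p-value is the
    overall-fit F test.
    """
    import statsmodels.api as sm

    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    elif X.shape[0] < X.shape[1] and X.shape[0] <= 2:  # columns passed as rows
        X = X.T
    yv = np.asarray(y, dtype=float)
    if np.ndim(log10_x) == 0:
        log10_x = [bool(log10_x)] * X.shape[1]
    X = np.column_stack(
        [np.log10(col) if lg else col for col, lg in zip(X.T, log10_x)]
    )
    if log10_y:
        yv = np.log10(yv)
    n, p = X.shape
    if n <= p + 1:
        raise DomainError("need n > number of predictors + 1")
    model = sm.OLS(yv, sm.add_constant(X)).fit()
    r2 = float(model.rsquared)
    r = math.sqrt(max(r2, 0.0))
    if p == 1 and model.params[1] < 0:
        r = -r
    return RegressionFit(
        coefficients=tuple(float(c) for c in model.params),
        r=r,
        r_squared=r2,
        p_value=float(model.f_pvalue),
        n=n,
    )


def estimate_potency(
    empa_fraction: float | None = None,
    mean_dcc: float | None = None,
    biosolubility: float = TREMOLITE_BIOSOLUBILITY,
) -> dict:
    """Both potency estimates for one dataset summary, plus their mean.

    ``empa_fraction`` is the summary's EMPA as a fraction (converted to
    percent internally).  Either input may be omitted.
    """
    out: dict[str, float] = {}
    if empa_fraction is not None:
        out["rm_empa"] = potency_empa(100.0 * empa_fraction)
    if mean_dcc is not None and mean_dcc > 0:
        out["rm_dcc"] = potency_dcc(mean_dcc, biosolubility)
    if len(out) == 2:
        out["rm_mean"] = 0.5 * (out["rm_empa"] + out["rm_dcc"])
    return out
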