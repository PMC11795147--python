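"""Population-level filtering and summary metrics for EMP datasets.

Counting rules are expressed as named filter profiles.  The main analysis
window keeps particles longer than 5 µm (strict), 0.05–3 µm wide
(inclusive) and with aspect ratio at least 3; the Pearson-index window
relaxes the length bound to 2 µm; the EMPA numerator additionally requires
width <= 0.15 µm.  ``*_ar5`` variants raise the aspect-ratio bound to 5 for
standards that count only 5:1 particles.

Summary metrics per dataset:

* criteria fraction — share of criteria particles among the main window,
* EMPA — share of particles <= 0.15 µm wide among the main window,
* Pearson index — correlation of (log10 L, log10 W) over the Pearson
  window, near 0 for asbestiform growth (width independent of length) and
  elevated for comminuted fragments, together with the fibrosity-index
  regression log10 W = F log10 L + c,
* mean DCC (arithmetic mean of per-particle DCC), and arithmetic plus
  geometric dimensional summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import DCCParams, DEFAULT_DCC_PARAMS, metrics_frame

__all__ = [
    "FilterProfile",
    "FILTER_PROFILES",
    "DatasetSummary",
    "GroupComparison",
    "apply_filter",
    "pearson_index",
    "PearsonFit",
    "summarize",
    "group_ttest",
]


class ConfigError(KeyError):
    pass


class DegeneratePopulationError(ValueError):
    pass


class SampleSizeError(ValueError):
    pass


@dataclass(frozen=True)
class FilterProfile:
    """A particle counting window.

    ``min_length`` is exclusive ("longer than"); width bounds and the
    aspect-ratio bound are inclusive.
    """

    name: str
    min_length: float
    min_width: float = 0.05
    max_width: float = 3.0
    min_aspect_ratio: float = 3.0
    max_width_numerator: float | None = None  # EMPA numerator cap

    def mask(self, length: np.ndarray, width: np.ndarray) -> np.ndarray:
        m = (
            (length > self.min_length)
            & (width >= self.min_width)
            & (width <= self.max_width)
            & (length / width >= self.min_aspect_ratio)
        )
        if self.max_width_numerator is not None:
            m &= width <= self.max_width_numerator
        return m


FILTER_PROFILES: dict[str, FilterProfile] = {
    "main_emp": FilterProfile("main_emp", min_length=5.0),
    "pearson": FilterProfile("pearson", min_length=2.0),
    "empa_numerator": FilterProfile("empa_numerator", min_length=5.0, max_width_numerator=0.15),
    "main_emp_ar5": FilterProfile("main_emp_ar5", min_length=5.0, min_aspect_ratio=5.0),
    "pearson_ar5": FilterProfile("pearson_ar5", min_length=2.0, min_aspect_ratio=5.0),
}


def _profile(profile) -> FilterProfile:
    if isinstance(profile, FilterProfile):
        return profile
    try:
        return FILTER_PROFILES[profile]
    except KeyError:
        raise ConfigError(f"unknown filter profile {profile!r}") from None


def apply_filter(particles: pd.DataFrame, profile) -> pd.DataFrame:
    """Subset a particle table to a counting window."""
    prof = _profile(profile)
    if len(particles) == 0:
        return particles.copy()
    L = particles["length_um"].to_numpy(float)
    W = particles["width_um"].to_numpy(float)
    if np.any(L <= 0) or np.any(W <= 0):
        raise ValueError("particles must have positive dimensions")
    return particles.loc[prof.mask(L, W)]


@dataclass(frozen=True)
class PearsonFit:
    r: float  # Pearson index: corr(log10 L, log10 W)
    slope: float  # fibrosity index F of log10 W = F log10 L + c
    intercept: float
    n: int


def pearson_index(particles: pd.DataFrame, profile="pearson", prefilter: bool = True) -> PearsonFit:
    """Pearson index of a population: corr(log10 length, log10 width).

    Computed over the Pearson counting window by default.  Raises for
    fewer than three particles or zero variance in either log dimension.
    """
    sub = apply_filter(particles, profile) if prefilter else particles
    if len(sub) < 3:
        raise SampleSizeError(f"need >= 3 particles for the Pearson index, got {len(sub)}")
    x = np.log10(sub["length_um"].to_numpy(float))
    y = np.log10(sub["width_um"].to_numpy(float))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegeneratePopulationError("zero variance in logged length or width")
    slope, intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    return PearsonFit(r=r, slope=float(slope), intercept=float(intercept), n=len(sub))


@dataclass(frozen=True)
class DatasetSummary:
    """Population metrics over the counting windows (µm / µm² scale)."""

    dataset_id: str
    n_particles: int  # main-window count
    criteria_fraction: float
    empa: float
    pearson_index: float
    pearson_slope: float
    mean_dcc: float
    mean_length: float
    sd_length: float
    mean_width: float
    sd_width: float
    mean_ar: float
    sd_ar: float
    mean_ad: float
    sd_ad: float
    mean_sa: float
    sd_sa: float
    gm_length: float
    gsd_length: float
    gm_width: float
    gsd_width: float

    def as_dict(self) -> dict:
        return asdict(self)


def _gm_gsd(x: np.ndarray) -> tuple[float, float]:
    lg = np.log10(x)
    gm = 10.0 ** lg.mean()
    gsd = 10.0 ** lg.std(ddof=1) if len(x) > 1 else math.nan
    return float(gm), float(gsd)


def summarize(
    particles: pd.DataFrame,
    dataset_id: str | None = None,
    params: DCCParams = DEFAULT_DCC_PARAMS,
    variant: str = "ar3",
) -> DatasetSummary:
    """Summary metrics for one dataset.

    ``variant="ar5"`` computes the aspect-ratio-5 analogues (criteria
    fraction and Pearson index over AR >= 5 windows).
    """
    if variant not in ("ar3", "ar5"):
        raise ConfigError(f"unknown variant {variant!r}")
    main_name = "main_emp" if variant == "ar3" else "main_emp_ar5"
    pearson_name = "pearson" if variant == "ar3" else "pearson_ar5"
    if dataset_id is None:
        dataset_id = str(particles["dataset_id"].iloc[0]) if "dataset_id" in particles and len(particles) else ""
    main = apply_filter(particles, main_name)
    if len(main) == 0:
        raise DegeneratePopulationError(f"no particles survive the {main_name} filter")
    m = metrics_frame(main, params)
    L = m["length_um"].to_numpy(float)
    W = m["width_um"].to_numpy(float)
    AR = L / W
    AD = m["aerodynamic_diameter_um"].to_numpy(float)
    SA = m["surface_area_um2"].to_numpy(float)
    gm_l, gsd_l = _gm_gsd(L)
    gm_w, gsd_w = _gm_gsd(W)
    try:
        fit = pearson_index(particles, pearson_name)
    except (SampleSizeError, DegeneratePopulationError):
        # too few particles or no dimensional spread: the correlation is
        # undefined, but the counting metrics still are
        fit = PearsonFit(r=math.nan, slope=math.nan, intercept=math.nan, n=0)
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else math.nan
    return DatasetSummary(
        dataset_id=dataset_id,
        n_particles=len(main),
        criteria_fraction=float(m["is_criteria"].mean()),
        empa=float((W <= 0.15).mean()),
        pearson_index=fit.r,
        pearson_slope=fit.slope,
        mean_dcc=float(m["dcc"].mean()),
        mean_length=float(L.mean()),
        sd_length=sd(L),
        mean_width=float(W.mean()),
        sd_width=sd(W),
        mean_ar=float(AR.mean()),
        sd_ar=sd(AR),
        mean_ad=float(AD.mean()),
        sd_ad=sd(AD),
        mean_sa=float(SA.mean()),
        sd_sa=sd(SA),
        gm_length=gm_l,
        gsd_length=gsd_l,
        gm_width=gm_w,
        gsd_width=gsd_w,
    )


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    degenerate: bool = False


def group_ttest(values_a, values_b) -> GroupComparison:
    """Welch two-sample t test (unequal variances, n-1 denominators).

    Zero pooled variance with differing means yields an infinite statistic
    flagged ``degenerate``; identical constant groups give t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise SampleSizeError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    base = dict(mean_a=float(a.mean()), sd_a=float(np.sqrt(va)),
                mean_b=float(b.mean()), sd_b=float(np.sqrt(vb)))
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return GroupComparison(**base, t_statistic=0.0, p_value=1.0)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return GroupComparison(**base, t_statistic=t, p_value=0.0, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(**base, t_statistic=float(t), p_value=float(p))
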