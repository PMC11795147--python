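"""Habit classification of EMP datasets.

A dataset is summarised by its criteria fraction (CF) and Pearson index
(PI).  The published decision boundary calls a dataset asbestiform iff

    CF >= 0.58 * PI + 0.12,

with two "undetermined" rectangles for possibly-mixed samples (mid-range
Pearson index with a low criteria fraction), and an aspect-ratio-5 variant
``CF* >= 5.8 * PI* - 2.02`` for counting rules that only record 5:1
particles.  A second, distribution-based classifier measures the
Mahalanobis distance between a dataset's (length, width) centroid and
reference asbestiform / non-asbestiform particle clouds under a pooled
covariance.  The published boundary is the default method; refitting the
linear margin (soft-margin SVM, linear kernel, C = 1000) is opt-in.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import DomainError
from .population import apply_filter

__all__ = [
    "Habit",
    "HabitCall",
    "MahalanobisReference",
    "BoundaryFit",
    "classify_boundary",
    "classify_boundary_ar5",
    "mahalanobis_distance",
    "classify_mahalanobis",
    "fit_linear_boundary",
]

BOUNDARY_SLOPE = 0.58
BOUNDARY_INTERCEPT = 0.12
AR5_SLOPE = 5.8
AR5_INTERCEPT = -2.02

#: Undetermined rectangles (PI range, CF range), bounds inclusive.
MIXED_RULES = (
    ((0.3, 0.5), (0.2, 0.3)),
    ((0.4, 0.5), (0.1, 0.2)),
)


class Habit(str, enum.Enum):
    ASBESTIFORM = "asbestiform"
    NON_ASBESTIFORM = "non_asbestiform"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class HabitCall:
    label: Habit
    rule_fired: str
    boundary_margin: float


def _check_cf_pi(criteria_fraction: float, pearson_index: float) -> None:
    if not 0.0 <= criteria_fraction <= 1.0:
        raise DomainError("criteria_fraction must lie in [0, 1]")
    if not -1.0 <= pearson_index <= 1.0:
        raise DomainError("pearson_index must lie in [-1, 1]")


def classify_boundary(
    criteria_fraction: float, pearson_index: float, mixed_rules: bool = True
) -> HabitCall:
    """Classify a dataset's habit from (CF, PI) with the published boundary.

    ``mixed_rules=False`` disables the undetermined rectangles (pure
    two-class boundary).
    """
    _check_cf_pi(criteria_fraction, pearson_index)
    margin = criteria_fraction - (BOUNDARY_SLOPE * pearson_index + BOUNDARY_INTERCEPT)
    if margin >= 0:
        return HabitCall(Habit.ASBESTIFORM, "boundary", margin)
    if mixed_rules:
        for i, ((pi_lo, pi_hi), (cf_lo, cf_hi)) in enumerate(MIXED_RULES, start=1):
            if pi_lo <= pearson_index <= pi_hi and cf_lo <= criteria_fraction <= cf_hi:
                return HabitCall(Habit.UNDETERMINED, f"mixed_rule_{i}", margin)
    return HabitCall(Habit.NON_ASBESTIFORM, "boundary", margin)


def classify_boundary_ar5(criteria_fraction_ar5: float, pearson_index_ar5: float) -> HabitCall:
    """Aspect-ratio-5 variant of the decision boundary (no undetermined zone)."""
    _check_cf_pi(criteria_fraction_ar5, pearson_index_ar5)
    margin = criteria_fraction_ar5 - (AR5_SLOPE * pearson_index_ar5 + AR5_INTERCEPT)
    label = Habit.ASBESTIFORM if margin >= 0 else Habit.NON_ASBESTIFORM
    return HabitCall(label, "boundary_ar5", margin)


@dataclass(frozen=True)
class MahalanobisReference:
    """A reference particle cloud in (length, width) space."""

    centroid: np.ndarray  # (mean length, mean width)
    covariance: np.ndarray  # 2x2, n-1 normalised
    n: int

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be positive-definite")

    @classmethod
    def from_particles(
        cls, particles: pd.DataFrame, log_space: bool = False, prefilter: bool = True
    ) -> "MahalanobisReference":
        sub = apply_filter(particles, "main_emp") if prefilter else particles
        if len(sub) < 3:
            raise ValueError("need >= 3 particles for a Mahalanobis reference")
        X = sub[["length_um", "width_um"]].to_numpy(float)
        if log_space:
            X = np.log10(X)
        return cls(centroid=X.mean(axis=0), covariance=np.cov(X.T, ddof=1), n=len(X))


def _as_reference(sample, log_space: bool, prefilter: bool) -> MahalanobisReference:
    if isinstance(sample, MahalanobisReference):
        return sample
    return MahalanobisReference.from_particles(sample, log_space=log_space, prefilter=prefilter)


def mahalanobis_distance(
    sample,
    reference: MahalanobisReference,
    log_space: bool = False,
    prefilter: bool = True,
) -> float:
    """Mahalanobis distance between a sample's (L, W) centroid and a reference.

    ``D = sqrt((mu_x - mu_y)^T S^-1 (mu_x - mu_y))`` where S is the pooled
    (n-1 weighted) covariance of the two compared groups.  Raw micrometre
    coordinates by default; ``log_space=True`` uses log10 coordinates.
    """
    s = _as_reference(sample, log_space, prefilter)
    S = ((s.n - 1) * s.covariance + (reference.n - 1) * reference.covariance) / (
        s.n + reference.n - 2
    )
    d = s.centroid - reference.centroid
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular pooled covariance: {exc}") from exc
    return float(np.sqrt(d @ sol))


def classify_mahalanobis(
    sample,
    ref_asbestiform: MahalanobisReference,
    ref_non_asbestiform: MahalanobisReference,
    log_space: bool = False,
) -> HabitCall:
    """Habit call by proximity to the nearer reference cloud; ties → undetermined."""
    d_asb = mahalanobis_distance(sample, ref_asbestiform, log_space=log_space)
    d_non = mahalanobis_distance(sample, ref_non_asbestiform, log_space=log_space)
    margin = d_non - d_asb
    if d_asb < d_non:
        return HabitCall(Habit.ASBESTIFORM, "mahalanobis", margin)
    if d_asb > d_non:
        return HabitCall(Habit.NON_ASBESTIFORM, "mahalanobis", margin)
    return HabitCall(Habit.UNDETERMINED, "mahalanobis_tie", margin)


@dataclass(frozen=True)
class BoundaryFit:
    """A refitted linear margin in (PI, CF) space: asbestiform iff CF >= slope*PI + intercept."""

    slope: float
    intercept: float
    n_margin_violations: int
    n_misclassified: int


def fit_linear_boundary(points, labels, penalty: float = 1000.0) -> BoundaryFit:
    """Refit the maximum-margin linear separator from labelled (PI, CF) points.

    ``points`` are (pearson_index, criteria_fraction) pairs and ``labels``
    are truthy for asbestiform.  Soft-margin linear SVM with penalty C.
    """
    from sklearn.svm import SVC

    X = np.asarray(points, dtype=float)
    y = np.asarray([1 if bool(l) else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("need points from both classes to fit a boundary")
    svc = SVC(kernel="linear", C=penalty)
    svc.fit(X, y)
    w_pi, w_cf = svc.coef_[0]
    b = svc.intercept_[0]
    if w_cf <= 0:
        # asbestiform datasets have the higher criteria fraction, so the
        # separator must put them above the line in (PI, CF) space
        raise np.linalg.LinAlgError("degenerate separator orientation in CF")
    # decision function w_pi*PI + w_cf*CF + b >= 0 for asbestiform; rearrange
    # so the asbestiform side is CF >= slope*PI + intercept.
    slope = -w_pi / w_cf
    intercept = -b / w_cf
    df = svc.decision_function(X) * np.where(y == 1, 1, -1)
    return BoundaryFit(
        slope=float(slope),
        intercept=float(intercept),
        n_margin_violations=int(np.sum(df < 1 - 1e-9)),
        n_misclassified=int(np.sum(df < 0)),
    )
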