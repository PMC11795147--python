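"""Per-particle dimensional metrics for elongate mineral particles (EMPs).

An EMP is described by its length L and width W (both in micrometres, as
measured on a 2-D microscope image), its mineral class and its density.
From these the module derives

* thickness ``Th`` (the third dimension, via an empirical per-class rule),
* surface area ``SA`` (rectangular-prism model, or cylinder-with-caps for
  serpentine),
* aerodynamic diameter ``AD`` (Timbrell's formula for fibres),
* the criteria-particle score (a log-linear discriminant in L and W whose
  non-negative values are associated with asbestiform habit), and
* the Dimensional Coefficient of Carcinogenicity (DCC), a [0, 1) score
  ``1 - exp(-A * SA**K / (B * W**T + C))`` that increases with surface area
  and decreases with width.

All functions accept scalars or numpy arrays and operate in micrometres
end-to-end.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MineralClass",
    "Particle",
    "DerivedMetrics",
    "DCCParams",
    "DEFAULT_DCC_PARAMS",
    "MINERAL_CONFIG",
    "thickness",
    "surface_area",
    "aerodynamic_diameter",
    "criteria_score",
    "is_criteria_particle",
    "dcc",
    "derive_metrics",
    "metrics_frame",
]


class DomainError(ValueError):
    """An input lies outside the physical domain of a metric."""


class MineralClass(str, enum.Enum):
    """Structural class of a mineral particle, as used by the thickness rule."""

    SERPENTINE = "serpentine"
    AMPHIBOLE_ASBESTIFORM_OR_MIXED = "amphibole_asbestiform_or_mixed"
    ERIONITE = "erionite"
    BALANGEROITE = "balangeroite"
    FIBROUS_TALC = "fibrous_talc"
    OTHER_NONSERPENTINE = "other_nonserpentine"


@dataclass(frozen=True)
class MineralInfo:
    """Reference data for a mineral species.

    density: g/cm^3, from standard descriptive mineralogy texts (small
    variations affect only the aerodynamic diameter, mildly).
    biosolubility: modelled lifetime of a fibre in biological fluid, years.
    """

    mineral_class: MineralClass
    density: float
    biosolubility: float | None = None


#: Editable mineral configuration keyed by species name.  Non-asbestiform
#: amphiboles deliberately map to OTHER_NONSERPENTINE (the W/1.9 thickness
#: rule); the asbestiform/mixed amphibole rule is reserved for asbestiform
#: habit and Libby-type mixed material.
MINERAL_CONFIG: dict[str, MineralInfo] = {
    "chrysotile": MineralInfo(MineralClass.SERPENTINE, 2.55, 0.3),
    "amosite": MineralInfo(MineralClass.AMPHIBOLE_ASBESTIFORM_OR_MIXED, 3.4, 74.0),
    "grunerite": MineralInfo(MineralClass.OTHER_NONSERPENTINE, 3.4, 74.0),
    "crocidolite": MineralInfo(MineralClass.AMPHIBOLE_ASBESTIFORM_OR_MIXED, 3.4, 66.0),
    "riebeckite": MineralInfo(MineralClass.OTHER_NONSERPENTINE, 3.4, 66.0),
    "tremolite": MineralInfo(MineralClass.AMPHIBOLE_ASBESTIFORM_OR_MIXED, 3.0, 49.0),
    "anthophyllite": MineralInfo(MineralClass.AMPHIBOLE_ASBESTIFORM_OR_MIXED, 3.0, 245.0),
    "libby_amphibole": MineralInfo(MineralClass.AMPHIBOLE_ASBESTIFORM_OR_MIXED, 3.0, 49.0),
    "erionite": MineralInfo(MineralClass.ERIONITE, 2.1, 181.0),
    "balangeroite": MineralInfo(MineralClass.BALANGEROITE, 3.0, None),
    "fibrous_talc": MineralInfo(MineralClass.FIBROUS_TALC, 2.7, None),
}

#: Fallback density when only the structural class is known.
CLASS_DEFAULT_DENSITY: dict[MineralClass, float] = {
    MineralClass.SERPENTINE: 2.55,
    MineralClass.AMPHIBOLE_ASBESTIFORM_OR_MIXED: 3.0,
    MineralClass.ERIONITE: 2.1,
    MineralClass.BALANGEROITE: 3.0,
    MineralClass.FIBROUS_TALC: 2.7,
    MineralClass.OTHER_NONSERPENTINE: 3.0,
}


@dataclass(frozen=True)
class DCCParams:
    """Coefficients (A, K, B, T, C) of the DCC expression.

    The default instance holds the fitted values; B is a scale convention
    (any value can be absorbed into A and C).
    """

    A: float = 0.11
    K: float = 1.0
    B: float = 1000.0
    T: float = 3.0
    C: float = 1.0

    def __post_init__(self) -> None:
        for name in ("A", "K", "B", "T", "C"):
            if getattr(self, name) <= 0:
                raise DomainError(f"DCC coefficient {name} must be > 0")


DEFAULT_DCC_PARAMS = DCCParams()


@dataclass(frozen=True)
class Particle:
    """One elongate mineral particle."""

    length: float  # µm
    width: float  # µm
    mineral_class: MineralClass = MineralClass.OTHER_NONSERPENTINE
    density: float = field(default=float("nan"))  # g/cm^3

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise DomainError("particle dimensions must be positive")
        if math.isnan(self.density):
            object.__setattr__(
                self, "density", CLASS_DEFAULT_DENSITY[MineralClass(self.mineral_class)]
            )
        if self.density <= 0:
            raise DomainError("particle density must be positive")

    @property
    def aspect_ratio(self) -> float:
        return self.length / self.width


@dataclass(frozen=True)
class DerivedMetrics:
    """Per-particle derived quantities (thickness in µm, SA in µm², AD in µm)."""

    thickness: float
    surface_area: float
    aerodynamic_diameter: float
    criteria_score: float
    dcc: float


def _check_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise DomainError(f"{name} must be positive and finite")
    return arr


# Empirical thickness rules: the third dimension of a particle inferred from
# its width.  Asbestiform/mixed amphibole fibres are markedly thinner than
# wide (power-law rule); non-asbestiform fragments are blockier (W/1.9);
# erionite crystals are square in cross-section (Th = W).
_THICKNESS_DIVISORS = {
    MineralClass.ERIONITE: 1.0,
    MineralClass.BALANGEROITE: 1.1,
    MineralClass.FIBROUS_TALC: 3.0,
    MineralClass.OTHER_NONSERPENTINE: 1.9,
}


def thickness(width, mineral_class: MineralClass):
    """Particle thickness (µm) from width, by mineral-class rule.

    Serpentine has no thickness rule: its surface area model is a cylinder
    and does not use one.
    """
    cls = MineralClass(mineral_class)
    if cls is MineralClass.SERPENTINE:
        raise DomainError("thickness undefined for serpentine")
    w = _check_positive("width", width)
    if cls is MineralClass.AMPHIBOLE_ASBESTIFORM_OR_MIXED:
        out = 10.0 ** (0.692 * np.log10(w) - 0.493)
    else:
        out = w / _THICKNESS_DIVISORS[cls]
    return out if out.ndim else float(out)


def surface_area(particle_or_length, width=None, mineral_class=None, *, thickness_override=None):
    """Particle surface area in µm².

    Non-serpentine particles are modelled as rectangular prisms,
    ``SA = 2LW + 2L*Th + 2W*Th``; serpentine fibrils as cylinders with end
    caps, ``SA = 0.5*pi*W**2 + pi*W*L``.

    Accepts either a :class:`Particle` or ``(length, width, mineral_class)``
    arrays.  ``thickness_override`` substitutes a fixed thickness (testing
    hook and sensitivity analyses).
    """
    if isinstance(particle_or_length, Particle):
        p = particle_or_length
        length, width, mineral_class = p.length, p.width, p.mineral_class
    else:
        length = particle_or_length
        if width is None or mineral_class is None:
            raise TypeError("surface_area needs (length, width, mineral_class)")
    cls = MineralClass(mineral_class)
    L = _check_positive("length", length)
    W = _check_positive("width", width)
    if cls is MineralClass.SERPENTINE:
        out = 0.5 * np.pi * W**2 + np.pi * W * L
    else:
        th = thickness(W, cls) if thickness_override is None else np.asarray(
            thickness_override, dtype=float
        )
        out = 2 * L * W + 2 * L * th + 2 * W * th
    out = np.asarray(out)
    return out if out.ndim else float(out)


def aerodynamic_diameter(particle_or_width, aspect_ratio=None, density=None, rho0: float = 1.0):
    """Timbrell aerodynamic diameter of a fibre, µm.

    ``AD = 66 * W * (AR / (2 + 4*AR))**2.2 * (rho / rho0)**0.5`` — the
    diameter of the unit-density sphere with the same settling velocity.
    Strictly increasing in W at fixed AR; bounded by the AR → ∞ limit
    ``66 * W * 0.25**2.2 * sqrt(rho)``.
    """
    if isinstance(particle_or_width, Particle):
        p = particle_or_width
        width, aspect_ratio, density = p.width, p.aspect_ratio, p.density
    else:
        width = particle_or_width
        if aspect_ratio is None or density is None:
            raise TypeError("aerodynamic_diameter needs (width, aspect_ratio, density)")
    W = _check_positive("width", width)
    AR = _check_positive("aspect_ratio", aspect_ratio)
    rho = _check_positive("density", density)
    if rho0 <= 0:
        raise DomainError("reference density must be positive")
    out = 66.0 * W * (AR / (2.0 + 4.0 * AR)) ** 2.2 * np.sqrt(rho / rho0)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def criteria_score(length, width):
    """Criteria-particle discriminant ``2.99*log10(L) - 5.82*log10(W) - 3.80``.

    A particle is a *criteria particle* (dimensions associated with
    asbestiform habit) iff the score is >= 0; the boundary is inclusive.
    """
    L = _check_positive("length", length)
    W = _check_positive("width", width)
    out = 2.99 * np.log10(L) - 5.82 * np.log10(W) - 3.80
    out = np.asarray(out)
    return out if out.ndim else float(out)


def is_criteria_particle(length, width):
    """Boolean criteria-particle test (score >= 0, boundary inclusive)."""
    return np.asarray(criteria_score(length, width)) >= 0


def dcc(surface_area, width, params: DCCParams = DEFAULT_DCC_PARAMS):
    """Dimensional Coefficient of Carcinogenicity, in [0, 1).

    ``DCC = 1 - exp(-A * SA**K / (B * W**T + C))``.  Monotone increasing in
    surface area; tends to 0 as width grows at fixed surface area.  With
    C > 0 it also vanishes for vanishingly small particles, reflecting
    clearance of the smallest material from the lung.
    """
    sa = np.asarray(surface_area, dtype=float)
    if np.any(sa < 0) or np.any(~np.isfinite(sa)):
        raise DomainError("surface_area must be non-negative and finite")
    W = _check_positive("width", width)
    out = 1.0 - np.exp(-params.A * sa**params.K / (params.B * W**params.T + params.C))
    # the score is strictly below 1 analytically; keep it so at float resolution
    out = np.minimum(np.asarray(out), np.nextafter(1.0, 0.0))
    return out if out.ndim else float(out)


def derive_metrics(particle: Particle, params: DCCParams = DEFAULT_DCC_PARAMS) -> DerivedMetrics:
    """All derived metrics for a single particle."""
    cls = MineralClass(particle.mineral_class)
    sa = surface_area(particle)
    th = float("nan") if cls is MineralClass.SERPENTINE else thickness(particle.width, cls)
    return DerivedMetrics(
        thickness=th,
        surface_area=sa,
        aerodynamic_diameter=aerodynamic_diameter(particle),
        criteria_score=criteria_score(particle.length, particle.width),
        dcc=dcc(sa, particle.width, params),
    )


def metrics_frame(df, params: DCCParams = DEFAULT_DCC_PARAMS):
    """Vectorised derived metrics for a particle table.

    ``df`` needs columns ``length_um``, ``width_um`` and optionally
    ``mineral_class`` (default other_nonserpentine) and ``density`` (default
    from the class).  Returns a copy with columns ``thickness_um``,
    ``surface_area_um2``, ``aerodynamic_diameter_um``, ``criteria_score``,
    ``is_criteria`` and ``dcc`` appended.
    """
    import pandas as pd

    out = df.copy()
    if "mineral_class" not in out:
        out["mineral_class"] = MineralClass.OTHER_NONSERPENTINE.value
    classes = out["mineral_class"].map(lambda c: MineralClass(c))
    if "density" not in out:
        out["density"] = classes.map(CLASS_DEFAULT_DENSITY.get)
    L = out["length_um"].to_numpy(float)
    W = out["width_um"].to_numpy(float)
    rho = out["density"].to_numpy(float)
    th = np.full(len(out), np.nan)
    sa = np.empty(len(out))
    for cls in classes.unique():
        m = (classes == cls).to_numpy()
        if cls is MineralClass.SERPENTINE:
            sa[m] = 0.5 * np.pi * W[m] ** 2 + np.pi * W[m] * L[m]
        else:
            th[m] = thickness(W[m], cls)
            sa[m] = 2 * L[m] * W[m] + 2 * (L[m] + W[m]) * th[m]
    out["thickness_um"] = th
    out["surface_area_um2"] = sa
    out["aerodynamic_diameter_um"] = aerodynamic_diameter(W, L / W, rho)
    score = criteria_score(L, W)
    out["criteria_score"] = score
    out["is_criteria"] = np.asarray(score) >= 0
    out["dcc"] = dcc(sa, W, params)
    return pd.DataFrame(out)
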