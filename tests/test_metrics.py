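"""Per-particle metric oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from empdcc.metrics import (
    DCCParams,
    DomainError,
    MineralClass,
    Particle,
    aerodynamic_diameter,
    criteria_score,
    dcc,
    derive_metrics,
    is_criteria_particle,
    metrics_frame,
    surface_area,
    thickness,
)

AMPH = MineralClass.AMPHIBOLE_ASBESTIFORM_OR_MIXED


class TestThickness:
    @pytest.mark.parametrize(
        "width, cls, expected",
        [
            (1.0, AMPH, 10 ** (-0.493)),  # log10(W)=0 isolates the intercept
            (1.9, MineralClass.OTHER_NONSERPENTINE, 1.0),
            (0.5, MineralClass.ERIONITE, 0.5),
            (1.1, MineralClass.BALANGEROITE, 1.0),
            (3.0, MineralClass.FIBROUS_TALC, 1.0),
            (0.35, AMPH, 0.1554157707998803),
        ],
    )
    def test_class_rules(self, width, cls, expected):
        assert thickness(width, cls) == pytest.approx(expected, rel=1e-12)

    def test_serpentine_has_no_thickness(self):
        with pytest.raises(DomainError, match="serpentine"):
            thickness(1.0, MineralClass.SERPENTINE)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(DomainError):
            thickness(0.0, AMPH)

    def test_amphibole_rule_thinner_than_wide_over_observed_range(self):
        # the power law crosses Th = W at 10**(-0.493/0.308) ~ 0.025 um,
        # well below any observed fibre width
        w = np.linspace(0.05, 3.0, 500)
        assert np.all(thickness(w, AMPH) < w)
        crossover = 10 ** (-0.493 / (1 - 0.692))
        assert crossover == pytest.approx(0.0251, abs=2e-4)
        assert thickness(crossover * 0.5, AMPH) > crossover * 0.5


class TestSurfaceArea:
    def test_prism_model_with_forced_thickness(self):
        # 2LW + 2L*Th + 2W*Th with L=10, W=1, Th=0.5 -> 20 + 10 + 1
        sa = surface_area(10.0, 1.0, MineralClass.OTHER_NONSERPENTINE, thickness_override=0.5)
        assert sa == pytest.approx(31.0)

    def test_serpentine_cylinder_model(self):
        assert surface_area(10.0, 1.0, MineralClass.SERPENTINE) == pytest.approx(10.5 * math.pi)

    def test_amphibole_with_derived_thickness(self):
        assert surface_area(11.4, 0.35, AMPH) == pytest.approx(11.6323, abs=1e-3)

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(DomainError):
            surface_area(-1.0, 1.0, AMPH)


class TestAerodynamicDiameter:
    def test_timbrell_formula(self):
        assert aerodynamic_diameter(1.0, 3.0, 1.0) == pytest.approx(66 * (3 / 14) ** 2.2, rel=1e-9)

    def test_bounded_by_infinite_aspect_ratio_limit(self):
        sup = 66 * 0.25**2.2
        assert sup == pytest.approx(3.1262, abs=1e-3)
        for ar in (1, 3, 10, 100, 1e6):
            assert aerodynamic_diameter(1.0, ar, 1.0) < sup

    def test_density_scaling_and_domain(self):
        assert aerodynamic_diameter(1.0, 3.0, 4.0) == pytest.approx(
            2 * aerodynamic_diameter(1.0, 3.0, 1.0)
        )
        with pytest.raises(DomainError):
            aerodynamic_diameter(1.0, 3.0, 0.0)

    def test_increasing_in_width_at_fixed_ar(self):
        w = np.linspace(0.05, 3, 100)
        ad = aerodynamic_diameter(w, 10.0, 3.0)
        assert np.all(np.diff(ad) > 0)


class TestCriteriaScore:
    @pytest.mark.parametrize(
        "length, width, expected, criteria",
        [
            (10.0, 0.25, 2.6940, True),
            (10.0, 1.0, -0.81, False),
            (10.0, 0.7258129995, 0.0, True),  # boundary is inclusive
        ],
    )
    def test_examples(self, length, width, expected, criteria):
        assert criteria_score(length, width) == pytest.approx(expected, abs=1e-3)
        assert bool(is_criteria_particle(length, width)) is criteria

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(min_value=0.1, max_value=200), st.floats(min_value=0.01, max_value=5)
    )
    def test_sign_matches_bruteforce(self, length, width):
        brute = 2.99 * math.log10(length) - 5.82 * math.log10(width) - 3.80
        assert (criteria_score(length, width) >= 0) == (brute >= 0)


class TestDCC:
    def test_zero_surface_area_gives_zero(self):
        assert dcc(0.0, 0.3) == 0.0

    def test_mean_input_value(self):
        assert dcc(13.47, 0.31) == pytest.approx(0.046982, abs=1e-5)

    def test_vanishes_for_wide_particles(self):
        assert dcc(13.47, 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(DomainError):
            dcc(1.0, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=0.0, max_value=500.0),
        st.floats(min_value=0.01, max_value=5.0),
    )
    def test_bounded_in_unit_interval(self, sa, width):
        val = dcc(sa, width)
        assert 0.0 <= val < 1.0

    def test_monotone_in_surface_area(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = rng.uniform(0.05, 3)
            sa = np.sort(rng.uniform(0, 100, 20))
            assert np.all(np.diff(dcc(sa, w)) >= 0)


class TestParticleApi:
    def test_density_defaults_by_class(self):
        p = Particle(10.0, 0.3, MineralClass.SERPENTINE)
        assert p.density == pytest.approx(2.55)
        assert p.aspect_ratio == pytest.approx(10 / 0.3)

    def test_invalid_particle_rejected(self):
        with pytest.raises(DomainError):
            Particle(0.0, 0.3)

    def test_derive_metrics_consistent_with_frame(self):
        import pandas as pd

        p = Particle(11.4, 0.35, AMPH, 3.0)
        d = derive_metrics(p)
        frame = metrics_frame(
            pd.DataFrame(
                {"length_um": [11.4], "width_um": [0.35],
                 "mineral_class": [AMPH.value], "density": [3.0]}
            )
        )
        assert d.surface_area == pytest.approx(frame["surface_area_um2"].iloc[0])
        assert d.dcc == pytest.approx(frame["dcc"].iloc[0])
        assert d.aerodynamic_diameter == pytest.approx(
            frame["aerodynamic_diameter_um"].iloc[0]
        )

    def test_default_dcc_params(self):
        p = DCCParams()
        assert (p.A, p.K, p.B, p.T, p.C) == (0.11, 1.0, 1000.0, 3.0, 1.0)
        with pytest.raises(DomainError):
            DCCParams(A=-0.1)
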