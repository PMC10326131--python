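import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from skinaniso.ellipse import (
    DegenerateFitError,
    InsufficientDataError,
    analyze_profile,
    anisotropic_ratio,
    fit_ellipse_direct,
    metrics_from_fit,
    polar_to_cartesian,
)
from .conftest import make_elliptical_profile


def ellipse_points(a, b, tilt_deg=0.0, cx=0.0, cy=0.0, n=36):
    """Oracle: points from the parametric ellipse equation."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    phi = np.deg2rad(tilt_deg)
    x = a * np.cos(t) * np.cos(phi) - b * np.sin(t) * np.sin(phi) + cx
    y = a * np.cos(t) * np.sin(phi) + b * np.sin(t) * np.cos(phi) + cy
    return np.column_stack((x, y))


class TestPolarToCartesian:
    @pytest.mark.parametrize(
        "angle, r, expected",
        [(0.0, 160.0, (160.0, 0.0)), (90.0, 200.0, (0.0, 200.0)), (180.0, 137.0, (-137.0, 0.0))],
    )
    def test_cardinal_directions(self, angle, r, expected):
        from skinaniso.angular_io import AngularProfile, Configuration

        prof = AngularProfile("s", Configuration.NATURAL, np.array([angle]), np.array([r]))
        np.testing.assert_allclose(polar_to_cartesian(prof)[0], expected, atol=1e-12)

    def test_radius_preserved(self, e07_profile):
        pts = polar_to_cartesian(e07_profile)
        np.testing.assert_allclose(np.hypot(pts[:, 0], pts[:, 1]), e07_profile.rrt)


class TestDirectFit:
    def test_circle_recovered(self):
        fit = fit_ellipse_direct(ellipse_points(160.0, 160.0))
        assert fit.semi_major == pytest.approx(160.0, abs=1e-6)
        assert fit.semi_minor == pytest.approx(160.0, abs=1e-6)
        np.testing.assert_allclose(fit.center, (0.0, 0.0), atol=1e-6)

    @pytest.mark.parametrize(
        "a, b, tilt, cx, cy",
        [
            (224.044, 160.0, 30.0, 0.0, 0.0),
            (367.065, 160.0, 117.0, 0.0, 0.0),
            (200.0, 180.0, 0.0, 50.0, -30.0),   # axis-aligned, offset center
            (300.0, 100.0, 90.0, 0.0, 0.0),      # vertical major axis
            (184.75, 160.0, 179.5, 10.0, 10.0),  # tilt near the axial wrap
        ],
    )
    def test_parametric_oracle_recovery(self, a, b, tilt, cx, cy):
        fit = fit_ellipse_direct(ellipse_points(a, b, tilt, cx, cy))
        assert fit.semi_major == pytest.approx(a, rel=1e-6)
        assert fit.semi_minor == pytest.approx(b, rel=1e-6)
        assert fit.center[0] == pytest.approx(cx, abs=1e-6)
        assert fit.center[1] == pytest.approx(cy, abs=1e-6)
        d = abs(fit.tilt_deg - (tilt % 180.0))
        assert min(d, 180.0 - d) < 1e-6

    @given(
        b=st.floats(50.0, 400.0),
        ratio=st.floats(1.0, 10.0),
        tilt=st.floats(0.0, 180.0, exclude_max=True),
    )
    def test_exactness_property(self, b, ratio, tilt):
        """Noiseless 36-point profiles are recovered within 1e-6 relative error."""
        a = b * ratio
        fit = fit_ellipse_direct(ellipse_points(a, b, tilt))
        assert fit.semi_major == pytest.approx(a, rel=1e-6)
        assert fit.semi_minor == pytest.approx(b, rel=1e-6)

    def test_rotation_equivariance(self):
        pts = ellipse_points(224.044, 160.0, 20.0)
        base = fit_ellipse_direct(pts)
        for phi in (33.0, 90.0, 145.0):
            c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
            rot = pts @ np.array([[c, s], [-s, c]])
            f = fit_ellipse_direct(rot)
            assert f.semi_major == pytest.approx(base.semi_major, abs=1e-8 * base.semi_major + 1e-8)
            assert f.semi_minor == pytest.approx(base.semi_minor, abs=1e-8 * base.semi_minor + 1e-8)
            d = abs(f.tilt_deg - (base.tilt_deg + phi) % 180.0)
            assert min(d, 180.0 - d) < 1e-7

    def test_scale_equivariance(self):
        pts = ellipse_points(224.044, 160.0, 20.0)
        base = fit_ellipse_direct(pts)
        k = 3.7
        f = fit_ellipse_direct(k * pts)
        m_base = metrics_from_fit(base)
        m = metrics_from_fit(f)
        assert f.semi_major == pytest.approx(k * base.semi_major, rel=1e-9)
        assert f.semi_minor == pytest.approx(k * base.semi_minor, rel=1e-9)
        assert m.area == pytest.approx(k**2 * m_base.area, rel=1e-9)
        assert m.eccentricity == pytest.approx(m_base.eccentricity, abs=1e-9)

    def test_deterministic(self, rng):
        pts = ellipse_points(224.044, 160.0, 30.0) + rng.normal(0, 5, (36, 2))
        f1, f2 = fit_ellipse_direct(pts), fit_ellipse_direct(pts)
        assert f1.semi_major == f2.semi_major and f1.tilt_deg == f2.tilt_deg

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_ellipse_direct(ellipse_points(200.0, 100.0)[:5])

    def test_collinear_points_degenerate(self):
        x = np.linspace(0, 100, 36)
        with pytest.raises(DegenerateFitError):
            fit_ellipse_direct(np.column_stack((x, 2 * x + 1)))


class TestMetrics:
    def test_unit_circle(self):
        fit = fit_ellipse_direct(ellipse_points(1.0, 1.0))
        m = metrics_from_fit(fit)
        assert m.eccentricity == pytest.approx(0.0, abs=1e-7)
        assert m.area == pytest.approx(np.pi, rel=1e-7)

    @pytest.mark.parametrize(
        "a, b, e_expected",
        [(224.044, 160.0, 0.7), (367.065, 160.0, 0.9)],
    )
    def test_study_eccentricities(self, a, b, e_expected):
        fit = fit_ellipse_direct(ellipse_points(a, b))
        m = metrics_from_fit(fit)
        assert m.eccentricity == pytest.approx(e_expected, abs=1e-5)

    def test_area_closed_form(self):
        fit = fit_ellipse_direct(ellipse_points(367.065, 160.0))
        m = metrics_from_fit(fit)
        assert m.area == pytest.approx(np.pi * 367.065 * 160.0, rel=1e-7)

    def test_langer_angle_perpendicular_to_tilt(self):
        fit = fit_ellipse_direct(ellipse_points(224.044, 160.0, 30.0))
        m = metrics_from_fit(fit)
        assert m.langer_angle_deg == pytest.approx(120.0, abs=1e-6)


class TestAnisotropicRatio:
    def test_constant_profile_is_one(self, circle_profile):
        assert anisotropic_ratio(circle_profile) == pytest.approx(1.0)

    def test_e07_reference_value(self, e07_profile):
        # noiseless ellipse with semi-axes 224.044 / 160: AR = 1.4 to 3 s.f.
        assert round(anisotropic_ratio(e07_profile), 1) == 1.4

    def test_e09_closed_form(self):
        prof = make_elliptical_profile(367.065, 160.0)
        assert anisotropic_ratio(prof) == pytest.approx(1 / np.sqrt(1 - 0.81), abs=0.005)

    @given(
        e=st.floats(0.0, 0.95),
        tilt_step=st.integers(0, 17),
    )
    def test_exact_identity_when_axes_on_grid(self, e, tilt_step):
        """With the ellipse axes aligned to the 10° grid the extremes are
        sampled exactly, so AR = a/b = 1/sqrt(1-e^2) to machine precision."""
        b = 160.0
        a = b / np.sqrt(1 - e * e)
        prof = make_elliptical_profile(a, b, tilt_deg=10.0 * tilt_step)
        assert anisotropic_ratio(prof) == pytest.approx(a / b, rel=1e-12)

    @given(
        e=st.floats(0.0, 0.65),
        tilt=st.floats(0.0, 180.0, exclude_max=True),
    )
    def test_oracle_identity_within_grid_tolerance(self, e, tilt):
        """The 10° grid can miss the exact extremes by at most 5°; for
        e <= 0.65 that bounds AR below a/b by under 0.5% at any tilt
        (at higher eccentricity the worst-case discretization error
        exceeds the bound, so exactness is asserted on-grid above)."""
        b = 160.0
        a = b / np.sqrt(1 - e * e)
        prof = make_elliptical_profile(a, b, tilt_deg=tilt)
        ar = anisotropic_ratio(prof)
        assert ar <= a / b * (1 + 1e-12)  # grid can only miss the extremes
        assert ar == pytest.approx(a / b, rel=0.005)


def test_analyze_profile_combines_fit_and_metrics(e07_profile):
    fit, m = analyze_profile(e07_profile)
    assert m.eccentricity == pytest.approx(0.7, abs=1e-5)
    assert m.anisotropic_ratio == pytest.approx(1.4, abs=0.005)
    assert fit.rms_residual < 1e-8
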