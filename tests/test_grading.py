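"""Posterior refractive power maps and the 0-5 color grade."""

import numpy as np
import pytest
from dataclasses import replace

from ektopo import grading
from ektopo.grading import BandConfig, GradeResult, PRPMap
from ektopo.synthetic import dmek_dehydration, dsaek_meniscus, make_conicoid
from ektopo.synthetic import _hoa_direction, _perturbation


def random_prp_map(rng, bump=True):
    """Cornea-like randomized posterior map: conicoid + perturbation + bump."""
    post = make_conicoid(rng.uniform(5.9, 6.6), rng.uniform(-0.8, 0.1))
    amp = rng.uniform(0.0, 0.25)
    if amp > 0:
        pert = _perturbation(_hoa_direction(rng), amp, -0.040, post.grid_spacing, post.half_width)
        post = replace(post, sag=post.sag + pert)
    if bump:
        kind = rng.integers(0, 3)
        if kind == 1:
            post = dmek_dehydration(post, rng.uniform(0, 40))
        elif kind == 2:
            post = dsaek_meniscus(post, rng.uniform(0, 120))
    return grading.prp_map(post)


def offset_map(m, off):
    return PRPMap(prp=m.prp + off, grid_spacing=m.grid_spacing, half_width=m.half_width,
                  zone_diameter=m.zone_diameter, valid_mask=m.valid_mask)


class TestAxialRadius:
    def test_sphere_radius_constant(self):
        ra = grading.axial_radius_map(make_conicoid(6.5, 0.0))
        rr = make_conicoid(6.5, 0.0).radius()
        zone = (rr <= 3.0) & np.isfinite(ra)
        assert np.abs(ra[zone] - 6.5).max() < 1e-3

    def test_conicoid_matches_closed_form(self):
        # axial radius of a conicoid: R_a = sqrt(R^2 - Q r^2); fine grid so
        # the finite-difference slope error (O(h^2)) sits below the bound
        R, Q = 6.5, -0.3
        m = make_conicoid(R, Q, grid_spacing=0.02)
        ra = grading.axial_radius_map(m)
        c = m.n // 2
        i = c + int(round(2.0 / m.grid_spacing))  # on-axis point at r = 2 mm
        assert ra[c, i] == pytest.approx(np.sqrt(R**2 - Q * 4.0), abs=1e-4)

    def test_rotated_surface_gives_rotated_map(self, rng):
        post = make_conicoid(6.4, -0.3)
        pert = _perturbation(_hoa_direction(rng), 0.15, -0.040, post.grid_spacing, post.half_width)
        post = replace(post, sag=post.sag + pert)
        rot = replace(post, sag=np.rot90(post.sag).copy())
        ra, ra_rot = grading.axial_radius_map(post), grading.axial_radius_map(rot)
        zone = make_conicoid(6.4, -0.3).radius() <= 3.0
        a, b = np.rot90(ra), ra_rot
        ok = zone & np.isfinite(a) & np.isfinite(b)
        assert np.abs(a[ok] - b[ok]).max() < 1e-9

    def test_flat_surface_masked_invalid(self):
        n = 141
        flat = replace(make_conicoid(6.5, 0.0), sag=np.zeros((n, n)))
        ra = grading.axial_radius_map(flat)
        assert not np.isfinite(ra).any()

    def test_vertex_limit_equals_apical_radius(self):
        ra = grading.axial_radius_map(make_conicoid(6.2, -0.4))
        c = ra.shape[0] // 2
        assert ra[c, c] == pytest.approx(6.2, abs=2e-3)


class TestPrpMap:
    @pytest.mark.parametrize("R,expected", [(6.349, -6.30), (5.797, -6.90)])
    def test_sphere_power_at_band_thresholds(self, R, expected):
        m = grading.prp_map(make_conicoid(R, 0.0))
        zone = m.zone_mask() & m.valid_mask
        assert np.allclose(m.prp[zone], expected, atol=5e-3)

    def test_flatter_radius_less_negative_power(self):
        flat = grading.prp_map(make_conicoid(7.0, 0.0))
        steep = grading.prp_map(make_conicoid(6.0, 0.0))
        zone = flat.zone_mask() & flat.valid_mask & steep.valid_mask
        assert np.all(flat.prp[zone] > steep.prp[zone])


class TestBands:
    @pytest.mark.parametrize(
        "value,band",
        [(-6.0, "cool"), (-6.6, "orange"), (-7.5, "red"),
         (-6.3, "yellow"), (-6.45, "yellow"), (-6.15, "yellow"),
         (-6.9, "orange"), (-6.14, "cool"), (-6.91, "red")],
    )
    def test_classification(self, value, band):
        assert grading.classify_band(value) == band

    def test_non_finite_value_rejected(self):
        with pytest.raises(ValueError):
            grading.classify_band(float("nan"))

    def test_band_fractions_sum_to_one(self, rng):
        for _ in range(10):
            fr = grading.band_fractions(random_prp_map(rng))
            assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_band_config_validation(self):
        with pytest.raises(ValueError):
            BandConfig(yellow_width=0.0)
        with pytest.raises(ValueError):
            BandConfig(red_threshold=-6.0)


def disc_map(inner_value, outer_value, disc_radius):
    m = PRPMap.uniform(outer_value)
    ax = np.linspace(-m.half_width, m.half_width, m.n)
    xx, yy = np.meshgrid(ax, ax)
    m.prp[np.hypot(xx, yy) <= disc_radius] = inner_value
    return m


class TestRedFractionAndBackground:
    def test_uniform_red_map(self):
        assert grading.red_fraction(PRPMap.uniform(-7.5)) == 1.0

    def test_uniform_cool_map(self):
        assert grading.red_fraction(PRPMap.uniform(-6.0)) == 0.0

    def test_central_red_disc_quarter_area(self):
        m = disc_map(-7.5, -6.6, 1.5)  # red disc r=1.5 in the 6-mm zone
        assert grading.red_fraction(m) == pytest.approx(0.25, abs=0.01)

    def test_background_examples(self):
        assert grading.background_band(PRPMap.uniform(-6.6)) == "orange"
        assert grading.background_band(PRPMap.uniform(-7.5)) == "red"
        # 60% orange / 40% red: red below the 0.75 dominance threshold
        m = disc_map(-7.5, -6.6, 3.0 * np.sqrt(0.4))
        assert grading.background_band(m) == "orange"

    def test_mostly_invalid_zone_rejected(self):
        m = PRPMap.uniform(-6.6)
        m.valid_mask = np.zeros_like(m.valid_mask)
        with pytest.raises(ValueError):
            grading.red_fraction(m)


class TestGrade:
    @pytest.mark.parametrize(
        "value,expected", [(-6.0, 0), (-7.5, 5), (-6.3, 1), (-6.6, 2)]
    )
    def test_uniform_maps(self, value, expected):
        assert grading.grade(PRPMap.uniform(value)).grade == expected

    def test_orange_background_red_tiers(self):
        for frac, expected in ((0.10, 2), (0.35, 3), (0.60, 4), (0.80, 5)):
            m = disc_map(-7.5, -6.6, 3.0 * np.sqrt(frac))
            assert grading.grade(m).grade == expected

    def test_boundary_fractions_take_higher_grade(self):
        m = PRPMap.uniform(-6.6)
        idx = np.argwhere(m.zone_mask())
        quarter = idx[: int(np.ceil(0.25 * len(idx)))]
        m.prp[tuple(quarter.T)] = -7.5  # red fraction exactly >= 1/4
        assert grading.grade(m).grade == 3

    def test_grade_result_consistency(self, rng):
        for _ in range(10):
            res = grading.grade(random_prp_map(rng))
            assert 0 <= res.grade <= 5
            assert sum(res.band_fractions.values()) == pytest.approx(1.0)
            assert (res.background_band == "red") == (res.grade == 5)

    def test_monotone_under_uniform_steepening(self, rng):
        for _ in range(300):
            m = random_prp_map(rng)
            prev = grading.grade(m).grade
            for off in (-0.2, -0.5, -1.0, -1.8):
                g = grading.grade(offset_map(m, off)).grade
                assert g >= prev
                prev = g

    def test_rotation_invariance(self, rng):
        for _ in range(5):
            m = random_prp_map(rng)
            rot = PRPMap(prp=np.rot90(m.prp).copy(), grid_spacing=m.grid_spacing,
                         half_width=m.half_width, zone_diameter=m.zone_diameter,
                         valid_mask=np.rot90(m.valid_mask).copy())
            r1, r2 = grading.grade(m), grading.grade(rot)
            assert r1.grade == r2.grade
            assert r1.red_fraction == pytest.approx(r2.red_fraction, abs=1e-12)

    def test_vanishing_yellow_band_collapses_grades(self, rng):
        cfg = BandConfig(yellow_width=1e-9)
        for _ in range(20):
            res = grading.grade(random_prp_map(rng), cfg)
            assert res.band_fractions["yellow"] < 1e-3
            assert res.grade in {0, 2, 3, 4, 5}

    def test_grade_result_validation(self):
        with pytest.raises(ValueError):
            GradeResult(grade=6, background_band="red", red_fraction=1.0)
        with pytest.raises(ValueError):
            GradeResult(grade=2, background_band="orange", red_fraction=1.5)
        with pytest.raises(ValueError):
            GradeResult(grade=2, background_band="orange", red_fraction=0.1,
                        band_fractions={"cool": 0.5, "yellow": 0.2, "orange": 0.2, "red": 0.2})
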