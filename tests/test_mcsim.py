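"""Photon transport: sampling primitives, boundary optics, full runs."""

import numpy as np
import pytest

import tetmc
from tetmc.mcsim import (fresnel_boundary, fresnel_reflectance,
                         quaternion_to_direction, sample_free_path, sample_hg)


def _quat_rotation_matrix(q):
    """Independent oracle: rotation matrix of a unit quaternion."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestQuaternionToDirection:
    def test_identity_gives_reference_direction(self):
        np.testing.assert_allclose(quaternion_to_direction((1, 0, 0, 0)),
                                   (0, 0, -1), atol=1e-15)

    def test_half_turn_about_x(self):
        np.testing.assert_allclose(quaternion_to_direction((0, 1, 0, 0)),
                                   (0, 0, 1), atol=1e-15)

    def test_150_degrees_about_x(self):
        half = np.deg2rad(150) / 2
        q = (np.cos(half), np.sin(half), 0, 0)
        np.testing.assert_allclose(
            quaternion_to_direction(q),
            (0, 0.5, -np.cos(np.deg2rad(150))), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_rotation_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        expected = _quat_rotation_matrix(q) @ np.array([0.0, 0.0, -1.0])
        np.testing.assert_allclose(quaternion_to_direction(q), expected,
                                   atol=1e-12)

    def test_zero_quaternion_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            quaternion_to_direction((0, 0, 0, 0))


class TestFreePath:
    def test_closed_form(self):
        assert sample_free_path(1.0, np.exp(-1.0)) == pytest.approx(1.0)

    def test_ballistic_limit(self):
        assert sample_free_path(0.0, 0.5) == np.inf

    def test_sample_mean_mid_slab(self):
        mus = 37.594
        rng = np.random.default_rng(123)
        u = rng.random(10 ** 6)
        samples = -np.log(u) / mus  # closed form applied in bulk
        se = (1 / mus) / np.sqrt(len(samples))  # exponential: sd = mean
        assert abs(samples.mean() - 1 / mus) < 3 * se
        # spot-check scalar path matches the vectorized closed form
        assert sample_free_path(mus, u[0]) == pytest.approx(samples[0])


class TestHenyeyGreenstein:
    def test_isotropic_cos_theta_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        ct = np.array([sample_hg(0.0, u1, u2) @ np.array([0, 0, 1.0])
                       for u1, u2 in rng.random((10 ** 4, 2))])
        res = stats.kstest(ct, stats.uniform(loc=-1, scale=2).cdf)
        assert res.pvalue > 0.01

    def test_mean_cos_theta_equals_g(self):
        g = 0.9
        rng = np.random.default_rng(11)
        u1 = rng.random(10 ** 5)
        frac = (1 - g * g) / (1 - g + 2 * g * u1)
        ct = (1 + g * g - frac ** 2) / (2 * g)
        sd = ct.std(ddof=1)
        assert abs(ct.mean() - g) < 3 * sd / np.sqrt(len(ct))

    def test_forward_limit(self):
        for u1 in (0.1, 0.5, 0.9):
            d = sample_hg(0.999999, u1, 0.3, incident=(0, 0, 1))
            assert d @ np.array([0, 0, 1.0]) > 0.99

    def test_scattered_direction_is_unit(self):
        d = sample_hg(0.7, 0.3, 0.8, incident=(0.6, 0.0, 0.8))
        assert np.linalg.norm(d) == pytest.approx(1.0)


class TestFresnel:
    def test_matched_media_always_refracts_unchanged(self):
        d = np.array([0.6, 0.0, 0.8])
        kind, out = fresnel_boundary(1.37, 1.37, d, (0, 0, 1.0), u=0.999999)
        assert kind == "refract"
        np.testing.assert_allclose(out, d)

    def test_normal_incidence_tissue_value(self):
        R = fresnel_reflectance(1.0, 1.37, 1.0)
        assert R == pytest.approx(((1 - 1.37) / (1 + 1.37)) ** 2, abs=1e-12)
        assert R == pytest.approx(0.02437, abs=1e-5)

    def test_total_internal_reflection_beyond_critical(self):
        # critical angle for 1.37 -> 1.0 is about 46.9 deg
        inc = np.deg2rad(60.0)
        assert fresnel_reflectance(1.37, 1.0, np.cos(inc)) == 1.0
        d = np.array([np.sin(inc), 0.0, np.cos(inc)])
        kind, out = fresnel_boundary(1.37, 1.0, d, (0, 0, 1.0), u=0.999999)
        assert kind == "reflect"
        np.testing.assert_allclose(out, [np.sin(inc), 0, -np.cos(inc)],
                                   atol=1e-12)

    def test_snell_refraction_angle(self):
        n1, n2 = 1.0, 1.5
        inc = np.deg2rad(30.0)
        d = np.array([np.sin(inc), 0.0, np.cos(inc)])
        kind, out = fresnel_boundary(n1, n2, d, (0, 0, 1.0), u=0.999999)
        assert kind == "refract"
        sin_t = n1 / n2 * np.sin(inc)
        assert out[0] == pytest.approx(sin_t, abs=1e-12)
        assert out[2] == pytest.approx(np.sqrt(1 - sin_t ** 2), abs=1e-12)


def _uniform_props(mua=0.05, mus=5.0, g=0.8, n=1.0):
    return {1: tetmc.OpticalProps(mua=mua, mus=mus, g=g, n=n)}


class TestRunSimulation:
    def test_missing_label_props_rejected(self, box_mesh_1mm):
        src = tetmc.PhotonSource(position=(0.5, 0.5, 0), direction=(0, 0, 1),
                                 nphoton=10)
        with pytest.raises(ValueError, match="missing optical properties"):
            tetmc.run_simulation(box_mesh_1mm, {}, src)

    def test_pencil_source_outside_rejected(self, box_mesh_1mm):
        src = tetmc.PhotonSource(position=(0.5, 0.5, -5.0),
                                 direction=(0, 0, 1), nphoton=10)
        with pytest.raises(ValueError, match="outside"):
            tetmc.run_simulation(box_mesh_1mm, _uniform_props(), src)

    def test_weight_conservation_and_nonnegativity(self, box_mesh_1mm):
        src = tetmc.PhotonSource(position=(0.5, 0.5, 0), direction=(0, 0, 1),
                                 nphoton=5000)
        fl = tetmc.run_simulation(box_mesh_1mm, _uniform_props(), src,
                                  tetmc.SimSettings(seed=2))
        s = fl.stats
        balance = s["absorbed"] + s["escaped"] + s["truncated"]
        assert balance == pytest.approx(s["launched"], rel=1e-6)
        assert np.all(fl.values >= 0)
        assert s["lost"] < 1e-5 * s["launched"]

    def test_seed_determinism(self, box_mesh_1mm):
        src = tetmc.PhotonSource(position=(0.5, 0.5, 0), direction=(0, 0, 1),
                                 nphoton=2000)
        a = tetmc.run_simulation(box_mesh_1mm, _uniform_props(), src,
                                 tetmc.SimSettings(seed=9))
        b = tetmc.run_simulation(box_mesh_1mm, _uniform_props(), src,
                                 tetmc.SimSettings(seed=9))
        np.testing.assert_array_equal(a.values, b.values)
        assert a.stats == b.stats
        c = tetmc.run_simulation(box_mesh_1mm, _uniform_props(), src,
                                 tetmc.SimSettings(seed=10))
        assert not np.array_equal(a.values, c.values)

    def test_ballistic_beam_stays_on_axis(self, box_mesh_1mm):
        """With no scattering the packet path is a straight polyline: all
        deposited fluence lies on nodes adjacent to the beam line."""
        src = tetmc.PhotonSource(position=(0.5, 0.5, 0), direction=(0, 0, 1),
                                 nphoton=200)
        fl = tetmc.run_simulation(
            box_mesh_1mm, _uniform_props(mua=1.0, mus=0.0), src,
            tetmc.SimSettings(seed=3))
        hot = fl.gate() > 0
        dist = np.linalg.norm(box_mesh_1mm.node[:, :2] - [0.5, 0.5], axis=1)
        assert np.all(dist[hot] <= 0.25 * np.sqrt(2) + 1e-9)
        assert fl.stats["escaped_fraction"] == pytest.approx(np.exp(-1.0),
                                                             rel=1e-9)

    def test_disk_source_enters_from_outside(self, box_mesh_1mm):
        src = tetmc.PhotonSource(position=(0.5, 0.5, -0.05),
                                 direction=(0, 0, 1), srctype="disk",
                                 srcparam1=(0.2, 0, 0, 0), unit_scale=1.0,
                                 nphoton=2000)
        fl = tetmc.run_simulation(box_mesh_1mm, _uniform_props(), src,
                                  tetmc.SimSettings(seed=4))
        s = fl.stats
        assert s["absorbed"] + s["escaped"] + s["truncated"] == \
            pytest.approx(s["launched"], rel=1e-6)
        assert s["absorbed"] > 0

    def test_reflection_increases_absorption(self, box_mesh_1mm):
        """Index-mismatched boundaries trap light inside the tissue."""
        src = tetmc.PhotonSource(position=(0.5, 0.5, 0), direction=(0, 0, 1),
                                 nphoton=3000)
        props = _uniform_props(n=1.37)
        off = tetmc.run_simulation(box_mesh_1mm, props, src,
                                   tetmc.SimSettings(seed=6,
                                                     do_reflection=False))
        on = tetmc.run_simulation(box_mesh_1mm, props, src,
                                  tetmc.SimSettings(seed=6,
                                                    do_reflection=True))
        assert on.stats["absorbed_fraction"] > off.stats["absorbed_fraction"]


class TestLog10Display:
    def test_values(self):
        disp = tetmc.log10_display(np.array([100.0, 0.0]), floor=1e-12)
        np.testing.assert_allclose(disp, [2.0, -12.0])

    def test_monotone(self):
        rng = np.random.default_rng(0)
        v = rng.random(50)
        disp = tetmc.log10_display(v, floor=1e-15)
        assert np.all(np.argsort(disp) == np.argsort(v))

    def test_floor_must_be_positive(self):
        with pytest.raises(ValueError):
            tetmc.log10_display(np.ones(3), floor=0.0)
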