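"""Synthetic scene generator: geometry, determinism, artifacts, oracle."""

import numpy as np
import pytest

import stemscan as ss
from stemscan.synthetic import GROUND_LABEL, STEM_LABEL_OFFSET

from conftest import grid_circle_fit


def single_stem_config(**overrides):
    kw = dict(
        plot_radius=4.0,
        ground_relief_amplitude=0.0,
        ground_point_spacing=0.05,
        ground_noise_sd=0.0,
        point_spacing=0.02,
        stems=[ss.StemSpec(base_xy=(0.5, 0.0), dbh_true=30.0, height=2.0,
                           taper_rate=0.0)],
        seed=11,
    )
    kw.update(overrides)
    return ss.SceneConfig(**kw)


class TestGenerateScene:
    def test_noiseless_cylinder_radius_exact(self, flat_single_stem_scene):
        scene = flat_single_stem_scene
        lab = scene.cloud.attributes["label"]
        at_bh = np.isclose(scene.cloud.z, 1.3) & (lab == STEM_LABEL_OFFSET)
        assert at_bh.sum() > 10
        d = np.hypot(scene.cloud.xyz[at_bh, 0] - 1.0,
                     scene.cloud.xyz[at_bh, 1] - 0.5)
        np.testing.assert_allclose(d, 0.15, atol=1e-9)

    def test_two_stem_truth_distance(self):
        cfg = single_stem_config(stems=[
            ss.StemSpec(base_xy=(0.0, 0.0), dbh_true=20.0, height=2.0),
            ss.StemSpec(base_xy=(2.0, 0.0), dbh_true=20.0, height=2.0),
        ])
        scene = ss.generate_scene(cfg)
        assert scene.truth_stems[0]["nearest_stem_distance_true"] == pytest.approx(2.0)
        assert scene.truth_stems[1]["nearest_stem_distance_true"] == pytest.approx(2.0)

    def test_seed_determinism(self):
        a = ss.generate_scene(single_stem_config(seed=42))
        b = ss.generate_scene(single_stem_config(seed=42))
        np.testing.assert_array_equal(a.cloud.xyz, b.cloud.xyz)
        np.testing.assert_array_equal(a.cloud.attributes["label"],
                                      b.cloud.attributes["label"])

    def test_overlapping_stems_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ss.generate_scene(single_stem_config(stems=[
                ss.StemSpec(base_xy=(0.0, 0.0), dbh_true=40.0, height=2.0),
                ss.StemSpec(base_xy=(0.3, 0.0), dbh_true=40.0, height=2.0),
            ]))

    def test_ground_follows_terrain(self, sinusoid_understory_scene):
        scene = sinusoid_understory_scene
        lab = scene.cloud.attributes["label"]
        g = scene.cloud.xyz[lab == GROUND_LABEL]
        truth = scene.true_ground_height(g[:, 0], g[:, 1])
        # ground deviates from the terrain function only by the point noise
        assert np.abs(g[:, 2] - truth).max() < 5 * 0.005

    def test_config_yaml_roundtrip(self):
        cfg = single_stem_config(artifact=ss.ArtifactSpec(backscatter_bias=0.01))
        back = ss.SceneConfig.from_yaml(cfg.to_yaml())
        assert back.stems[0].dbh_true == 30.0
        assert back.artifact.backscatter_bias == 0.01
        np.testing.assert_array_equal(
            ss.generate_scene(back).cloud.xyz,
            ss.generate_scene(cfg).cloud.xyz,
        )


class TestApplyArtifacts:
    def test_identity_artifacts_leave_points_unchanged(self):
        scene = ss.generate_scene(single_stem_config())
        art = ss.ArtifactSpec(duplicate_offset=0.0, duplicate_fraction=0.25,
                              drift_rate=0.0, backscatter_bias=0.0,
                              sensor_range=3.0)
        out = ss.apply_artifacts(scene, art)
        n = len(scene.cloud)
        np.testing.assert_array_equal(out.cloud.xyz[:n], scene.cloud.xyz)
        # any extra points are duplicated in place
        dup = out.cloud.attributes["duplicate"] == 1
        assert (~dup[:n]).all()

    def test_positive_backscatter_inflates_fitted_diameter(self):
        """+1 cm edge bias on a noiseless 30 cm stem must push the fitted
        circle diameter above 30 cm (checked against an independent
        brute-force circle search)."""
        scene = ss.generate_scene(single_stem_config())
        art = ss.ArtifactSpec(backscatter_bias=0.01, backscatter_fraction=0.3,
                              drift_rate=0.0, duplicate_fraction=0.0,
                              sensor_range=3.0)
        out = ss.apply_artifacts(scene, art)
        lab = out.cloud.attributes["label"]
        sl = (np.abs(out.cloud.z - 1.3) <= 0.05) & (lab == STEM_LABEL_OFFSET)
        _, r = grid_circle_fit(out.cloud.xyz[sl][:, :2])
        assert 200 * r > 30.0

    def test_negative_backscatter_deflates_fitted_diameter(self):
        scene = ss.generate_scene(single_stem_config())
        art = ss.ArtifactSpec(backscatter_bias=-0.01, backscatter_fraction=0.3,
                              drift_rate=0.0, duplicate_fraction=0.0,
                              sensor_range=3.0)
        out = ss.apply_artifacts(scene, art)
        lab = out.cloud.attributes["label"]
        sl = (np.abs(out.cloud.z - 1.3) <= 0.05) & (lab == STEM_LABEL_OFFSET)
        _, r = grid_circle_fit(out.cloud.xyz[sl][:, :2])
        assert 200 * r < 30.0

    def test_fitted_bias_monotone_in_backscatter_bias(self):
        """On a fixed seed the fitted DBH is nondecreasing in the injected
        radial edge bias."""
        dbhs = []
        for bias in (-0.02, -0.01, 0.0, 0.01, 0.02):
            scene = ss.generate_scene(single_stem_config())
            art = ss.ArtifactSpec(backscatter_bias=bias,
                                  backscatter_fraction=0.3,
                                  drift_rate=0.0, duplicate_fraction=0.0,
                                  sensor_range=3.0)
            out = ss.apply_artifacts(scene, art)
            lab = out.cloud.attributes["label"]
            sl = (np.abs(out.cloud.z - 1.3) <= 0.05) & (lab == STEM_LABEL_OFFSET)
            _, _, r = _kasa(out.cloud.xyz[sl][:, :2])
            dbhs.append(200 * r)
        assert all(b >= a for a, b in zip(dbhs, dbhs[1:]))

    def test_duplicate_face_offset_appears(self):
        cfg = single_stem_config(stems=[
            ss.StemSpec(base_xy=(0.0, 0.0), dbh_true=30.0, height=2.0),
            ss.StemSpec(base_xy=(2.0, 0.0), dbh_true=30.0, height=2.0),
        ])
        scene = ss.generate_scene(cfg)
        art = ss.ArtifactSpec(duplicate_offset=0.05, duplicate_fraction=0.3,
                              drift_rate=0.0, sensor_range=3.0)
        out = ss.apply_artifacts(scene, art)
        dup = out.cloud.attributes["duplicate"] == 1
        assert dup.sum() > 0
        assert len(out.cloud) > len(scene.cloud)


def _kasa(xy):
    c, r = ss.fit_circle_kasa(xy)
    return c[0], c[1], r


class TestVolumeOracle:
    def test_aligned_box_exact(self):
        patch = ss.PatchSpec(shape="box", center_xy=(1.0, 1.0), extent=(1, 1, 0.5))
        vol = ss.analytic_understory_volume_oracle([patch], (1.0, 1.0), 2.0, 0.01)
        assert vol == pytest.approx(0.5, abs=1e-12)

    def test_empty_patches(self):
        assert ss.analytic_understory_volume_oracle([], (0, 0), 2.0, 0.01) == 0.0

    def test_invalid_voxel_edge(self):
        with pytest.raises(ValueError):
            ss.analytic_understory_volume_oracle([], (0, 0), 2.0, 0.0)

    def test_hemisphere_between_half_ball_and_cylinder(self):
        """Column-fill volume of a hemisphere must land between the true
        half-ball volume and its bounding cylinder, and agree with a 4x
        finer rasterisation."""
        r = 0.5
        patch = ss.PatchSpec(shape="hemisphere", center_xy=(0.0, 0.0),
                             extent=(2 * r, 2 * r, r))
        vol = ss.analytic_understory_volume_oracle([patch], (0, 0), 2.0, 0.01)
        half_ball = 2.0 / 3.0 * np.pi * r ** 3
        cylinder = np.pi * r ** 2 * r
        assert half_ball < vol < cylinder
        fine = ss.analytic_understory_volume_oracle([patch], (0, 0), 2.0, 0.0025)
        assert vol == pytest.approx(fine, rel=0.02)
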