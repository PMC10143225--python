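"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import stemscan as ss


def grid_circle_fit(xy: np.ndarray, refinements: int = 6):
    """Independent brute-force circle fit: coarse-to-fine grid search over
    (cx, cy, r) minimising sum((dist - r)^2). Slow but has no shared code
    with the least-squares path it cross-checks."""
    xy = np.asarray(xy, dtype=float)
    cx, cy = xy.mean(axis=0)
    r = float(np.hypot(xy[:, 0] - cx, xy[:, 1] - cy).mean())
    span = max(r, 0.1)

    def cost(cx, cy, r):
        d = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
        return float(np.sum((d - r) ** 2))

    for _ in range(refinements):
        grid = np.linspace(-span, span, 11)
        best = (cost(cx, cy, r), cx, cy, r)
        for dx in grid:
            for dy in grid:
                for dr in grid:
                    rr = r + dr
                    if rr <= 0:
                        continue
                    c = cost(cx + dx, cy + dy, rr)
                    if c < best[0]:
                        best = (c, cx + dx, cy + dy, rr)
        _, cx, cy, r = best
        span /= 5.0
    return np.array([cx, cy]), r


@pytest.fixture(scope="session")
def flat_single_stem_scene():
    """One vertical noiseless 30 cm stem at (1, 0.5) on flat ground."""
    cfg = ss.SceneConfig(
        plot_radius=5.0,
        ground_relief_amplitude=0.0,
        ground_point_spacing=0.05,
        ground_noise_sd=0.0,
        point_spacing=0.02,
        stems=[ss.StemSpec(base_xy=(1.0, 0.5), dbh_true=30.0, height=2.0,
                           taper_rate=0.0)],
        seed=42,
    )
    return ss.generate_scene(cfg)


@pytest.fixture(scope="session")
def sinusoid_understory_scene():
    """Sinusoidal relief (0.3 m amplitude) with two understory patches."""
    cfg = ss.SceneConfig(
        plot_radius=6.0,
        ground_relief_amplitude=0.3,
        ground_point_spacing=0.05,
        ground_noise_sd=0.005,
        point_spacing=0.02,
        understory_patches=[
            ss.PatchSpec(shape="box", center_xy=(1.5, 0.0), extent=(1, 1, 0.5),
                         surface_point_spacing=0.02),
            ss.PatchSpec(shape="hemisphere", center_xy=(-2.0, 1.0),
                         extent=(2, 2, 0.8), surface_point_spacing=0.02),
        ],
        seed=7,
    )
    return ss.generate_scene(cfg)


def segments_from_truth_labels(scene: ss.SyntheticScene, ground_mask: np.ndarray):
    """Build stem segments from the generator's truth labels, bypassing the
    segmentation stage, so measurement tests isolate the circle fit."""
    from stemscan.synthetic import STEM_LABEL_OFFSET

    labels = scene.cloud.attributes["label"]
    veg_idx = np.nonzero(~ground_mask)[0]
    veg_labels = labels[veg_idx]
    segs = []
    for i in range(len(scene.config.stems)):
        member = np.nonzero(veg_labels == STEM_LABEL_OFFSET + i)[0]
        segs.append(ss.StemSegment(stem_id=i, point_indices=member,
                                   voxel_count=len(member)))
    return segs
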