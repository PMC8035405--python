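"""Generator tests: determinism, truth consistency, mixing behavior,
volume/time-lapse ground truth."""

import numpy as np
import pandas as pd
import pytest

from osteomix.containers import ConfigurationError, DataError
from osteomix.synthetic import (
    ContactEpisode,
    SceneConfig,
    generate_field,
    generate_timelapse,
    generate_volume,
    pair_overlap_pixels,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"mixing_lambda": -0.1},
        {"mixing_lambda": 1.5},
        {"n_blue_cells": -1},
        {"r_red_um": 0.0},
        {"cluster_count": 0},
        {"pixel_size_um": -1.0},
        {"noise_sd": -0.5},
    ],
)
def test_invalid_config_raises_naming_error(kwargs):
    with pytest.raises(ConfigurationError):
        SceneConfig(**kwargs)


def test_field_determinism(small_scene_config):
    img1, t1 = generate_field(small_scene_config)
    img2, t2 = generate_field(small_scene_config)
    assert np.array_equal(img1.cyan, img2.cyan)
    assert np.array_equal(img1.red, img2.red)
    pd.testing.assert_frame_equal(t1.objects, t2.objects)
    pd.testing.assert_frame_equal(t1.tile_areas, t2.tile_areas)


def test_field_truth_rasterizes_to_masks(small_scene_config):
    _, truth = generate_field(small_scene_config)
    re_rendered = truth.rasterize()
    for ch in ("cyan", "red"):
        assert np.array_equal(re_rendered[ch], truth.masks[ch])


def test_field_tile_areas_match_masks(small_scene_config):
    _, truth = generate_field(small_scene_config)
    fh, fw = small_scene_config.field_shape
    for row in truth.tile_areas.itertuples(index=False):
        sl = np.s_[row.tile_row * fh : (row.tile_row + 1) * fh,
                   row.tile_col * fw : (row.tile_col + 1) * fw]
        assert row.cyan_area_px == truth.masks["cyan"][sl].sum()
        assert row.red_area_px == truth.masks["red"][sl].sum()


def test_empty_blue_channel_is_background_only(small_scene_config):
    cfg = SceneConfig(
        **{**small_scene_config.__dict__, "n_blue_cells": 0}
    )
    image, truth = generate_field(cfg)
    assert (truth.objects["channel"] == "cyan").sum() == 0
    assert not truth.masks["cyan"].any()
    # only background + noise: nothing near the blob amplitude
    assert image.cyan.max() < cfg.background + 6 * cfg.noise_sd


def test_segregated_scene_keeps_red_away_from_blue_centers():
    """At mixing_lambda=0 with a small cluster SD, no red object centroid
    falls within 2 cluster SDs of any blue cluster center (checked on the
    generator's own truth over 20 seeds)."""
    violations = 0
    for seed in range(20):
        cfg = SceneConfig(
            field_shape=(256, 256),
            field_grid=(2, 2),
            n_blue_cells=40,
            n_red_cells=25,
            r_blue_um=5.0,
            r_red_um=8.0,
            cluster_count=4,
            cluster_sd_um=15.0,
            mixing_lambda=0.0,
            seed=seed,
        )
        image, truth = generate_field(cfg)
        sd_px = cfg.cluster_sd_um / cfg.pixel_size_um
        reds = truth.objects[truth.objects["channel"] == "red"]
        centers = truth.cluster_centers
        blue_centers = centers[centers["channel"] == "cyan"]
        for r in reds.itertuples(index=False):
            d = np.hypot(
                blue_centers["row"] - r.centroid_row,
                blue_centers["col"] - r.centroid_col,
            )
            if (d < 2 * sd_px).any():
                violations += 1
    assert violations == 0


def test_mixing_reduces_red_to_blue_distance():
    """Mean nearest blue-object distance from red objects is non-increasing
    in mixing_lambda, averaged over 20 seeds."""
    lambdas = [0.0, 0.5, 1.0]
    means = []
    for lam in lambdas:
        dists = []
        for seed in range(20):
            cfg = SceneConfig(
                field_shape=(256, 256),
                field_grid=(1, 1),
                n_blue_cells=30,
                n_red_cells=15,
                cluster_count=3,
                cluster_sd_um=20.0,
                mixing_lambda=lam,
                seed=seed,
            )
            _, truth = generate_field(cfg)
            obj = truth.objects
            b = obj[obj.channel == "cyan"][["centroid_row", "centroid_col"]].to_numpy()
            r = obj[obj.channel == "red"][["centroid_row", "centroid_col"]].to_numpy()
            d = np.sqrt(((r[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min(axis=1)
            dists.append(d.mean())
        means.append(np.mean(dists))
    assert means[0] >= means[1] >= means[2]
    assert means[0] > means[2]


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def test_volume_truth_volumes_are_count_exact(small_volume_config):
    cfg = SceneConfig(**{**small_volume_config.__dict__, "pixel_size_um": 0.5,
                         "z_step_um": 1.0, "n_z": 20, "n_red_cells": 0})
    volume, truth = generate_volume(cfg, blue_volumes_um3=[100.0, 500.0], red_volumes_um3=[])
    vv = volume.voxel_volume_um3
    got = sorted(truth.objects["volume_um3"])
    assert got[0] == pytest.approx(100.0, abs=vv)
    assert got[1] == pytest.approx(500.0, abs=vv)
    # voxel-count oracle on the truth masks
    assert truth.objects["voxel_count"].sum() == truth.masks["cyan"].sum()


def test_volume_truth_rasterizes_to_masks(small_volume_config):
    _, truth = generate_volume(small_volume_config, n_scripted_contacts=1)
    re_rendered = truth.rasterize()
    for ch in ("cyan", "red"):
        assert np.array_equal(re_rendered[ch], truth.masks[ch])


def test_voxel_volume_scales_cubically(small_volume_config):
    _, t1 = generate_volume(small_volume_config)
    doubled = SceneConfig(**{**small_volume_config.__dict__,
                             "pixel_size_um": 2 * small_volume_config.pixel_size_um,
                             "z_step_um": 2 * small_volume_config.z_step_um})
    _, t2 = generate_volume(doubled)
    # same voxel counts => 8x physical volume
    v1 = t1.objects.sort_values("id")["voxel_count"].to_numpy()
    v2 = t2.objects.sort_values("id")["voxel_count"].to_numpy()
    vol1 = t1.objects.sort_values("id")["volume_um3"].to_numpy()
    vol2 = t2.objects.sort_values("id")["volume_um3"].to_numpy()
    np.testing.assert_allclose(vol2 / vol1, 8.0 * v2 / v1)


def test_empty_volume_config_gives_empty_table(small_volume_config):
    cfg = SceneConfig(**{**small_volume_config.__dict__,
                         "n_blue_cells": 0, "n_red_cells": 0})
    _, truth = generate_volume(cfg)
    assert truth.objects.empty
    assert not truth.masks["cyan"].any() and not truth.masks["red"].any()


def test_scripted_volume_contacts_have_overlap(small_volume_config):
    cfg = SceneConfig(**{**small_volume_config.__dict__, "field_shape": (150, 150),
                         "n_blue_cells": 3, "n_red_cells": 2})
    _, truth = generate_volume(cfg, n_scripted_contacts=2)
    assert len(truth.contacts) == 2
    assert (truth.contacts["overlap_voxels"] > 2).all()


# ---------------------------------------------------------------------------
# Time-lapse
# ---------------------------------------------------------------------------

def _tl_config(seed=0, n_blue=2, n_red=2):
    return SceneConfig(
        field_shape=(200, 200),
        field_grid=(1, 1),
        n_blue_cells=n_blue,
        n_red_cells=n_red,
        r_blue_um=8.0,
        r_red_um=18.0,
        snr=10.0,
        noise_sd=0.01,
        seed=seed,
    )


def test_scripted_episode_overlap_frames_match_script():
    episodes = [ContactEpisode(blue_id=0, red_id=0, start=2, end=4)]
    _, truth = generate_timelapse(_tl_config(), n_frames=6, frame_interval_min=8.0,
                                  scripted_contacts=episodes)
    for t in range(6):
        overlap = pair_overlap_pixels(truth, t, 0, 0)
        if 2 <= t <= 4:
            assert overlap > 0
        else:
            assert overlap == 0


def test_empty_script_has_no_cross_channel_overlap():
    for seed in range(10):
        _, truth = generate_timelapse(_tl_config(seed=seed), n_frames=5,
                                      frame_interval_min=8.0)
        for t in range(5):
            both = truth.masks["cyan"][t] & truth.masks["red"][t]
            assert both.sum() == 0, f"seed {seed} frame {t}"


def test_episode_duration_arithmetic():
    episodes = [ContactEpisode(0, 0, 1, 3)]
    _, truth = generate_timelapse(_tl_config(), n_frames=6, frame_interval_min=8.0,
                                  scripted_contacts=episodes)
    assert truth.episodes["duration_min"].iloc[0] == 24.0


def test_contradictory_episodes_rejected():
    with pytest.raises(ConfigurationError):
        generate_timelapse(
            _tl_config(),
            n_frames=6,
            frame_interval_min=8.0,
            scripted_contacts=[ContactEpisode(0, 0, 1, 3), ContactEpisode(1, 0, 2, 4)],
        )


@pytest.mark.parametrize(
    "episode",
    [ContactEpisode(5, 0, 0, 1), ContactEpisode(0, 9, 0, 1), ContactEpisode(0, 0, 4, 7)],
)
def test_invalid_episode_references_rejected(episode):
    with pytest.raises(ConfigurationError):
        generate_timelapse(_tl_config(), n_frames=5, frame_interval_min=8.0,
                           scripted_contacts=[episode])


def test_timelapse_determinism():
    episodes = [ContactEpisode(0, 1, 1, 2)]
    tl1, t1 = generate_timelapse(_tl_config(seed=3), 4, 8.0, episodes)
    tl2, t2 = generate_timelapse(_tl_config(seed=3), 4, 8.0, episodes)
    for f1, f2 in zip(tl1.frames, tl2.frames):
        assert np.array_equal(f1.cyan, f2.cyan)
        assert np.array_equal(f1.red, f2.red)
    pd.testing.assert_frame_equal(t1.objects, t2.objects)
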