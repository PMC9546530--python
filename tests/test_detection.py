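"""Detector tests: background subtraction, LoG detection, split-touching,
soma counting and region assignment."""

import numpy as np
import pandas as pd
import pytest

import synaptomap as sm
from synaptomap.detection import empty_spot_table
from synaptomap.synthdata import FWHM_TO_SIGMA, sample_spots_min_spacing
from synaptomap.volumes import CHANNEL_RED

VOXEL = (1.0, 0.2, 0.2)
NOISE_SD = np.sqrt(100.0 + 100.0)  # Poisson at background 100 + read sd 10


def render_points(coords_um, shape, amplitude=100.0, fwhm=0.8, noise="none",
                  background=0.0, seed=0, channel="syp_egfp"):
    spots = pd.DataFrame(
        {
            "id": np.arange(1, len(coords_um) + 1),
            "z_um": [c[0] for c in coords_um],
            "y_um": [c[1] for c in coords_um],
            "x_um": [c[2] for c in coords_um],
            "region_label": 1,
            "amplitude": 1.0,
        }
    )
    truth = sm.GroundTruth(spots, {}, {}, seed=seed)
    cfg = sm.SyntheticConfig(
        volume_shape=shape, voxel_size=VOXEL, punctum_amplitude=amplitude,
        punctum_fwhm=fwhm, background_level=background, noise_model=noise, seed=seed,
    )
    return sm.render_volume(truth, cfg, channel=channel, fwhm_um=fwhm)


class TestSubtractBackground:
    def test_constant_volume_removed_exactly(self):
        vol = sm.ImageVolume(np.full((8, 32, 32), 37.0), VOXEL)
        out = sm.subtract_background(vol, 5.0)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_narrow_punctum_retained(self):
        vol = render_points([(8.5, 3.3, 3.3)], (16, 32, 32), amplitude=100.0)
        peak_before = vol.data.max()
        out = sm.subtract_background(vol, 5.0)  # 5 um >> 6 sigma (0.34 um)
        assert out.data.max() >= 0.9 * peak_before

    def test_output_never_negative(self):
        rng = np.random.default_rng(0)
        vol = sm.ImageVolume(rng.random((8, 16, 16)) * 50, VOXEL)
        assert sm.subtract_background(vol, 4.0).data.min() >= 0

    def test_nonpositive_radius_rejected(self):
        vol = sm.ImageVolume(np.zeros((4, 8, 8)), VOXEL)
        with pytest.raises(ValueError):
            sm.subtract_background(vol, 0.0)


class TestDetectSpots:
    def test_empty_volume_gives_empty_table(self):
        vol = sm.ImageVolume(np.zeros((8, 32, 32)), VOXEL)
        spots = sm.detect_spots(vol)
        assert len(spots) == 0
        assert list(spots.columns) == list(empty_spot_table().columns)

    def test_recovers_separated_puncta_at_snr10(self, small_atlas):
        truth = sample_spots_min_spacing(small_atlas, 50, 2.0, seed=3)
        cfg = sm.SyntheticConfig(
            volume_shape=(32, 64, 64), voxel_size=VOXEL,
            punctum_amplitude=10 * NOISE_SD, seed=3,
        )
        vol = sm.render_volume(truth, cfg)
        params = sm.DetectionParams(threshold_policy="absolute", threshold_value=40.0)
        detected = sm.detect_spots(vol, params)
        metrics = sm.match_spots(detected, truth.spots, match_radius_um=0.5)
        assert len(detected) == 50
        assert metrics["n_matched"] == 50

    @pytest.mark.parametrize(
        "separation_um, expected",
        [(0.8, 1), (1.5, 2)],
        ids=["touching-pair-merges", "resolved-pair-splits"],
    )
    def test_split_touching_rule(self, separation_um, expected):
        """Peaks closer than the 1 um split-touching distance merge."""
        y0 = 6.4
        coords = [(8.5, y0 - separation_um / 2, 6.4), (8.5, y0 + separation_um / 2, 6.4)]
        vol = render_points(coords, (16, 64, 64), amplitude=100.0)
        params = sm.DetectionParams(threshold_policy="absolute", threshold_value=5.0)
        assert len(sm.detect_spots(vol, params)) == expected

    def test_translation_equivariance(self):
        coords = [(8.5, 3.1, 3.7), (4.5, 8.3, 9.1)]
        shift_vox = (2, 5, 7)  # whole voxels
        shift_um = np.array(shift_vox) * np.array(VOXEL)
        vol = render_points(coords, (16, 64, 64))
        shifted = render_points([tuple(np.array(c) + shift_um) for c in coords], (16, 64, 64))
        params = sm.DetectionParams(threshold_policy="absolute", threshold_value=5.0)
        a = sm.detect_spots(vol, params).sort_values("z_um").reset_index(drop=True)
        b = sm.detect_spots(shifted, params).sort_values("z_um").reset_index(drop=True)
        assert len(a) == len(b) == 2
        # exact up to filter edge handling, which perturbs at the 1e-5 um level
        for col, s in zip(["z_um", "y_um", "x_um"], shift_um):
            np.testing.assert_allclose(b[col], a[col] + s, atol=1e-3)

    def test_threshold_adjust_monotone(self, rendered_sample):
        _, volume, _ = rendered_sample
        counts = [
            len(sm.detect_spots(volume, sm.DetectionParams(threshold_adjust=adj)))
            for adj in (0.95, 1.0, 1.05)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_noisefree_localization_below_half_voxel_diagonal(self, small_atlas):
        truth = sample_spots_min_spacing(small_atlas, 40, 2.0, seed=11)
        cfg = sm.SyntheticConfig(
            volume_shape=(32, 64, 64), voxel_size=VOXEL, noise_model="none",
            background_level=0.0, punctum_amplitude=100.0, seed=11,
        )
        vol = sm.render_volume(truth, cfg)
        params = sm.DetectionParams(threshold_policy="absolute", threshold_value=5.0)
        metrics = sm.match_spots(sm.detect_spots(vol, params), truth.spots)
        half_diagonal = 0.5 * np.sqrt(sum(d * d for d in VOXEL))
        assert metrics["recall"] == 1.0
        assert metrics["median_error_um"] <= half_diagonal

    def test_anisotropy_invariance(self, small_atlas):
        """Physical-unit results survive re-rendering at finer z sampling."""
        truth = sample_spots_min_spacing(small_atlas, 30, 2.5, seed=13)
        params = sm.DetectionParams(threshold_policy="absolute", threshold_value=5.0)
        results = []
        for vox in [(1.0, 0.2, 0.2), (0.5, 0.2, 0.2)]:
            shape = (int(32 / vox[0]), 64, 64)
            cfg = sm.SyntheticConfig(
                volume_shape=shape, voxel_size=vox, noise_model="none",
                background_level=0.0, punctum_amplitude=100.0, seed=13,
            )
            vol = sm.render_volume(truth, cfg)
            results.append(sm.match_spots(sm.detect_spots(vol, params), truth.spots))
        assert results[0]["n_matched"] == results[1]["n_matched"] == 30


class TestDetectSomas:
    def test_no_somas_counts_zero(self):
        vol = sm.ImageVolume(np.zeros((16, 64, 64)), VOXEL, channel=CHANNEL_RED)
        _, count = sm.detect_somas(vol)
        assert count == 0

    def test_counts_rendered_somas_and_ignores_puncta(self):
        atlas = sm.make_atlas((48, 256, 256), VOXEL, n_regions=1, seed=2)
        somas = sample_spots_min_spacing(atlas, 5, 25.0, seed=2)
        red = render_points(
            [tuple(c) for c in somas.coords_um], (48, 256, 256),
            amplitude=10 * NOISE_SD, fwhm=10.0, noise="poisson+gaussian",
            background=100.0, seed=2, channel=CHANNEL_RED,
        )
        _, count = sm.detect_somas(red)
        assert count == 5
        # scale selectivity: dense sub-micron puncta do not change the count
        puncta = sm.sample_spots(atlas, {1: 2450.0}, 2000, seed=3)
        green = sm.render_volume(
            puncta,
            sm.SyntheticConfig(volume_shape=(48, 256, 256), voxel_size=VOXEL,
                               noise_model="none", background_level=0.0, seed=3),
        )
        mixed = sm.ImageVolume(red.data + green.data, VOXEL, channel=CHANNEL_RED)
        _, count_mixed = sm.detect_somas(mixed)
        assert count_mixed == 5

    def test_green_channel_rejected(self):
        vol = sm.ImageVolume(np.zeros((16, 64, 64)), VOXEL)
        with pytest.raises(ValueError, match="tdtomato"):
            sm.detect_somas(vol)


class TestAssignRegions:
    def _table(self, coords):
        return pd.DataFrame(
            {
                "id": np.arange(1, len(coords) + 1),
                "z_um": [c[0] for c in coords],
                "y_um": [c[1] for c in coords],
                "x_um": [c[2] for c in coords],
                "intensity": 1.0,
                "region_label": 0,
                "region_acronym": "",
            }
        )

    def test_voxel_center_lookup(self, small_atlas):
        zi, yi, xi = [int(v[0]) for v in np.nonzero(small_atlas.labels == 3)]
        center = ((zi + 0.5) * 1.0, (yi + 0.5) * 0.2, (xi + 0.5) * 0.2)
        out = sm.assign_regions(self._table([center]), small_atlas)
        assert out.loc[0, "region_label"] == 3
        assert out.loc[0, "region_acronym"] == small_atlas.acronym(3)

    def test_boundary_goes_to_higher_voxel(self):
        labels = np.zeros((1, 1, 4), dtype=np.int32)
        labels[0, 0, :2] = 1
        labels[0, 0, 2:] = 2
        atlas = sm.LabelAtlas(labels, (1.0, 1.0, 1.0))
        # x = 2.0 um sits exactly on the voxel-2|voxel-3 boundary -> voxel 2
        out = sm.assign_regions(self._table([(0.5, 0.5, 2.0)]), atlas)
        assert out.loc[0, "region_label"] == 2

    def test_outside_brain_flagged_not_dropped(self, small_atlas):
        out = sm.assign_regions(self._table([(0.5, 0.1, 0.1)]), small_atlas)
        assert len(out) == 1
        assert out.loc[0, "region_label"] == 0

    def test_generated_spots_assign_to_recorded_labels(self, small_atlas):
        dens = {label: 2e5 for label in small_atlas.region_labels()}
        truth = sm.sample_spots(small_atlas, dens, 2000, seed=21)
        assert len(truth.spots) >= 1000
        table = truth.spots.rename(columns={"amplitude": "intensity"}).assign(
            region_label=0, region_acronym=""
        )
        out = sm.assign_regions(table, small_atlas)
        np.testing.assert_array_equal(
            out["region_label"].to_numpy(), truth.spots["region_label"].to_numpy()
        )

    def test_shape_mismatch_rejected(self, small_atlas, rendered_sample):
        _, volume, _ = rendered_sample
        spots = sm.detect_spots(volume)
        other = sm.make_atlas((16, 32, 32), VOXEL, n_regions=2, seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            sm.assign_regions(spots, other)
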