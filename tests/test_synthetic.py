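"""Generator ground truth must be recomputable from the generated arrays."""

import numpy as np
import pytest

from jmpkit import synthetic
from jmpkit.containers import ParameterError


class TestMonolayerScene:
    def test_no_dynamics_means_identical_frames(self):
        sc = synthetic.make_monolayer_scene(patch_spec=0, bleach_rate=0.0,
                                            drift=(0, 0), noise_sd=0.0,
                                            seed=1, shape=(6, 96, 96))
        assert np.array_equal(sc.stack.data[0], sc.stack.data[-1])

    def test_patch_raises_temporal_variance_on_truth_pixels(self):
        sc = synthetic.make_monolayer_scene(
            patch_spec=[{"radius_um": 2.5, "amplitude": 0.6}],
            bleach_rate=0.0, drift=(0, 0), noise_sd=0.0, seed=2,
            shape=(30, 128, 128))
        p = sc.truth_dynamic_patches[0]
        px = sc.stack.pixel_size_um
        yy, xx = np.mgrid[:128, :128]
        inside = ((yy - p.center_xy_um[1] / px) ** 2 +
                  (xx - p.center_xy_um[0] / px) ** 2) <= (p.radius_um / px) ** 2
        var = sc.stack.data.var(axis=0)
        assert var[inside].mean() > 100 * var[~inside].mean() + 1e-12

    def test_same_seed_is_byte_identical(self):
        kw = dict(patch_spec=2, noise_sd=2.0, seed=11, shape=(5, 96, 96))
        a = synthetic.make_monolayer_scene(**kw)
        b = synthetic.make_monolayer_scene(**kw)
        assert a.stack.data.tobytes() == b.stack.data.tobytes()
        assert np.array_equal(a.cell_labels, b.cell_labels)

    def test_patches_sit_on_junction_pixels(self):
        sc = synthetic.make_monolayer_scene(patch_spec=3, seed=4,
                                            shape=(4, 128, 128))
        px = sc.stack.pixel_size_um
        for p in sc.truth_dynamic_patches:
            r = int(round(p.center_xy_um[1] / px))
            c = int(round(p.center_xy_um[0] / px))
            assert sc.junction_mask[r, c]

    @pytest.mark.parametrize("bad", [
        dict(patch_spec=[{"radius_um": 200.0, "amplitude": 1.0}]),
        dict(patch_spec=[{"radius_um": 2.0, "amplitude": -1.0}]),
        dict(n_cells=1),
    ])
    def test_parameter_errors(self, bad):
        with pytest.raises(ParameterError):
            synthetic.make_monolayer_scene(seed=0, shape=(3, 96, 96), **bad)


class TestMembraneVolume:
    def test_hemisphere_truth_matches_closed_form(self, hemisphere_scene):
        tr = hemisphere_scene.truth_protrusions[0]
        assert tr.analytic_volume_um3 == pytest.approx(261.799, abs=0.01)
        assert tr.analytic_base_area_um2 == pytest.approx(78.540, abs=0.01)

    def test_voxelized_volume_recomputes_truth(self, hemisphere_scene):
        # independent brute force: count protrusion voxels above the sheet
        sc = hemisphere_scene
        vz = sc.voxel_size_um[0]
        z_top_idx = int(np.ceil(sc.sheet_top_um / vz))
        membrane = sc.volume.data > 50.0
        vox_vol = float(np.prod(sc.voxel_size_um))
        measured = membrane[z_top_idx:].sum() * vox_vol
        assert measured == pytest.approx(
            sc.truth_protrusions[0].analytic_volume_um3, rel=0.05)

    def test_ridge_truth_closed_form(self):
        sc = synthetic.make_membrane_volume(
            [{"kind": "ridge", "center_yx_um": (10.0, 10.0),
              "radius_um": 2.0, "length_um": 8.0, "axis": "y"}],
            voxel_size_um=(0.2, 0.2, 0.2), shape=(32, 112, 112), seed=0)
        tr = sc.truth_protrusions[0]
        assert tr.analytic_volume_um3 == pytest.approx(0.5 * np.pi * 4 * 8)
        assert tr.analytic_base_area_um2 == pytest.approx(32.0)

    def test_no_protrusions_gives_plane(self):
        sc = synthetic.make_membrane_volume([], voxel_size_um=(0.2, 0.2, 0.2),
                                            shape=(24, 64, 64), seed=0)
        assert sc.truth_protrusions == []
        membrane = sc.volume.data > 50.0
        per_slice = membrane.any(axis=(1, 2))
        assert per_slice.sum() == synthetic.SHEET_THICKNESS_VOXELS

    def test_deskew_padding_mask_matches_wedge_geometry(self):
        nz, ny, nx = 24, 64, 96
        sc = synthetic.make_membrane_volume(
            [{"kind": "hemisphere", "center_yx_um": (6.0, 9.0),
              "radius_um": 2.0}],
            voxel_size_um=(0.2, 0.2, 0.2), shape=(nz, ny, nx),
            pad_style="deskew", seed=0)
        max_off = nx // 6
        expected_zero = sum(
            ny * max_off for _ in range(nz))  # off + tail = max_off per slice
        assert (~sc.padding_mask).sum() == expected_zero
        assert not sc.volume.data[~sc.padding_mask].any()

    def test_overlapping_protrusions_rejected(self):
        with pytest.raises(ParameterError, match="overlap"):
            synthetic.make_membrane_volume(
                [{"kind": "hemisphere", "center_yx_um": (10.0, 10.0),
                  "radius_um": 4.0},
                 {"kind": "hemisphere", "center_yx_um": (10.0, 14.0),
                  "radius_um": 4.0}],
                voxel_size_um=(0.2, 0.2, 0.2), shape=(40, 128, 128), seed=0)


class TestStainVolume:
    def test_edge_mode_concentrates_at_rim(self, hemisphere_scene):
        sv = synthetic.make_stain_volume(hemisphere_scene, mode="edge", seed=0)
        sc = hemisphere_scene
        stained = np.argwhere(sv.data > 50.0)
        zz = stained[:, 0] * 0.2 - sc.sheet_top_um
        yy = stained[:, 1] * 0.2 - sc.truth_protrusions[0].center_yx_um[0]
        xx = stained[:, 2] * 0.2 - sc.truth_protrusions[0].center_yx_um[1]
        theta = np.arccos(np.clip(zz / np.sqrt(zz**2 + yy**2 + xx**2), 0, 1))
        frac_near_rim = (theta >= (np.pi / 2) * 0.9).mean()
        assert frac_near_rim >= 0.9

    def test_uniform_mode_is_uniform_over_equal_area_bands(self,
                                                           hemisphere_scene):
        from scipy import stats
        sv = synthetic.make_stain_volume(hemisphere_scene, mode="uniform",
                                         seed=0)
        sc = hemisphere_scene
        stained = np.argwhere(sv.data > 50.0)
        zz = stained[:, 0] * 0.2 - sc.sheet_top_um
        yy = stained[:, 1] * 0.2 - sc.truth_protrusions[0].center_yx_um[0]
        xx = stained[:, 2] * 0.2 - sc.truth_protrusions[0].center_yx_um[1]
        cos_t = np.clip(zz / np.sqrt(zz**2 + yy**2 + xx**2), 0, 1)
        # equal-area bands of a hemisphere are equal-width in cos(theta)
        counts, _ = np.histogram(cos_t, bins=8, range=(0, 1))
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_center_mode_peaks_at_apex(self, hemisphere_scene):
        sv = synthetic.make_stain_volume(hemisphere_scene, mode="center",
                                         seed=0)
        sc = hemisphere_scene
        tr = sc.truth_protrusions[0]
        apex = (int(round((sc.sheet_top_um + tr.radius_um) / 0.2)),
                int(round(tr.center_yx_um[0] / 0.2)),
                int(round(tr.center_yx_um[1] / 0.2)))
        peak = np.unravel_index(np.argmax(sv.data), sv.data.shape)
        assert np.linalg.norm(np.subtract(peak, apex)) <= 2.0

    def test_bad_inputs_rejected(self, hemisphere_scene):
        with pytest.raises(ParameterError):
            synthetic.make_stain_volume(hemisphere_scene, mode="sideways")
        empty = synthetic.make_membrane_volume(
            [], voxel_size_um=(0.2, 0.2, 0.2), shape=(24, 64, 64), seed=0)
        with pytest.raises(ParameterError):
            synthetic.make_stain_volume(empty, mode="uniform")


class TestFretPair:
    def test_noise_free_construction_identity(self):
        ratio = np.full((32, 32), 0.9)
        fs = synthetic.make_fret_pair(ratio, alpha_true=0.62, background=11.0,
                                      noise_sd=0.0, seed=0)
        expected = (0.9 + 0.62) * fs.donor_signal + 11.0
        np.testing.assert_allclose(fs.acceptor.data[0], expected)

    def test_unit_ratio_no_alpha_no_background(self):
        ratio = np.ones((16, 16))
        fs = synthetic.make_fret_pair(ratio, alpha_true=0.0, background=0.0,
                                      noise_sd=0.0, seed=0)
        np.testing.assert_allclose(fs.acceptor.data[0], fs.donor_signal)

    def test_seeded_noise_reproducible(self):
        ratio = np.ones((16, 16))
        a = synthetic.make_fret_pair(ratio, noise_sd=3.0, seed=5)
        b = synthetic.make_fret_pair(ratio, noise_sd=3.0, seed=5)
        assert a.acceptor.data.tobytes() == b.acceptor.data.tobytes()

    @pytest.mark.parametrize("kw", [dict(alpha_true=1.2),
                                    dict(alpha_true=-0.1),
                                    dict(background=-1.0)])
    def test_parameter_errors(self, kw):
        with pytest.raises(ParameterError):
            synthetic.make_fret_pair(np.ones((8, 8)), **kw)


class TestTracks:
    def test_truth_flags_by_construction(self, monolayer_scene):
        ts = synthetic.make_tracks(
            monolayer_scene,
            [{"kind": "immediate"}, {"kind": "lateral"}, {"kind": "turn"}],
            seed=9)
        imm, lat, turn = ts.truth_events
        assert (imm.first_junction, imm.immediate, imm.lateral,
                imm.turn) == (True, True, False, False)
        assert (lat.lateral, lat.immediate) == (True, False)
        assert turn.turn and turn.immediate

    def test_lateral_path_length_exceeds_threshold(self, monolayer_scene):
        from skimage.graph import MCP_Geometric
        ts = synthetic.make_tracks(monolayer_scene, [{"kind": "lateral"}],
                                   seed=21, lateral_distance_um=15.0)
        track = ts.tracks[0]
        px = monolayer_scene.stack.pixel_size_um
        site = np.array([track.diapedesis_site[1],
                         track.diapedesis_site[0]]) / px
        # independent bookkeeping: along-junction distance from the first
        # on-junction position to the site
        costs = np.where(monolayer_scene.junction_mask, 1.0, np.inf)
        pos_px = track.positions_um[:, ::-1] / px
        jpix = np.argwhere(monolayer_scene.junction_mask)
        d_first = np.sqrt(((jpix - pos_px[:, None]) ** 2).sum(2)).min(1)
        first = np.flatnonzero(d_first <= 1.0)[0]
        start = jpix[np.argmin(((jpix - pos_px[first]) ** 2).sum(1))]
        mcp = MCP_Geometric(costs)
        dist, _ = mcp.find_costs([tuple(start)])
        got = dist[tuple(np.round(site).astype(int))] * px
        assert got > 10.0

    def test_events_lie_on_junction(self, monolayer_scene):
        ts = synthetic.make_tracks(monolayer_scene,
                                   [{"kind": "immediate", "at_jmp": True},
                                    {"kind": "lateral"}], seed=2)
        px = monolayer_scene.stack.pixel_size_um
        for ev in ts.truth_events:
            r = int(round(ev.site[1] / px))
            c = int(round(ev.site[0] / px))
            assert monolayer_scene.junction_mask[r, c]

    def test_off_junction_site_rejected(self, monolayer_scene):
        labels = monolayer_scene.cell_labels
        interior = np.argwhere(labels == labels[10, 10])
        deep = interior[len(interior) // 2]
        px = monolayer_scene.stack.pixel_size_um
        from scipy import ndimage
        dist = ndimage.distance_transform_edt(~monolayer_scene.junction_mask)
        far = np.unravel_index(np.argmax(dist), dist.shape)
        with pytest.raises(ParameterError, match="off the junction"):
            synthetic.make_tracks(
                monolayer_scene,
                [{"kind": "immediate",
                  "site_um": (far[1] * px, far[0] * px)}], seed=0)

    def test_determinism(self, monolayer_scene):
        spec = [{"kind": "lateral"}, {"kind": "turn"}]
        a = synthetic.make_tracks(monolayer_scene, spec, seed=8)
        b = synthetic.make_tracks(monolayer_scene, spec, seed=8)
        for ta, tb in zip(a.tracks, b.tracks):
            np.testing.assert_array_equal(ta.positions_um, tb.positions_um)
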