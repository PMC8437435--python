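"""3D surfacing and protrusion morphometry against analytic geometry and a
brute-force neighborhood oracle."""

import networkx as nx
import numpy as np
import pytest
import trimesh

from jmpkit import meshops, surface, synthetic
from jmpkit.containers import (DegenerateInputError, ParameterError,
                               VolumeFrame, VolumeSeries)


def digitized_sphere(r_um=5.0, voxel=0.2, n=64):
    c = (n // 2) * voxel
    zz, yy, xx = np.mgrid[:n, :n, :n] * voxel
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r_um ** 2


class TestValidMask:
    def test_wedge_excluded_exactly(self):
        sc = synthetic.make_membrane_volume(
            [{"kind": "hemisphere", "center_yx_um": (6.0, 9.0),
              "radius_um": 2.0}],
            voxel_size_um=(0.2, 0.2, 0.2), shape=(24, 64, 96),
            pad_style="deskew", seed=0)
        mask = surface.compute_valid_mask(sc.volume)
        np.testing.assert_array_equal(mask, sc.padding_mask)

    def test_fully_nonzero_volume_is_all_true(self):
        vol = VolumeFrame(np.ones((8, 8, 8)), (0.2, 0.2, 0.2))
        assert surface.compute_valid_mask(vol).all()

    def test_slice_holes_filled(self):
        data = np.ones((4, 16, 16))
        data[2, 6:10, 6:10] = 0.0  # internal hole in one slice
        vol = VolumeFrame(data, (0.2, 0.2, 0.2))
        assert surface.compute_valid_mask(vol).all()

    def test_union_over_first_frames(self):
        a = VolumeFrame(np.zeros((4, 8, 8)), (0.2, 0.2, 0.2))
        b = VolumeFrame(np.ones((4, 8, 8)), (0.2, 0.2, 0.2))
        assert surface.compute_valid_mask(VolumeSeries([a, b])).all()
        with pytest.raises(DegenerateInputError):
            surface.compute_valid_mask(a)


class TestSegmentMembrane:
    def test_bimodal_recovers_truth_shell(self):
        sc = synthetic.make_membrane_volume(
            [{"kind": "hemisphere", "center_yx_um": (8.0, 8.0),
              "radius_um": 3.0}],
            voxel_size_um=(0.2, 0.2, 0.2), shape=(32, 80, 80),
            noise_sd=2.0, seed=4)
        truth = synthetic.make_membrane_volume(
            [{"kind": "hemisphere", "center_yx_um": (8.0, 8.0),
              "radius_um": 3.0}],
            voxel_size_um=(0.2, 0.2, 0.2), shape=(32, 80, 80),
            noise_sd=0.0, seed=4).volume.data > 50.0
        seg = surface.segment_membrane(sc.volume, sc.padding_mask)
        sym_diff = (seg ^ truth).sum() / truth.sum()
        assert sym_diff < 0.01

    def test_small_speck_removed(self):
        data = np.full((40, 60, 60), 10.0)
        data[10:13] = 100.0
        data[30, 5, 5] = 100.0  # 1 voxel, far below 0.1% of the mask
        seg = surface.segment_membrane(VolumeFrame(data, (0.2,) * 3),
                                       np.ones_like(data, bool))
        assert not seg[30, 5, 5]
        assert seg[11].all()

    def test_large_hull_component_dropped(self):
        # a big hollow box: its convex hull spans most of the mask volume
        data = np.full((40, 40, 40), 10.0)
        shell = np.zeros((40, 40, 40), bool)
        shell[2:38, 2:38, 2:38] = True
        shell[4:36, 4:36, 4:36] = False
        data[shell] = 100.0
        seg = surface.segment_membrane(VolumeFrame(data, (0.2,) * 3),
                                       np.ones_like(data, bool))
        assert not seg.any()

    def test_constant_intensity_rejected(self):
        vol = VolumeFrame(np.full((8, 8, 8), 5.0), (0.2,) * 3)
        with pytest.raises(DegenerateInputError, match="degenerate"):
            surface.segment_membrane(vol, np.ones((8, 8, 8), bool))


class TestExtractSurface:
    def test_sphere_volume_within_three_percent(self):
        mesh = surface.extract_surface(digitized_sphere(), (0.2, 0.2, 0.2))
        assert mesh.is_watertight
        assert abs(mesh.volume) == pytest.approx(4 / 3 * np.pi * 125,
                                                 rel=0.03)

    def test_slab_sheet_areas(self):
        binary = np.zeros((24, 64, 64), bool)
        binary[10:13] = True
        mesh = surface.extract_surface(binary, (0.2, 0.2, 0.2))
        parts = mesh.split(only_watertight=False)
        # slab spanning the full extent: open top and bottom sheets
        face_area = 63 * 0.2 * 63 * 0.2
        areas = sorted(p.area for p in parts)[-2:]
        for a in areas:
            assert a == pytest.approx(face_area, rel=0.05)

    def test_anisotropic_voxels_rescaled_to_physical(self):
        # a sphere sampled on 0.211 x 0.104 x 0.104 um voxels must come out
        # spherical in physical units (unscaled it would be 2:1 elongated)
        n = 112
        voxel = (0.211, 0.104, 0.104)
        c = np.array([n // 2 * v for v in voxel])
        zz, yy, xx = np.mgrid[:n, :n, :n].astype(float)
        pos = np.stack([zz * voxel[0], yy * voxel[1], xx * voxel[2]])
        binary = ((pos[0] - c[0]) ** 2 + (pos[1] - c[1]) ** 2 +
                  (pos[2] - c[2]) ** 2) <= 5.0 ** 2
        mesh = surface.extract_surface(binary, voxel)
        centered = np.asarray(mesh.vertices) - np.asarray(mesh.vertices).mean(axis=0)
        extents = centered.max(axis=0) - centered.min(axis=0)
        assert extents.max() / extents.min() < 1.03

    def test_empty_volume_rejected(self):
        with pytest.raises(DegenerateInputError):
            surface.extract_surface(np.zeros((8, 8, 8), bool), (0.2,) * 3)


class TestSmoothing:
    def test_zero_iterations_is_identity(self):
        plane = meshops.make_grid_plane_mesh(8, 8)
        sm = meshops.smooth_mesh(plane, 0)
        np.testing.assert_array_equal(sm.vertices, plane.vertices)

    def test_plane_interior_is_fixed_point(self):
        plane = meshops.make_grid_plane_mesh(16, 16)
        sm = meshops.smooth_mesh(plane, 1)
        interior = np.all(
            (plane.vertices[:, 1:] > 0.5) & (plane.vertices[:, 1:] < 14.5),
            axis=1)
        np.testing.assert_allclose(sm.vertices[interior],
                                   plane.vertices[interior], atol=1e-12)

    def test_spike_height_strictly_decreases(self):
        plane = meshops.make_grid_plane_mesh(9, 9)
        v = plane.vertices.copy()
        spike = 4 * 9 + 4
        v[spike, 0] = 2.0
        mesh = trimesh.Trimesh(vertices=v, faces=plane.faces, process=False)
        heights = [2.0]
        for it in (1, 2, 3):
            sm = meshops.smooth_mesh(mesh, it)
            heights.append(sm.vertices[:, 0].max())
        assert all(b < a for a, b in zip(heights, heights[1:]))


class TestSurfaceVariation:
    def test_exact_plane_is_zero(self):
        plane = meshops.make_grid_plane_mesh(20, 20)
        vals, _ = surface.compute_surface_variation(plane, 5)
        np.testing.assert_allclose(vals, 0.0, atol=1e-12)

    def test_bump_dominates_plane(self, hemisphere_mesh):
        sm = meshops.smooth_mesh(hemisphere_mesh, 4)
        vals, _ = surface.compute_surface_variation(sm, 20)
        z = sm.vertices[:, 0]
        top = z > z[z < z.mean()].max() + 0.3  # bump vertices
        plane_med = np.median(vals[~top])
        assert vals[top].max() > 10 * max(plane_med, 1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        plane = meshops.make_grid_plane_mesh(14, 15)  # 210 vertices
        v = plane.vertices.copy()
        v[:, 0] += rng.normal(0, 0.4, len(v))
        mesh = trimesh.Trimesh(vertices=v, faces=plane.faces, process=False)
        vals, _ = surface.compute_surface_variation(mesh, 4)
        normals = np.asarray(mesh.vertex_normals)
        normals = normals / np.linalg.norm(normals, axis=1)[:, None]
        g = nx.Graph(mesh.edges_unique.tolist())
        for i in range(len(v)):
            nbrs = list(nx.single_source_shortest_path_length(g, i, cutoff=4))
            d = mesh.vertices[nbrs] - mesh.vertices[i]
            h = d @ normals[i]
            r2 = (d ** 2).sum(axis=1) - h ** 2
            expected = np.pi * r2.max() * (h.max() - h.min())
            assert vals[i] == pytest.approx(expected, abs=1e-9)

    def test_boundary_vertices_flagged(self):
        plane = meshops.make_grid_plane_mesh(10, 10)
        _, flags = surface.compute_surface_variation(plane, 2)
        border = np.any((plane.vertices[:, 1:] < 0.5) |
                        (plane.vertices[:, 1:] > 8.5), axis=1)
        assert flags[border].all()

    def test_scale_equivariance_k2(self, hemisphere_mesh):
        sm = meshops.smooth_mesh(hemisphere_mesh, 4)
        vals, _ = surface.compute_surface_variation(sm, 10)
        big = trimesh.Trimesh(vertices=2.0 * sm.vertices,
                              faces=sm.faces, process=False)
        vals2, _ = surface.compute_surface_variation(big, 10)
        nz = vals > 1e-9
        np.testing.assert_allclose(vals2[nz] / vals[nz], 8.0, atol=1e-6)


class TestLabelRefine:
    def test_all_below_threshold_empty(self):
        plane = meshops.make_grid_plane_mesh(12, 12)
        labels = surface.label_and_refine(plane, np.zeros(144))
        assert not labels.any()

    def test_isolated_vertex_removed_by_opening(self):
        plane = meshops.make_grid_plane_mesh(12, 12)
        var = np.zeros(144)
        var[6 * 12 + 6] = 100.0
        labels = surface.label_and_refine(plane, var)
        assert not labels.any()

    def test_annulus_hole_filled(self):
        plane = meshops.make_grid_plane_mesh(30, 30)
        center = plane.vertices.mean(axis=0)
        r = np.linalg.norm(plane.vertices - center, axis=1)
        var = np.where((r > 4) & (r < 10), 100.0, 0.0)
        params = surface.VariationParams(close_ring=1)
        labels = surface.label_and_refine(plane, var, params)
        assert labels[r <= 4].all()

    def test_nuclear_mask_forced_off(self):
        plane = meshops.make_grid_plane_mesh(12, 12)
        var = np.full(144, 100.0)
        nuc = np.zeros(144, bool)
        nuc[:72] = True
        labels = surface.label_and_refine(plane, var, nuclear_mask=nuc)
        assert not labels[nuc].any() and labels[~nuc].any()

    def test_raising_threshold_never_adds_labels(self, hemisphere_mesh):
        sm = meshops.smooth_mesh(hemisphere_mesh, 4)
        vals, _ = surface.compute_surface_variation(sm, 10)
        counts = []
        for thr in (1.0, 3.5, 10.0, 50.0):
            p = surface.VariationParams(variation_threshold=thr)
            counts.append(surface.label_and_refine(sm, vals, p).sum())
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestExtractRegions:
    def test_exact_labels_recover_hemisphere_morphometry(self,
                                                         hemisphere_scene,
                                                         hemisphere_mesh):
        sc = hemisphere_scene
        tr = sc.truth_protrusions[0]
        # on the raw mesh the sheet top is exactly planar, so a height cut
        # labels the protrusion vertices and nothing else
        labels = hemisphere_mesh.vertices[:, 0] > sc.sheet_top_um + 0.05
        regions = surface.extract_regions(hemisphere_mesh, labels)
        assert len(regions) == 1
        reg = regions[0]
        assert reg.submesh.is_watertight
        assert reg.volume_um3 == pytest.approx(tr.analytic_volume_um3,
                                               rel=0.05)
        assert reg.base_area_um2 == pytest.approx(tr.analytic_base_area_um2,
                                                  rel=0.05)

    def test_two_bumps_two_regions(self):
        sc = synthetic.make_membrane_volume(
            [{"kind": "hemisphere", "center_yx_um": (8.0, 8.0),
              "radius_um": 2.5},
             {"kind": "hemisphere", "center_yx_um": (24.0, 24.0),
              "radius_um": 3.0}],
            voxel_size_um=(0.2, 0.2, 0.2), shape=(40, 160, 160), seed=0)
        regions, *_ = surface.detect_jmp_regions(sc.volume)
        assert len(regions) == 2

    def test_no_labels_no_regions(self, hemisphere_mesh):
        assert surface.extract_regions(
            hemisphere_mesh, np.zeros(len(hemisphere_mesh.vertices),
                                      bool)) == []

    def test_region_volume_scale_equivariance(self, hemisphere_scene,
                                              hemisphere_mesh):
        sc = hemisphere_scene
        labels = hemisphere_mesh.vertices[:, 0] > sc.sheet_top_um + 0.05
        r1 = surface.extract_regions(hemisphere_mesh, labels)[0]
        big = trimesh.Trimesh(vertices=2 * hemisphere_mesh.vertices,
                              faces=hemisphere_mesh.faces, process=False)
        r2 = surface.extract_regions(big, labels)[0]
        assert r2.volume_um3 / r1.volume_um3 == pytest.approx(8.0, abs=1e-6)


class TestPipeline:
    def test_detected_region_count_and_volume(self, hemisphere_scene):
        regions, mesh, variation, labels = surface.detect_jmp_regions(
            hemisphere_scene.volume)
        assert len(regions) == 1
        tr = hemisphere_scene.truth_protrusions[0]
        assert regions[0].volume_um3 == pytest.approx(tr.analytic_volume_um3,
                                                      rel=0.10)
        assert regions[0].submesh.is_watertight
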