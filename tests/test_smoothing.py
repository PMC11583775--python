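import numpy as np
import pytest

from printqa.ct import HUVolume
from printqa.mesh import TriMesh, mesh_volume
from printqa.smoothing import (
    SmoothingSpec,
    dee_metrics,
    smooth_mesh_factor,
    smooth_volume_median,
)

from conftest import icosphere


class TestSmoothingSpec:
    @pytest.mark.parametrize(
        "profile,level,expected",
        [
            ("slicer_like", "low", 1.0),
            ("slicer_like", "medium", 3.0),
            ("slicer_like", "high", 5.0),
            ("d2p_like", "low", 1.0),
        ],
    )
    def test_volume_kernel_mapping(self, profile, level, expected):
        spec = SmoothingSpec(profile, level)
        assert spec.method == "volume"
        assert spec.median_kernel_mm == expected

    @pytest.mark.parametrize(
        "level,expected", [("low", 0.66), ("medium", 1.33), ("high", 2.00)]
    )
    def test_mesh_factor_mapping(self, level, expected):
        spec = SmoothingSpec("brainlab_like", level)
        assert spec.method == "mesh"
        assert spec.factor == expected

    @pytest.mark.parametrize("level", ["medium", "high"])
    def test_d2p_only_low(self, level):
        with pytest.raises(ValueError, match="low"):
            SmoothingSpec("d2p_like", level)


class TestVolumeMedian:
    def test_uniform_volume_unchanged(self):
        vol = HUVolume(np.full((6, 6, 6), 100.0), (1, 1, 1), (0, 0, 0))
        out = smooth_volume_median(vol, 3.0)
        assert np.array_equal(out.voxels, vol.voxels)

    def test_single_voxel_island_removed(self):
        voxels = np.full((7, 7, 7), -1000.0)
        voxels[3, 3, 3] = 200.0
        vol = HUVolume(voxels, (1, 1, 1), (0, 0, 0))
        out = smooth_volume_median(vol, 3.0)
        assert out.voxels.max() == -1000.0

    def test_subvoxel_kernel_is_identity_with_warning(self, caplog):
        vol = HUVolume(np.arange(27.0).reshape(3, 3, 3), (2, 2, 2), (0, 0, 0))
        with caplog.at_level("WARNING"):
            out = smooth_volume_median(vol, 0.5)
        assert np.array_equal(out.voxels, vol.voxels)
        assert any("identity" in r.message for r in caplog.records)

    def test_larger_kernel_shrinks_more(self, runner):
        """Median smoothing erodes convex detail; 5 mm kernel more than 1 mm."""
        from printqa.segmentation import segment_threshold

        vol = runner.ct_volume(1.5, "bone")
        base = segment_threshold(vol, -600.0, island_policy="largest_component")
        deltas = {}
        for k in (1.0, 5.0):
            sm = smooth_volume_median(vol, k)
            seg = segment_threshold(sm, -600.0, island_policy="largest_component")
            deltas[k] = abs(
                100.0
                * (seg.metrics.volume_mm3 - base.metrics.volume_mm3)
                / base.metrics.volume_mm3
            )
        assert deltas[5.0] > deltas[1.0]


class TestMeshFactor:
    def test_factor_zero_identity(self):
        sph = icosphere(10.0, subdivisions=2)
        out = smooth_mesh_factor(sph, 0.0)
        assert np.array_equal(out.vertices, sph.vertices)

    def test_sphere_volume_non_increasing_with_factor(self):
        sph = icosphere(10.0, subdivisions=3)
        vols = [
            mesh_volume(smooth_mesh_factor(sph, f)) for f in (0.0, 0.66, 1.33, 2.0)
        ]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_triangle_count_and_watertightness_preserved(self):
        sph = icosphere(8.0, subdivisions=2)
        out = smooth_mesh_factor(sph, 1.33)
        assert out.n_triangles == sph.n_triangles
        assert out.is_watertight

    def test_edges_move_most_on_cube(self):
        import trimesh.creation

        cube = TriMesh.from_trimesh(
            trimesh.creation.box(extents=[20.0] * 3).subdivide().subdivide().subdivide()
        )
        out = smooth_mesh_factor(cube, 2.0)
        disp = np.linalg.norm(out.vertices - cube.vertices, axis=1)
        on_edge = (np.isclose(np.abs(cube.vertices), 10.0, atol=1e-9).sum(axis=1)) >= 2
        face_center = np.linalg.norm(cube.vertices, ord=np.inf, axis=1) <= 10.0
        interior = ~on_edge & (
            np.isclose(np.abs(cube.vertices), 10.0, atol=1e-9).sum(axis=1) == 1
        )
        # strongest movement concentrates at edges/corners
        assert disp[on_edge].mean() > 3.0 * disp[interior].mean()


class TestLevelOrdering:
    def test_mean_more_negative_and_spread_wider_with_level(self, runner):
        """Increasing the smoothing level shifts the mean deviation further
        negative (shrinkage) and widens the 6-sigma interval, on the same
        segmentation the editing study uses."""
        from printqa.segmentation import segment_threshold

        vol = runner.ct_volume(1.5, "bone")
        seg = segment_threshold(vol, -600.0, island_policy="largest_component")
        means, spreads = [], []
        for level in ("low", "medium", "high"):
            spec = SmoothingSpec("brainlab_like", level)
            m = dee_metrics(
                seg.mesh, smooth_mesh_factor(seg.mesh, spec.factor),
                n_samples=6000, seed=0,
            )
            means.append(m.deviation.mean_dS)
            spreads.append(m.deviation.six_sigma_dS)
        assert means[0] > means[1] > means[2]  # increasingly negative
        assert spreads[0] < spreads[1] < spreads[2]


class TestDEEMetrics:
    def test_identity_all_zero(self):
        sph = icosphere(10.0, subdivisions=3)
        m = dee_metrics(sph, sph.copy(), n_samples=2000, seed=0)
        assert m.dFi_rel_pct == 0.0
        assert m.dV_rel_pct == 0.0
        assert m.deviation.mean_dS == pytest.approx(0.0, abs=1e-12)
        assert m.deviation.six_sigma_dS == pytest.approx(0.0, abs=1e-12)

    def test_halving_triangles_halves_file_size(self):
        # two disjoint spheres vs. one: triangle count exactly halves
        a = icosphere(10.0, subdivisions=3)
        b = TriMesh(a.vertices + [30.0, 0, 0], a.faces)
        both = TriMesh(
            np.vstack([a.vertices, b.vertices]),
            np.vstack([a.faces, b.faces + len(a.vertices)]),
        )
        m = dee_metrics(both, a, n_samples=2000, seed=0, compute_deviation=False)
        # the 84-byte header keeps the proxy from exactly -50%
        assert m.dFi_rel_pct == pytest.approx(-50.0, abs=0.05)
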