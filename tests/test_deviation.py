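import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from printqa.deviation import (
    DeviationStats,
    export_ascii,
    import_ascii,
    sample_surface,
    signed_surface_deviation,
)
from printqa.errors import NotWatertightError
from printqa.geometry import SurfaceIndex
from printqa.mesh import TriMesh

from conftest import icosphere


class TestSignedDeviation:
    def test_identity_zero(self):
        sph = icosphere(10.0, subdivisions=3)
        stats = signed_surface_deviation(sph, sph.copy(), n_samples=5000, seed=0)
        assert stats.mean_dS == pytest.approx(0.0, abs=1e-12)
        assert stats.six_sigma_dS == pytest.approx(0.0, abs=1e-12)

    def test_offset_sphere_mean(self):
        # analytic oracle: concentric spheres 10.1 vs 10.0 -> mean +0.1 mm
        analyzed = icosphere(10.1, subdivisions=4)
        reference = icosphere(10.0, subdivisions=4)
        stats = signed_surface_deviation(analyzed, reference, n_samples=20_000, seed=0)
        assert stats.mean_dS == pytest.approx(0.100, abs=0.005)

    def test_reverse_direction_same_sign_convention(self):
        # larger analyzed sphere: positive mean in both directions
        analyzed = icosphere(10.1, subdivisions=3)
        reference = icosphere(10.0, subdivisions=3)
        fwd = signed_surface_deviation(analyzed, reference, n_samples=4000, seed=0)
        rev = signed_surface_deviation(
            analyzed, reference, n_samples=4000, seed=0,
            direction="reference_to_analyzed",
        )
        assert fwd.mean_dS == pytest.approx(0.1, abs=0.01)
        assert rev.mean_dS == pytest.approx(0.1, abs=0.01)

    def test_shrunk_object_negative_mean(self, benchy):
        centroid = benchy.vertices.mean(axis=0)
        shrunk = TriMesh(
            centroid + 0.99 * (benchy.vertices - centroid), benchy.faces
        )
        stats = signed_surface_deviation(shrunk, benchy, n_samples=8000, seed=0)
        assert stats.mean_dS < 0.0

    def test_nested_spheres_sign_flip_on_swap(self):
        inner = icosphere(9.5, subdivisions=3)
        outer = icosphere(10.0, subdivisions=3)
        a = signed_surface_deviation(inner, outer, n_samples=4000, seed=0)
        b = signed_surface_deviation(outer, inner, n_samples=4000, seed=0)
        assert a.mean_dS < 0.0 < b.mean_dS
        assert a.mean_dS == pytest.approx(-b.mean_dS, abs=0.01)

    def test_rigid_invariance(self, benchy):
        shrunk = TriMesh(
            benchy.vertices.mean(0) + 0.995 * (benchy.vertices - benchy.vertices.mean(0)),
            benchy.faces,
        )
        base = signed_surface_deviation(shrunk, benchy, n_samples=5000, seed=3)
        rot = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        t = np.array([30.0, -12.0, 7.0])
        moved = signed_surface_deviation(
            shrunk.transformed(rot, t),
            benchy.transformed(rot, t),
            n_samples=5000,
            seed=3,
        )
        assert moved.mean_dS == pytest.approx(base.mean_dS, abs=1e-6)

    def test_internal_islands_drive_mean_negative(self):
        # analyzed = reference shell plus small islands deep inside it
        reference = icosphere(10.0, subdivisions=3)
        island = icosphere(1.0, subdivisions=1)
        analyzed = TriMesh(
            np.vstack([reference.vertices, island.vertices + [3.0, 0, 0],
                       island.vertices - [3.0, 0, 0]]),
            np.vstack(
                [
                    reference.faces,
                    island.faces + len(reference.vertices),
                    island.faces + len(reference.vertices) + len(island.vertices),
                ]
            ),
        )
        clean = signed_surface_deviation(reference, reference, n_samples=6000, seed=0)
        with_islands = signed_surface_deviation(
            analyzed, reference, n_samples=6000, seed=0
        )
        assert with_islands.mean_dS < clean.mean_dS - 0.1

    def test_non_watertight_reference_rejected(self):
        sph = icosphere(10.0, subdivisions=2)
        open_ref = TriMesh(sph.vertices, sph.faces[:-1])
        with pytest.raises(NotWatertightError):
            signed_surface_deviation(sph, open_ref, n_samples=500, seed=0)

    def test_vertex_sampling_below_budget(self):
        sph = icosphere(10.0, subdivisions=2)  # 162 vertices
        stats = signed_surface_deviation(sph, sph, n_samples=10_000, seed=0)
        assert stats.n_samples == len(sph.vertices)

    def test_area_weighted_sampling_seeded(self, benchy):
        a = sample_surface(benchy, 1000, seed=5)
        b = sample_surface(benchy, 1000, seed=5)
        c = sample_surface(benchy, 1000, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestSixSigmaCoverage:
    def test_normal_samples_within_3_sigma(self):
        """~99.73% of a large normal sample falls inside [mean-3s, mean+3s]."""
        rng = np.random.default_rng(123)
        samples = rng.normal(0.02, 0.15, size=1_000_000)
        stats = DeviationStats.from_samples(samples, np.zeros((len(samples), 3)))
        lo = stats.mean_dS - 3.0 * stats.sigma
        hi = stats.mean_dS + 3.0 * stats.sigma
        frac = np.mean((samples >= lo) & (samples <= hi))
        assert frac == pytest.approx(0.9973, abs=0.0005)
        assert stats.six_sigma_dS == pytest.approx(6.0 * stats.sigma)


class TestAsciiExport:
    def _stats(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return DeviationStats.from_samples(
            rng.normal(0, 0.2, n), rng.uniform(-10, 10, (n, 3))
        )

    def test_round_trip_mean(self, tmp_path):
        stats = self._stats(500)
        path = tmp_path / "dev.txt"
        export_ascii(stats, path)
        back = import_ascii(path)
        assert back.n_samples == 500
        assert back.mean_dS == pytest.approx(stats.mean_dS, abs=1e-6)
        assert back.six_sigma_dS == pytest.approx(stats.six_sigma_dS, abs=1e-5)

    def test_line_count_is_samples_plus_header(self, tmp_path):
        stats = self._stats(73)
        path = tmp_path / "dev.txt"
        export_ascii(stats, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 73 + 5

    def test_empty_stats_header_only(self, tmp_path):
        stats = DeviationStats.from_samples(np.array([]), np.zeros((0, 3)))
        path = tmp_path / "empty.txt"
        export_ascii(stats, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 5
        assert "n_samples 0" in lines[1]


class TestSurfaceIndexInside:
    def test_sphere_inside_classification(self):
        sph = icosphere(10.0, subdivisions=3)
        idx = SurfaceIndex(sph)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-12, 12, size=(5000, 3))
        r = np.linalg.norm(pts, axis=1)
        clear = np.abs(r - 10.0) > 0.1  # away from the polyhedral shell
        inside = idx.contains(pts)
        assert np.array_equal(inside[clear], r[clear] < 10.0)
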