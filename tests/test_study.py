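import numpy as np
import pandas as pd
import pytest

from printqa.study import StudyConfig, StudyRunner


@pytest.fixture(scope="module")
def tiny_config():
    """Reduced grid for fast pipeline-behaviour tests (coarse phantom and
    in-plane spacing; the default study conditions are exercised in the
    acceptance suite)."""
    return StudyConfig(
        phantom_complexity=1,
        in_plane_spacing_mm=1.0,
        slice_thicknesses_mm=[1.5, 5.0],
        kernels=["soft", "bone"],
        thresholds_hu=[-800.0, -400.0, 0.0, 200.0],
        profiles=["slicer_like", "d2p_like"],
        dee_slice_thicknesses_mm=[1.5, 5.0],
        deviation_samples=4000,
        print_replicates=2,
    )


@pytest.fixture(scope="module")
def tiny_tables(tiny_config):
    runner = StudyRunner(tiny_config)
    return {
        "runner": runner,
        "sege": runner.run_sege_sweep(),
        "dee": runner.run_dee_study(),
        "pre": runner.run_pre_study(),
    }


class TestConfig:
    def test_yaml_round_trip_lossless(self, tmp_path, tiny_config):
        path = tmp_path / "cfg.yaml"
        tiny_config.to_yaml(path)
        back = StudyConfig.from_yaml(path)
        assert back == tiny_config

    def test_default_grid_sizes(self):
        cfg = StudyConfig()
        assert len(cfg.slice_thicknesses_mm) == 5
        assert len(cfg.kernels) == 2
        assert len(cfg.thresholds_hu) == 7
        assert len(cfg.profiles) == 3


class TestSegeSweep:
    def test_cell_count(self, tiny_config, tiny_tables):
        n_expected = (
            len(tiny_config.profiles)
            * len(tiny_config.kernels)
            * len(tiny_config.slice_thicknesses_mm)
            * len(tiny_config.thresholds_hu)
        )
        assert len(tiny_tables["sege"]) == n_expected

    def test_errors_recorded_not_raised(self, tiny_tables):
        sege = tiny_tables["sege"]
        assert "error" in sege.columns  # per-cell capture; the sweep finished

    def test_excluded_cells_cluster_at_high_thresholds(self, tiny_tables):
        sege = tiny_tables["sege"]
        excluded = sege[~sege.included]
        included = sege[sege.included]
        assert len(excluded) > 0
        assert excluded.threshold_hu.min() >= included.threshold_hu.median()

    def test_deviation_only_for_included(self, tiny_tables):
        sege = tiny_tables["sege"]
        assert sege.loc[~sege.included, "mean_dS_mm"].isna().all()
        assert sege.loc[sege.included, "mean_dS_mm"].notna().all()

    def test_volume_monotone_in_threshold_per_cell(self, tiny_tables):
        sege = tiny_tables["sege"].fillna({"volume_mm3": 0.0})
        for _, grp in sege.groupby(["software_profile", "kernel", "slice_thickness_mm"]):
            v = grp.sort_values("threshold_hu").volume_mm3.to_numpy()
            # noise can wiggle individual cells a hair; the sweep trend holds
            assert v[0] > v[-1]
            assert (np.diff(v) <= 0.02 * v[0]).all()


class TestDeeStudy:
    def test_row_count(self, tiny_config, tiny_tables):
        # [slicer (3 levels) + d2p (1 level)] x two slice thicknesses
        assert len(tiny_tables["dee"]) == 8

    def test_levels_shrink_volume(self, tiny_tables):
        dee = tiny_tables["dee"]
        slicer = dee[
            (dee.software_profile == "slicer_like") & (dee.slice_thickness_mm == 1.5)
        ].set_index("level")
        assert abs(slicer.loc["high", "dV_rel_pct"]) > abs(slicer.loc["low", "dV_rel_pct"])

    def test_slice_thickness_secondary_to_level(self, tiny_tables):
        """The smoothing level, not the source slice thickness, dominates the
        mean deviation of the editing step."""
        slicer = tiny_tables["dee"][
            tiny_tables["dee"].software_profile == "slicer_like"
        ]
        by = slicer.pivot_table(
            index="level", columns="slice_thickness_mm", values="mean_dS_mm"
        )
        across_thickness = by.max(axis=1) - by.min(axis=1)
        between_levels = by.mean(axis=1).max() - by.mean(axis=1).min()
        assert across_thickness.max() < between_levels

    def test_d2p_low_has_only_small_effect(self, tiny_tables):
        """The strongest (only) available d2p-like level stays milder than
        high-level smoothing in the other profiles."""
        dee = tiny_tables["dee"]
        d2p = dee[dee.software_profile == "d2p_like"]
        strong = dee[(dee.software_profile == "slicer_like") & (dee.level == "high")]
        assert d2p.dV_rel_pct.abs().max() < strong.dV_rel_pct.abs().min()


class TestPreStudy:
    def test_replicates_distinct(self, tiny_tables):
        pre = tiny_tables["pre"]
        warped = pre[pre.printer == "warped"]
        assert warped.warp_amplitude_mm.nunique() == len(warped)
        assert pre.groupby("printer").size().eq(2).all()

    def test_accurate_vs_warped_spread(self, tiny_tables):
        pre = tiny_tables["pre"].groupby("printer").six_sigma_dS_mm.mean()
        assert pre["warped"] > pre["accurate"]


class TestDeterminism:
    def test_rerun_reproduces_tables(self, tiny_config, tiny_tables):
        runner2 = StudyRunner(tiny_config)
        sege2 = runner2.run_sege_sweep()
        pd.testing.assert_frame_equal(tiny_tables["sege"], sege2)
        pre2 = runner2.run_pre_study()
        pd.testing.assert_frame_equal(tiny_tables["pre"], pre2)


class TestOutputs:
    def test_save_outputs_and_manifest(self, tmp_path, tiny_config, tiny_tables):
        runner = tiny_tables["runner"]
        runner.config.output_dir = str(tmp_path / "out")
        runner.save_outputs(sege=tiny_tables["sege"], pre=tiny_tables["pre"])
        assert (tmp_path / "out" / "sege_sweep.csv").exists()
        assert (tmp_path / "out" / "run_manifest.json").exists()
        import json

        manifest = json.loads((tmp_path / "out" / "run_manifest.json").read_text())
        assert manifest["printqa_version"]
        assert manifest["seeds"]  # every random draw is logged
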