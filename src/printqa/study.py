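"""Config-driven orchestration of the full error-propagation study.

Reproduces the study design end to end on synthetic data: a segmentation
sweep over (software profile x protocol x threshold), the digital-editing
study over (profile x level x slice thickness), the printing study over
(printer spec x replicate), and the total-error propagation for an optimal
and a worst-case parameter configuration.

"Software" is modelled as three generic profiles combining a segmentation
parameterisation with a smoothing parameterisation; no vendor product is
emulated bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ct import CTProtocol, HUVolume, compute_occupancy, simulate_ct
from .deviation import signed_surface_deviation
from .error_model import PartialError, TotalError, format_report, propagate_total
from .errors import PrintQAError
from .mesh import TriMesh, mesh_volume
from .phantom import generate_benchy
from .printing import PrintSpec, simulate_print
from .segmentation import (
    DEFAULT_CUTOFF_MM3,
    DEFAULT_THRESHOLDS_HU,
    SegmentationResult,
    passes_cutoff,
    segment_threshold,
)
from .smoothing import SmoothingSpec, dee_metrics, smooth_mesh_factor, smooth_volume_median

log = logging.getLogger(__name__)

# segmentation flavour per software profile: the volume-median profiles use
# sub-voxel iso-surfacing; the d2p-like profile surfaces the binary mask
_PROFILE_SEG_METHOD = {
    "slicer_like": "subvoxel",
    "brainlab_like": "subvoxel",
    "d2p_like": "binary",
}


@dataclass
class StudyConfig:
    """Everything one study run depends on; round-trips through YAML."""

    phantom_complexity: int = 2
    phantom_seed: int = 42
    slice_thicknesses_mm: List[float] = field(
        default_factory=lambda: [0.4, 0.6, 1.5, 3.0, 5.0]
    )
    kernels: List[str] = field(default_factory=lambda: ["soft", "bone"])
    in_plane_spacing_mm: float = 0.5
    thresholds_hu: List[float] = field(
        default_factory=lambda: list(DEFAULT_THRESHOLDS_HU)
    )
    profiles: List[str] = field(
        default_factory=lambda: ["slicer_like", "brainlab_like", "d2p_like"]
    )
    island_policy: str = "keep_all"
    cutoff_mm3: float = DEFAULT_CUTOFF_MM3
    # digital-editing study inputs (bone-kernel scans, one low threshold)
    dee_slice_thicknesses_mm: List[float] = field(
        default_factory=lambda: [0.4, 1.5, 5.0]
    )
    dee_threshold_hu: float = -600.0
    dee_kernel: str = "bone"
    # printing study: spec name -> mean warp amplitude; five replicates each,
    # amplitude jittered per replicate to mimic bed-position effects
    printer_amplitudes_mm: Dict[str, float] = field(
        default_factory=lambda: {"accurate": 0.1, "warped": 1.2}
    )
    print_replicates: int = 5
    printer_amplitude_jitter: float = 0.15  # relative sd of the seeded draw
    layer_height_mm: float = 0.3
    # deviation engine
    deviation_samples: int = 20_000
    compute_deviation: bool = True
    base_seed: int = 1
    output_dir: Optional[str] = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


class StudyRunner:
    """Caches the phantom and CT volumes across the study stages."""

    def __init__(self, config: StudyConfig):
        self.config = config
        self.phantom = generate_benchy(
            config.phantom_complexity, config.phantom_seed
        )
        self.phantom_volume = mesh_volume(self.phantom)
        self._grids: Dict[float, Tuple] = {}
        self._occupancy: Dict[float, np.ndarray] = {}
        self._volumes: Dict[Tuple[float, str], HUVolume] = {}
        self.manifest: Dict = {
            "printqa_version": __version__,
            "config": dataclasses.asdict(config),
            "phantom_volume_mm3": self.phantom_volume,
            "seeds": {},
        }

    # -- shared CT machinery ------------------------------------------------
    def _grid_for(self, dz: float):
        """One grid per slice thickness, sized for the widest kernel PSF."""
        if dz not in self._grids:
            from .ct import _default_grid

            protos = [
                CTProtocol(
                    slice_thickness_mm=dz,
                    kernel=k,
                    in_plane_spacing_mm=self.config.in_plane_spacing_mm,
                )
                for k in self.config.kernels
            ]
            widest = max(protos, key=lambda p: p.psf_fwhm_mm)
            self._grids[dz] = _default_grid(self.phantom, widest)
        return self._grids[dz]

    def occupancy_for(self, dz: float) -> np.ndarray:
        if dz not in self._occupancy:
            origin, shape = self._grid_for(dz)
            spacing = (
                self.config.in_plane_spacing_mm,
                self.config.in_plane_spacing_mm,
                dz,
            )
            log.info("computing occupancy for slice thickness %.1f mm", dz)
            self._occupancy[dz] = compute_occupancy(
                self.phantom, spacing, origin, shape
            )
        return self._occupancy[dz]

    def ct_volume(self, dz: float, kernel: str, noiseless: bool = False) -> HUVolume:
        key = (dz, kernel, noiseless)
        if key not in self._volumes:
            seed = self._seed("ct", dz, kernel)
            proto = CTProtocol(
                slice_thickness_mm=dz,
                in_plane_spacing_mm=self.config.in_plane_spacing_mm,
                kernel=kernel,
                seed=seed,
            )
            if noiseless:
                proto = proto.noiseless()
            origin, shape = self._grid_for(dz)
            self._volumes[key] = simulate_ct(
                self.phantom, proto, origin=origin, shape=shape,
                occupancy=self.occupancy_for(dz),
            )
        return self._volumes[key]

    def _seed(self, *parts) -> int:
        """Deterministic per-task sub-seed derived from the base seed."""
        import zlib

        h = np.random.SeedSequence(
            [self.config.base_seed]
            + [zlib.crc32(str(p).encode()) for p in parts]
        )
        seed = int(h.generate_state(1)[0] % (2**31))
        self.manifest["seeds"]["/".join(str(p) for p in parts)] = seed
        return seed

    # -- stage 1: segmentation sweep ----------------------------------------
    def run_sege_sweep(self) -> pd.DataFrame:
        """(profile x protocol x threshold) sweep with cut-off bookkeeping."""
        cfg = self.config
        rows = []
        for profile in cfg.profiles:
            for kernel in cfg.kernels:
                for dz in cfg.slice_thicknesses_mm:
                    volume = self.ct_volume(dz, kernel)
                    for thr in cfg.thresholds_hu:
                        row = {
                            "software_profile": profile,
                            "kernel": kernel,
                            "slice_thickness_mm": dz,
                            "threshold_hu": thr,
                            "volume_mm3": np.nan,
                            "dV_rel_pct": np.nan,
                            "Fi_bytes": np.nan,
                            "n_components": np.nan,
                            "included": False,
                            "mean_dS_mm": np.nan,
                            "six_sigma_dS_mm": np.nan,
                            "error": "",
                        }
                        try:
                            seg = segment_threshold(
                                volume,
                                thr,
                                island_policy=cfg.island_policy,
                                method=_PROFILE_SEG_METHOD[profile],
                                reference_volume_mm3=self.phantom_volume,
                            )
                            row.update(
                                volume_mm3=seg.metrics.volume_mm3,
                                dV_rel_pct=seg.rel_volume_error_pct,
                                Fi_bytes=seg.metrics.file_size_bytes,
                                n_components=seg.n_components,
                                included=passes_cutoff(
                                    seg.metrics.volume_mm3, cfg.cutoff_mm3
                                ),
                            )
                            if row["included"] and cfg.compute_deviation:
                                stats = signed_surface_deviation(
                                    seg.mesh,
                                    self.phantom,
                                    n_samples=cfg.deviation_samples,
                                    seed=self._seed("sege", profile, kernel, dz, thr),
                                )
                                row.update(
                                    mean_dS_mm=stats.mean_dS,
                                    six_sigma_dS_mm=stats.six_sigma_dS,
                                )
                        except PrintQAError as exc:
                            row["error"] = f"{type(exc).__name__}: {exc}"
                        rows.append(row)
        return pd.DataFrame(rows)

    # -- stage 2: digital editing -------------------------------------------
    def _dee_segmentation(self, profile: str, dz: float) -> SegmentationResult:
        volume = self.ct_volume(dz, self.config.dee_kernel)
        return segment_threshold(
            volume,
            self.config.dee_threshold_hu,
            island_policy="largest_component",
            method=_PROFILE_SEG_METHOD[profile],
            reference_volume_mm3=self.phantom_volume,
        )

    def run_dee_study(self) -> pd.DataFrame:
        """Apply every available (profile, level) to the designated scans."""
        cfg = self.config
        rows = []
        for profile in cfg.profiles:
            levels = (
                ("low",) if profile == "d2p_like" else ("low", "medium", "high")
            )
            for dz in cfg.dee_slice_thicknesses_mm:
                seg = self._dee_segmentation(profile, dz)
                volume = self.ct_volume(dz, cfg.dee_kernel)
                for level in levels:
                    spec = SmoothingSpec(profile, level)
                    row = {
                        "software_profile": profile,
                        "level": level,
                        "slice_thickness_mm": dz,
                        "threshold_hu": cfg.dee_threshold_hu,
                        "kernel": cfg.dee_kernel,
                        "dFi_rel_pct": np.nan,
                        "dV_rel_pct": np.nan,
                        "mean_dS_mm": np.nan,
                        "six_sigma_dS_mm": np.nan,
                        "error": "",
                    }
                    try:
                        smoothed = self.apply_smoothing(spec, seg, volume)
                        metrics = dee_metrics(
                            seg.mesh,
                            smoothed,
                            n_samples=cfg.deviation_samples,
                            seed=self._seed("dee", profile, level, dz),
                            compute_deviation=cfg.compute_deviation,
                        )
                        row.update(
                            dFi_rel_pct=metrics.dFi_rel_pct,
                            dV_rel_pct=metrics.dV_rel_pct,
                        )
                        if metrics.deviation is not None:
                            row.update(
                                mean_dS_mm=metrics.deviation.mean_dS,
                                six_sigma_dS_mm=metrics.deviation.six_sigma_dS,
                            )
                    except PrintQAError as exc:
                        row["error"] = f"{type(exc).__name__}: {exc}"
                    rows.append(row)
        return pd.DataFrame(rows)

    def apply_smoothing(
        self,
        spec: SmoothingSpec,
        seg: SegmentationResult,
        volume: Optional[HUVolume] = None,
    ) -> TriMesh:
        """Produce the print-STL for one smoothing setting."""
        if spec.method == "mesh":
            return smooth_mesh_factor(seg.mesh, spec.factor)
        if volume is None:
            raise ValueError("volume-method smoothing needs the source HU volume")
        smoothed_volume = smooth_volume_median(volume, spec.median_kernel_mm)
        return segment_threshold(
            smoothed_volume,
            seg.threshold_hu,
            island_policy=seg.island_policy,
            method="subvoxel" if spec.profile != "d2p_like" else "binary",
        ).mesh

    # -- stage 3: printing ---------------------------------------------------
    def run_pre_study(self) -> pd.DataFrame:
        """Print-simulate the phantom per printer spec and replicate."""
        cfg = self.config
        rows = []
        for name, mean_amp in cfg.printer_amplitudes_mm.items():
            rng = np.random.default_rng(self._seed("pre", name))
            for rep in range(cfg.print_replicates):
                amp = float(
                    max(0.0, rng.normal(mean_amp, cfg.printer_amplitude_jitter * mean_amp))
                ) if mean_amp > 0 else 0.0
                spec = PrintSpec(
                    layer_height_mm=cfg.layer_height_mm,
                    warp_amplitude_mm=amp,
                    seed=cfg.base_seed,
                )
                printed = simulate_print(self.phantom, spec)
                stats = signed_surface_deviation(
                    printed,
                    self.phantom,
                    n_samples=cfg.deviation_samples,
                    seed=self._seed("pre", name, rep),
                )
                rows.append(
                    {
                        "printer": name,
                        "replicate": rep,
                        "warp_amplitude_mm": amp,
                        "mean_dS_mm": stats.mean_dS,
                        "sigma_mm": stats.sigma,
                        "six_sigma_dS_mm": stats.six_sigma_dS,
                    }
                )
        return pd.DataFrame(rows)

    # -- stage 4: total error -------------------------------------------------
    def run_total_error(self) -> Dict:
        """Propagate the optimal and worst-case configurations.

        Configuration 1 (optimal analog): 0.4 mm slices, soft kernel,
        threshold -400 HU, low smoothing, accurate printer.
        Configuration 2 (worst-case analog): 5.0 mm slices, soft kernel,
        threshold -600 HU, high smoothing, accurate printer.
        """
        presets = {
            "config_1": dict(dz=0.4, threshold=-400.0, level="low"),
            "config_2": dict(dz=5.0, threshold=-600.0, level="high"),
        }
        cfg = self.config
        pre_table = self.run_pre_study()
        accurate = pre_table[pre_table.printer == "accurate"]
        pr_e = PartialError(
            "PrE",
            float(accurate.mean_dS_mm.mean()),
            float(accurate.sigma_mm.mean()),
        )
        report = {}
        for name, p in presets.items():
            volume = self.ct_volume(p["dz"], "soft")
            seg = segment_threshold(
                volume,
                p["threshold"],
                island_policy="largest_component",
                method="subvoxel",
                reference_volume_mm3=self.phantom_volume,
            )
            seg_stats = signed_surface_deviation(
                seg.mesh, self.phantom, n_samples=cfg.deviation_samples,
                seed=self._seed("total", name, "sege"),
            )
            seg_e = PartialError("SegE", seg_stats.mean_dS, seg_stats.sigma)
            spec = SmoothingSpec("slicer_like", p["level"])
            smoothed = self.apply_smoothing(spec, seg, volume)
            dee_stats = signed_surface_deviation(
                smoothed, seg.mesh, n_samples=cfg.deviation_samples,
                seed=self._seed("total", name, "dee"),
            )
            dee = PartialError("DEE", dee_stats.mean_dS, dee_stats.sigma)
            total = propagate_total(seg_e, dee, pr_e)
            report[name] = format_report(
                {"SegE": seg_e, "DEE": dee, "PrE": pr_e}, total
            )
            report[name]["parameters"] = {
                "slice_thickness_mm": p["dz"],
                "threshold_hu": p["threshold"],
                "smoothing_level": p["level"],
                "printer": "accurate",
            }
        return report

    # -- persistence ----------------------------------------------------------
    def save_outputs(self, sege=None, dee=None, pre=None, total=None) -> None:
        out = Path(self.config.output_dir or "printqa_output")
        out.mkdir(parents=True, exist_ok=True)
        if sege is not None:
            sege.to_csv(out / "sege_sweep.csv", index=False)
        if dee is not None:
            dee.to_csv(out / "dee_study.csv", index=False)
        if pre is not None:
            pre.to_csv(out / "pre_study.csv", index=False)
        if total is not None:
            (out / "total_error.json").write_text(json.dumps(total, indent=2))
        (out / "run_manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str)
        )


def run_study(config: StudyConfig) -> Dict[str, object]:
    """Run every stage and save the tables; returns them keyed by stage."""
    runner = StudyRunner(config)
    sege = runner.run_sege_sweep()
    dee = runner.run_dee_study()
    pre = runner.run_pre_study()
    total = runner.run_total_error()
    runner.save_outputs(sege=sege, dee=dee, pre=pre, total=total)
    return {"sege": sege, "dee": dee, "pre": pre, "total": total, "runner": runner}
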