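"""Simulate CT scans and sweep the segmentation threshold.

Shows the two central segmentation effects: the extracted volume shrinks
as the threshold rises, and noisy bone-kernel scans fragment into many
components ("island formation") at high thresholds.
"""

from printqa import (
    CTProtocol,
    EmptySegmentationError,
    DEFAULT_THRESHOLDS_HU,
    generate_benchy,
    mesh_volume,
    relative_volume_error,
    segment_threshold,
    simulate_ct,
)

phantom = generate_benchy(complexity=1, seed=42)
v_ref = mesh_volume(phantom)
print(f"ground-truth volume: {v_ref:.0f} mm^3\n")

volume = simulate_ct(phantom, CTProtocol(slice_thickness_mm=1.5, kernel="soft", seed=1))
print("threshold sweep (soft kernel, 1.5 mm slices):")
print(f"{'HU':>6} {'volume mm^3':>12} {'dV rel %':>9} {'components':>11}")
for thr in DEFAULT_THRESHOLDS_HU:
    try:
        seg = segment_threshold(volume, thr, reference_volume_mm3=v_ref)
        print(f"{thr:6.0f} {seg.metrics.volume_mm3:12.0f} "
              f"{seg.rel_volume_error_pct:9.2f} {seg.n_components:11d}")
    except EmptySegmentationError:
        print(f"{thr:6.0f} {'empty':>12}")

bone = simulate_ct(phantom, CTProtocol(slice_thickness_mm=1.5, kernel="bone", seed=1))
n_bone = segment_threshold(bone, 0.0).n_components
n_soft = segment_threshold(volume, 0.0).n_components
print(f"\ncomponents at 0 HU: bone kernel {n_bone}, soft kernel {n_soft} "
      f"(noise-driven island formation)")
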