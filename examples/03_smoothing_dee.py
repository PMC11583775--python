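"""Quantify the digital-editing error (DEE) of the smoothing levels.

Smoothing the segmented model before printing shrinks it slightly and
rounds off edges; the effect grows with the smoothing level.
"""

from printqa import (
    CTProtocol,
    SmoothingSpec,
    dee_metrics,
    generate_benchy,
    segment_threshold,
    simulate_ct,
    smooth_mesh_factor,
)

phantom = generate_benchy(complexity=1, seed=42)
volume = simulate_ct(phantom, CTProtocol(slice_thickness_mm=1.5, kernel="bone", seed=1))
seg = segment_threshold(volume, -600.0, island_policy="largest_component")

print("mesh-domain smoothing (Taubin-style), factor mapped to iterations:")
print(f"{'level':>7} {'factor':>7} {'dFi rel %':>10} {'dV rel %':>9} "
      f"{'mean dS mm':>11} {'6s dS mm':>9}")
for level in ("low", "medium", "high"):
    spec = SmoothingSpec("brainlab_like", level)
    smoothed = smooth_mesh_factor(seg.mesh, spec.factor)
    m = dee_metrics(seg.mesh, smoothed, n_samples=10_000, seed=0)
    print(f"{level:>7} {spec.factor:7.2f} {m.dFi_rel_pct:10.2f} "
          f"{m.dV_rel_pct:9.3f} {m.deviation.mean_dS:11.4f} "
          f"{m.deviation.six_sigma_dS:9.4f}")
print("\nmesh smoothing keeps the triangle count, so dFi rel stays 0;")
print("volume-domain (median) profiles also reduce the file size.")
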