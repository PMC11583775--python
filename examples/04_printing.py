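"""Simulate FFF printing and measure the printing error (PrE).

A well-adhering printer leaves only the layer staircase; a poorly adhering
one additionally warps, lifting the base edges off the build plate, which
widens the deviation spread.
"""

from printqa import PrintSpec, generate_benchy, signed_surface_deviation, simulate_print

phantom = generate_benchy(complexity=1, seed=42)

print(f"{'printer':>10} {'warp mm':>8} {'mean dS mm':>11} {'6s dS mm':>9}")
for name, amplitude in (("accurate", 0.1), ("warped", 1.2)):
    printed = simulate_print(
        phantom, PrintSpec(layer_height_mm=0.3, warp_amplitude_mm=amplitude)
    )
    stats = signed_surface_deviation(printed, phantom, n_samples=10_000, seed=0)
    print(f"{name:>10} {amplitude:8.1f} {stats.mean_dS:11.4f} "
          f"{stats.six_sigma_dS:9.4f}")
print("\nthe 6-sigma spread grows with the warp amplitude; the staircase")
print("alone stays below the 0.3 mm layer height.")
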