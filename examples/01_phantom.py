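"""Generate the femur-like phantom and inspect its mesh metrics.

The phantom combines a spherical head, an angled neck and a flat-faced
shaft with smooth fillets -- the geometric features (curves, corners,
edges) that drive segmentation and printing errors.
"""

from printqa import MeshMetrics, generate_benchy, save_stl

phantom = generate_benchy(complexity=2, seed=42)
metrics = MeshMetrics.of(phantom)

print(f"triangles      : {metrics.n_triangles}")
print(f"volume         : {metrics.volume_mm3:.1f} mm^3")
print(f"STL file size  : {metrics.file_size_bytes / 1e6:.2f} MB (binary)")
print(f"extents        : {phantom.extents.round(1)} mm")
print(f"watertight     : {phantom.is_watertight}")

save_stl(phantom, "phantom.stl")
print("wrote phantom.stl")
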