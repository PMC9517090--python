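"""Write a deviation colormap PLY for the measured maxillary region.

Colors encode the signed point-to-surface deviation: blue = -2 mm (behind
the planned surface), green = on plan, red = +2 mm (in front); values beyond
the range clamp. The output is an ASCII PLY viewable in any mesh viewer.
"""

import numpy as np

from maxalign import (
    PhantomSpec,
    RigidTransform,
    compute_normals,
    extract_points,
    extract_submesh,
    generate_phantom_pair,
    surface_deviation,
    deviation_colormap,
)

res = RigidTransform(np.eye(3), np.array([0.0, 0.0, 1.2]))
t0, t1, truth = generate_phantom_pair(PhantomSpec(true_residual_transform=res))

reference = compute_normals(extract_submesh(t0, truth.roi2))
samples = extract_points(t1, truth.roi2)[0]
dev = surface_deviation(samples, reference, signed=True)
region = extract_submesh(t1, truth.roi2)
deviation_colormap(region, dev, "maxilla_deviation.ply", palette_range=2.0)

print(f"signed deviations: mean {dev.summary.mean_dev:+.3f} mm, "
      f"range [{dev.summary.min_dev:+.3f}, {dev.summary.max_dev:+.3f}] mm")
print("wrote maxilla_deviation.ply (blue -2 mm .. green 0 .. red +2 mm)")
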