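"""Analyze a single planned/postoperative pair on a synthetic skull phantom.

Builds a phantom whose maxilla was 'operated' with a known 1.2 mm residual
displacement, perturbs the scan frame, adds surface noise, then runs the
full pipeline: principal-axes initial alignment + trimmed point-to-mesh ICP
on the cranial reference region (ROI1), followed by point-to-surface
deviation of the maxillary region (ROI2) against the plan.
"""

import numpy as np

from maxalign import PhantomSpec, RigidTransform, generate_phantom_pair, run_case_meshes

residual = RigidTransform(np.eye(3), np.array([0.8, -0.6, 0.5]))  # ~1.1 mm slip
pose = RigidTransform.from_axis_angle([1, 2, 1], 15.0, (8.0, -5.0, 3.0))
spec = PhantomSpec(
    true_residual_transform=residual,
    global_pose_perturbation=pose,
    noise_sd=0.05,
    seed=1,
)
t0, t1, truth = generate_phantom_pair(spec)
outcome = run_case_meshes(t0, t1, truth.roi1, truth.roi2)

s = outcome.deviation.summary
print(f"ICP iterations        : {outcome.registration.iterations_run}")
print(f"registration RMS (mm) : {outcome.registration.rms_per_iteration[-1]:.4f}")
print(f"3D error / RMS (mm)   : {s.rms:.4f}")
print(f"mean deviation (mm)   : {s.mean_dev:.4f}")
print(f"max / min (mm)        : {s.max_dev:.4f} / {s.min_dev:.4f}")
print(f"clinically acceptable : {outcome.acceptable}  (RMS <= 2 mm)")
# The registration RMS sits near the 0.05 mm noise floor (the reference
# region is unchanged by surgery); the 3D error reflects the maxillary
# residual, here well inside the +/-2 mm clinical band.
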