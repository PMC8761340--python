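"""Build a template space and recover a known rigid motion by registration.

Averages phantom T1 volumes into a template (non-zero averaging with the 30%
occupancy rule), perturbs one T1 by a known rigid transform, runs the two-step
affine-then-rigid registration, and prints the recovery error.
"""

import numpy as np

from mvseg import (
    AffineTransform,
    PhantomConfig,
    build_template,
    generate_case,
    register_affine,
    resample,
    rigid_component,
)
from mvseg.standard_space import Dof, Interp

cases = [generate_case(PhantomConfig(seed=s, misalign_mm=0, misalign_deg=0))[0]
         for s in (1, 2, 3)]
tpl = build_template([c.t1 for c in cases], threshold=0.30)
frac = tpl.occupancy_mask.n_voxels / np.prod(tpl.template.shape)
print(f"template grid {tpl.template.shape}, occupancy mask covers {frac:.1%} of voxels")

t1 = cases[0].t1
center = t1.affine[:3, :3] @ ((np.asarray(t1.shape) - 1) / 2)
true = AffineTransform.from_rigid((6.0, -8.0, 3.0), (4.0, -3.0, 7.0), center_mm=center)
moved = resample(t1, true.inverse(), t1, Interp.LINEAR)

step1 = register_affine(moved, t1, dof=Dof.AFFINE)
recovered = register_affine(moved, t1, init=rigid_component(step1), dof=Dof.RIGID)

delta = recovered.matrix @ np.linalg.inv(true.matrix)
angle = np.rad2deg(np.arccos(np.clip((np.trace(delta[:3, :3]) - 1) / 2, -1, 1)))
disp = np.linalg.norm(AffineTransform(delta).apply(center) - center)
print(f"applied motion:  6.0/-8.0/3.0 mm, 4/-3/7 deg about the volume center")
print(f"recovery error:  {disp:.3f} mm translation, {angle:.3f} deg rotation")
print("Errors well under half a millimetre/degree mean the two-step scheme "
      "recovers the subject pose to sub-voxel precision.")
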