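"""Recover a known deformation with the two-stage registration.

A moving image is synthesized from the phantom through a known random
smooth warp; affine + B-spline FFD registration on sampled NMI should
recover (the inverse of) it. The printed numbers are mean displacement
errors in mm over the bony anatomy — after registration they should be
well under half the initial misalignment.
"""

import numpy as np

from multiatlas import CohortSpec, PhantomSpec, make_config, make_phantom, random_deformation, register_affine, register_bspline, warp
from multiatlas.transforms import TransformChain

phantom = make_phantom(PhantomSpec())
fixed = phantom.gray
sp = np.asarray(fixed.spacing)
dom = (fixed.origin - sp, fixed.physical_extent + 2 * sp)

true_ffd = random_deformation(CohortSpec(), seed=201, domain=dom)
moving = warp(fixed, TransformChain([true_ffd]), fixed, "linear")

cfg = make_config("desk")
affine = register_affine(fixed, moving, cfg)
ffd = register_bspline(fixed, moving, affine, cfg)

anatomy = fixed.voxels > 400
pts = fixed.index_to_physical(np.argwhere(anatomy))
y = pts.copy()
for _ in range(30):  # invert p -> p + d(p)
    y = pts - true_ffd.displacement(y)
pre = np.linalg.norm(y - pts, axis=1).mean()
post = np.linalg.norm(TransformChain([affine, ffd]).map_points(pts) - y, axis=1).mean()
print(f"misalignment before registration: {pre:.3f} mm (mean over bone voxels)")
print(f"residual after affine + FFD:      {post:.3f} mm")
print(f"error reduction:                  {100 * (1 - post / pre):.1f}%")
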