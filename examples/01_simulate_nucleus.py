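"""Generate one punctate rim-labeled nucleus and write it as TIFF + sidecar.

The image has three channels: a filled nuclear interior (counterstain), a
continuous envelope rim (reference lamin), and a rim concentrated in
discrete foci (test channel, prelamin A-like).
"""

import numpy as np

import laminafluct as lf

spec = lf.punctate_spec(seed=1)
stack, truth = lf.generate_nucleus_image(spec)
path = lf.write_stack(stack, "scratch_nucleus.tif", extra_meta={
    "true_contour": truth.contour.points.tolist(),
    "focus_angles": truth.focus_angles.tolist(),
})

print(f"wrote {path} with channels {stack.roles}")
print(f"image size: {stack.shape_yx}, foci at angles (rad): {np.round(truth.focus_angles, 2)}")
for role in ("counterstain", "reference", "test"):
    ch = stack.data[stack.roles[role], 0]
    print(f"  {role:12s} min {ch.min():7.1f}  max {ch.max():7.1f}")
# The reference rim peaks near rim_amplitude + background everywhere along
# the boundary; the test channel reaches that level only inside foci.
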