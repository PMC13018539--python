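"""Train the desk-scale UVF delineator on synthetic SIJ-like slices and
delineate a held-out slice.

Uses a reduced budget (40 slices, 120 steps) so the example runs in about
a minute; the acceptance benchmark uses 200 slices and 300 steps.
"""

import numpy as np

from sijkit.contour import WalkParams, closest_point_rms
from sijkit.delineation import DelineatorConfig, delineate_volume, train_delineator
from sijkit.synth import SceneSpec, make_slice

rng = np.random.default_rng(0)
spec = SceneSpec()
train = [make_slice(spec, rng) for _ in range(40)]
test = [make_slice(spec, rng) for _ in range(5)]

config = DelineatorConfig.desk(seed=0, steps=120)
model, history = train_delineator(train, config)
print(f"training loss: {history['train'][0]:.3f} -> {history['train'][-1]:.3f}")

for i, sample in enumerate(test):
    contours = delineate_volume(model, sample.image[None], WalkParams())[0]
    for side in ("left", "right"):
        gt = sample.landmarks[side]
        pred = contours[side]
        if not gt.present:
            print(f"slice {i} {side:5s}: annotation absent, "
                  f"predicted {'absent' if not pred.present else 'present'}")
        elif pred.present and len(pred) > 1:
            print(f"slice {i} {side:5s}: RMS {closest_point_rms(pred, gt):.2f} px")
        else:
            print(f"slice {i} {side:5s}: missed (no contour extracted)")

print()
print("Each RMS is the closest-point error between the walked contour and")
print("the ground-truth landmarks of that joint, in pixels of the 64 px grid.")
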