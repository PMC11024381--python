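"""Render a synthetic flower and inspect its ground truth.

The renderer draws tepals as rotated ellipses whose adjacent pairs
overlap; each overlap's depth relation is prescribed by an L/R pattern
(L = the left tepal, seen with the flower interior below, lies in
front).  Every render comes with exact ground truth for each pipeline
stage.
"""

import tepals as tp

spec = tp.FlowerSpec(n_tepals=5, lr_pattern="LLLLL", canvas=(1000, 662), seed=7)
image, truth = tp.render_flower(spec)

print(f"image: {image.shape[1]}x{image.shape[0]}, box: {truth.box.as_tuple()}")
print(f"foreground pixels: {truth.mask.sum()}")
for (x, y), label in truth.overlap_points:
    print(f"  overlap at ({x:6.1f}, {y:6.1f})  depth label {label}")
print(f"arrangement: {truth.arrangement} (catalog id {truth.arrangement_id})")
# An all-L pattern is a depth spiral: every tepal covers its clockwise
# neighbor, so every tepal is above one neighbor and below the other
# (class A), the quincuncial-like spiral B2.
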