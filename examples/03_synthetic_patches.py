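"""Generate labeled synthetic overlap patches from a single flower.

Real overlap crops cannot be labeled automatically, but single-margin
crops taken a little away from the overlap can be superimposed in a
chosen depth order, which fixes the label by construction: compositing
the left-rising arc in front simulates "left tepal forward" (L).  From
25 arcs of each slope type, every cross-type pair in both orders gives
25 x 25 x 2 = 1250 labeled patches per flower.
"""

import tepals as tp

image, truth = tp.render_flower(
    tp.FlowerSpec(n_tepals=6, lr_pattern="LRLRLR", canvas=(1000, 662), seed=3)
)
flower = tp.segment_flower(image, tp.detect_flower(image))
points = tp.detect_overlap_points(flower)

patch_set = tp.generate_synthetic_patch_set(flower, points, seed=0)
print(f"overlaps used: {patch_set.source_overlaps}")
print(f"synthetic patches: {len(patch_set.patches)}")
print(f"per class: {patch_set.per_class_counts}")

sizes = {p.pixels.shape for p in patch_set.patches}
print(f"patch shapes: {sizes}")
# 1250 patches, 625 L / 625 R: enough balanced supervision to adapt a
# classifier to this one flower's colors and margin shapes.
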