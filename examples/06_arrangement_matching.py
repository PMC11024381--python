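"""Circular-permutation matching against the arrangement catalog.

Interior-exterior labels (L/R), ordered clockwise around the flower
centroid, convert pairwise to per-tepal classes: I (internal, above both
neighbors), E (external, below both), A (alternating).  The resulting
circular string, read up to rotation and reflection, is matched to the
nearest catalog entry by cyclic edit distance.
"""

import tepals as tp

catalog = tp.load_catalog()
print(f"catalog: {len(catalog)} entries")
for e in catalog:
    print(f"  {e.id}: {e.canonical}")

seq = tp.lr_to_iea("LRLRLR")
print(f"\nLRLRLR converts to {seq} (two alternating whorls of three)")
m = tp.match_arrangement(seq, catalog)
print(f"match: {m.best.id} at distance {m.distance}")

# one corrupted label: still recovered, but at distance 1
noisy = tp.lr_to_iea("LRLLLR")
m2 = tp.match_arrangement(noisy, catalog)
print(f"corrupted LRLLLR -> {noisy}: {m2.best.id} at distance {m2.distance} "
      f"(ambiguous: {m2.ambiguous})")

# how many arrangements are conceivable at all, versus cataloged?
for n in range(4, 10):
    print(f"n={n}: {len(tp.enumerate_arrangements(n))} conceivable classes")
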