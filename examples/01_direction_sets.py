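"""Enumerate canonical digital directions on the 3D voxel lattice.

Co-occurrence statistics are symmetric under direction reversal, so only
one member of each antipodal pair {v, -v} is kept.  The number of
distinct directions grows with the Chebyshev displacement bound; dropping
collinear duplicates (integer multiples of a shorter vector) leaves only
primitive rays.
"""

from msglcm import enumerate_directions

base = enumerate_directions(3, 1)
print("13 base directions (displacement <= 1):")
for v in base:
    print("  ", v)

print("\ncounts by displacement bound:")
print(f"{'bound':>6} {'with duplicates':>16} {'without':>8}")
for d in (1, 2, 3):
    full = len(enumerate_directions(3, d, dedup=False))
    dedup = len(enumerate_directions(3, d, dedup=True))
    print(f"{d:>6} {full:>16} {dedup:>8}")

print("\n2D in-plane directions:", list(enumerate_directions(2, 1)))
# The direction count drives descriptor length: each direction contributes
# a 28-measure block, so e.g. 62 directions -> 1736 variables per lesion.
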