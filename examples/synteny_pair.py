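"""Pairwise synteny via 50 bp fragment anchors.

Takes a 40 kb genome, applies two inversions, and chains the fragment
anchors into collinear blocks; the inversions appear as blocks whose
partner coordinates run backwards.
"""

import numpy as np

from orgamosaic import Genome, apply_rearrangements
from orgamosaic.synteny import compare

rng = np.random.default_rng(1)
seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=40_000)])
a = Genome(id="A", seq=seq)
b, events = apply_rearrangements(a, n_inversions=2, seed=2)

anchors, blocks = compare(a, b)
print(f"{len(anchors)} anchors chained into {len(blocks)} blocks")
for blk in blocks:
    print(
        f"  A {blk.a_span.start:>6}-{blk.a_span.end:<6} ~ "
        f"B {blk.b_span.start:>6}-{blk.b_span.end:<6} "
        f"{blk.orientation:<9} ({blk.n_anchors} anchors)"
    )
print("planted events:")
for e in events:
    print(f"  {e['kind']} at {e['start']}-{e['end']}")

# Each planted inversion shows up as an 'inverted' block between two
# 'same'-orientation blocks; block spans on A are disjoint.
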