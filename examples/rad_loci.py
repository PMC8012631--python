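"""Derive RAD-locus footprints from per-base depth tracks.

Builds toy coverage tracks for three samples and shows the footprint rule:
a base passes when every sample covers it at depth >= 5; passing runs
merge across gaps of <= 10 bp; merged intervals < 100 bp are dropped.
"""

import numpy as np

from partho import DepthTrack, derive_rad_loci

L = 1000
tracks = []
for sample in ("mother", "off1", "off2"):
    depth = np.zeros(L, dtype=int)
    depth[100:260] = 20      # a solid locus
    depth[300:355] = 20      # run split by an 8-bp dip ...
    depth[363:420] = 20      # ... still merges into one locus
    depth[500:560] = 20      # too short on its own
    tracks.append(DepthTrack(sample, "chr1", 0, depth))
tracks[1].depth[150] = 2     # one low-depth base in one sample splits a run

loci = derive_rad_loci(tracks, min_depth=5, max_gap=10, min_len=100)
for locus in loci:
    print(f"{locus.chrom}\t{locus.start}\t{locus.end}\t({locus.length} bp)")
# The dip at base 150 only costs a 1-bp gap (within the 10-bp allowance),
# so [100,260) survives intact; [300,420) merges across its dip; the
# 60-bp island at 500 is discarded as shorter than 100 bp.
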