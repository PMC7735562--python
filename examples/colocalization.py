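"""GFP-marker colocalization with group statistics.

Simulates per-image correlation data for three treatment groups: untreated
cells (GFP in the ER, low overlap with a lysosomal marker) and two
chaperone treatments that move GFP into the marker-positive compartment.
Per-image Pearson correlations over the cell area are compared with a
Kruskal-Wallis omnibus test and Dunn's pairwise comparisons under
Benjamini-Hochberg adjustment.
"""

import numpy as np

from npcscreen import coloc_correlation, compare_groups
from npcscreen.io_plate import Channel, ImageField


def image_pair(overlap, seed):
    """Marker = overlap-weighted copy of GFP plus independent structure."""
    rng = np.random.default_rng(seed)
    gfp = np.clip(rng.random((128, 128)) * 0.5, 0, 1)
    other = rng.random((128, 128)) * 0.5
    marker = np.clip(overlap * gfp + (1 - overlap) * other, 0, 1)
    return (ImageField(gfp, Channel.GFP), ImageField(marker, Channel.MARKER))


mask = np.ones((128, 128), dtype=bool)
groups = {}
for name, overlap in (("vehicle", 0.1), ("chaperone_A", 0.6),
                      ("chaperone_B", 0.7)):
    vals = []
    for seed in range(10):
        g, m = image_pair(overlap, seed)
        vals.append(coloc_correlation(g, m, mask))
    groups[name] = vals
    print(f"{name:12s} mean r = {np.mean(vals):.3f} +- {np.std(vals, ddof=1):.3f}"
          f"  (n = {len(vals)} images)")

res = compare_groups(groups, method="kruskal_dunn_bh")
print(f"\nKruskal-Wallis omnibus p = {res.omnibus_p:.2e}")
print(res.pairwise.round(4).to_string(index=False))
print("\nBoth chaperone groups show far higher marker overlap than vehicle "
      "(adjusted p) — the signature of restored trafficking to the "
      "marker-positive compartment.")
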