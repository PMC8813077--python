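"""DMR calling from per-probe p-values.

The caller estimates the distance-binned autocorrelation of z-transformed
p-values, smooths each probe by Stouffer-Liptak combination with its
neighbours (<=500 bp), seeds regions at smoothed p < 1e-4, extends over
probes < 0.05, requires >=3 probes, scores each region by Stouffer-Liptak
over the members' original p-values, and applies a Sidak correction for
the number of region-sized windows in the covered genome.
"""

import numpy as np
import pandas as pd

from twinewas import estimate_acf, find_dmrs

rng = np.random.default_rng(1)
n = 600
pos = np.cumsum(rng.integers(60, 161, size=n)) + 1
annot = pd.DataFrame({"probe_id": [f"cg{i:05d}" for i in range(n)],
                      "chrom": "chr1", "pos": pos,
                      "gene": "", "island_relation": ""})
p = rng.uniform(0.02, 1.0, size=n)
p[300:306] = rng.uniform(1e-8, 1e-6, size=6)   # a 6-probe cluster of signal

acf = estimate_acf(p, annot)
print("autocorrelation by distance bin:")
print(acf.bins.head(4).to_string(index=False))

regions = find_dmrs(p, annot, acf)
print("\nregions:")
print(regions.to_string(index=False))
# p_region combines the member probes' evidence accounting for their
# spatial correlation; p_sidak corrects it for all region-sized windows in
# the ~%.0f kb covered, so it is the genome-wide-honest p-value.
print("\ncovered span: %.0f kb" % ((pos.max() - pos.min()) / 1000))
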