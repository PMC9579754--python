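"""Build a marker catalogue from parental calls and window it.

Two inbred founder strains are genotyped against a reference; sites where
one parent is homozygous reference and the other homozygous alternate
(confirmed by the alternate-allele frequency bounds 0.05/0.95) become
marker SNPs whose population frequency tracks founder ancestry.  Windows
of w consecutive markers are then laid out per chromosome with arms
concatenated.
"""

import numpy as np
import pandas as pd

from duoscan import assign_windows, build_marker_catalog

rng = np.random.default_rng(0)
n = 2000
positions = np.sort(rng.choice(5_000_000, size=n, replace=False)) + 1

# synthetic parental call sets: ~40% of sites are fixed differences
geno_a = rng.choice(["0/0", "1/1", "0/1"], size=n, p=[0.45, 0.45, 0.10])
opposite = {"0/0": "1/1", "1/1": "0/0", "0/1": "0/1"}
flip = rng.random(n) < 0.6
geno_b = np.where(flip, [opposite[g] for g in geno_a], geno_a)

def freq_for(geno):
    return np.where(geno == "0/0", rng.uniform(0, 0.04, n),
                    np.where(geno == "1/1", rng.uniform(0.96, 1, n), 0.5))

calls = lambda geno: pd.DataFrame({
    "arm": "2L", "position": positions, "ref": "A", "alt": "G",
    "genotype": geno, "alt_freq": freq_for(geno),
})

catalog = build_marker_catalog(calls(geno_a), calls(geno_b), focal="a")
print(catalog.summary())
print(f"\nmarker density: 1 per {5_000_000 // len(catalog)} bp")

for w in (50, 250):
    index = assign_windows(catalog, w)
    print(f"w={w:>3}: {len(index)} complete windows "
          f"(trailing {len(catalog) % w} markers dropped)")
# Each window count is floor(retained markers / w); the centre coordinate
# of each window is the midpoint of its first and last marker.
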