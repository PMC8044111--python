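"""Aggregate methylation around a region set and compare two profiles.

Builds a synthetic methylation landscape with a dip at transcription-factor
binding sites (the signature of active regulatory regions), aggregates site
betas onto a common relative axis, and correlates two noisy realizations as
a stand-in for cross-platform (nanopore vs array) agreement.
"""

import numpy as np
import pandas as pd

from mitometh import Region, aggregate_profile, platform_correlation, site_level_correlation

rng = np.random.default_rng(3)
regions = [Region("chr1", s, s + 600, set_label="TFBS")
           for s in range(2000, 38000, 4000)]
pos = np.arange(0, 40000, 13)
truth = np.full(pos.size, 0.8)
for r in regions:
    truth[(pos >= r.start) & (pos < r.end)] = 0.1

def noisy_sites(sd):
    return pd.DataFrame({"chrom": "chr1", "pos": pos,
                         "beta": np.clip(truth + rng.normal(0, sd, pos.size), 0, 1),
                         "coverage_called": 10})

nano, array = noisy_sites(0.02), noisy_sites(0.02)
p_nano = aggregate_profile(nano, regions, n_bins=21)
p_array = aggregate_profile(array, regions, n_bins=21)

print("relative-axis profile (nanopore), 21 bins from flank to flank:")
print("  " + " ".join(f"{v:.2f}" for v in p_nano.mean_meth))
print(f"center-bin mean: {p_nano.mean_meth[10]:.3f} (truth inside regions: 0.10)")
print(f"flank-bin mean:  {p_nano.mean_meth[0]:.3f} (truth outside: 0.80)")
print(f"profile-level Pearson r: {platform_correlation(p_nano, p_array):.4f}")
r, table = site_level_correlation(nano, array[["chrom", "pos", "beta"]])
print(f"site-level Pearson r over {len(table)} matched positions: {r:.4f}")
print("The dip at the profile center reproduces the loss of methylation at "
      "active regulatory elements; high r indicates platform agreement.")
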