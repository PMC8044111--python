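"""Methylation beta values from bisulfite qMSP Ct pairs.

Each locus is amplified with methylated- and unmethylated-specific primers;
the beta value is the methylated fraction of total signal,
beta = 2^-Ct_m / (2^-Ct_m + 2^-Ct_u).
"""

from mitometh import CtPair, compute_betas

pairs = [
    CtPair("patient1_T", "Dloop", ct_methylated=20.0, ct_unmethylated=22.0),
    CtPair("patient1_N", "Dloop", ct_methylated=26.0, ct_unmethylated=21.0),
    CtPair("patient2_T", "Dloop", ct_methylated=24.0, ct_unmethylated=24.0),
]
table = compute_betas(pairs)
print(table.to_string(index=False))
print("A 2-cycle Ct advantage of the methylated primer (20 vs 22) means a "
      "4-fold signal excess: beta = 1/(1+2^-2) = 0.8. Equal Cts give 0.5.")
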