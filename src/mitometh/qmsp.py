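"""Methylation beta values from bisulfite qMSP Ct pairs.

Quantitative methylation-specific PCR runs two primer sets per locus on
bisulfite-converted DNA — one amplifying the methylated template, one the
unmethylated. With M = 2^(-Ct_m) and U = 2^(-Ct_u) as relative signals,

    beta = M / (M + U) = 1 / (1 + 2^(Ct_m - Ct_u))

The second form is used: it depends only on the Ct difference and cannot
underflow at large cycle numbers.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .formats_io import CtPair


def beta_from_ct(ct_m, ct_u):
    """Beta value from methylated/unmethylated Ct values (scalar or array)."""
    ct_m = np.asarray(ct_m, dtype=float)
    ct_u = np.asarray(ct_u, dtype=float)
    if not (np.all(np.isfinite(ct_m)) and np.all(np.isfinite(ct_u))):
        raise ValueError("Ct values must be finite")
    if np.any(ct_m <= 0) or np.any(ct_u <= 0):
        raise ValueError("Ct values must be > 0")
    beta = 1.0 / (1.0 + np.exp2(ct_m - ct_u))
    if beta.ndim == 0:
        return float(beta)
    return beta


def compute_betas(pairs: Iterable[CtPair]) -> pd.DataFrame:
    """Per-sample, per-locus beta table from qMSP Ct pairs."""
    rows = []
    for p in pairs:
        beta = beta_from_ct(p.ct_methylated, p.ct_unmethylated)
        rows.append(
            (
                p.sample_id,
                p.locus_id,
                math.pow(2.0, -p.ct_methylated),
                math.pow(2.0, -p.ct_unmethylated),
                beta,
            )
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "locus_id", "m_signal", "u_signal", "beta"]
    )
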