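"""Background calibration against a fully-unmethylated (FU) control.

The FU control — whole-genome-amplified DNA with no methylation — defines
the technical false-positive rate of the caller per strand:

    FPR = (# read-level calls labeled methylated) / (# called read-level calls)

pooled over all sites of one molecule strand. Heavy and light strands are
calibrated separately. A site in a test sample is then declared detectably
methylated when its methylated-call count exceeds what the background rate
explains: an exact one-sided binomial tail P(X >= n_meth | coverage, FPR),
Benjamini-Hochberg corrected across the strand's sites, with the additional
requirement that the observed beta exceed the FPR itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


class CalibrationError(ValueError):
    """The FU control provides no called reads to calibrate on."""


@dataclass(frozen=True)
class BackgroundModel:
    """Per-strand false-positive rate with its Wilson 95% interval."""

    strand: str
    fpr: float
    n_meth_calls: int
    n_total_calls: int
    ci95: tuple[float, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BackgroundModel":
        with open(path) as fh:
            d = json.load(fh)
        d["ci95"] = tuple(d["ci95"])
        return cls(**d)


def estimate_fpr(fu_sites: pd.DataFrame, strand: str) -> BackgroundModel:
    """Estimate the per-strand FPR from an FU-control site table.

    Pools read-level calls (not distinct sites): fpr = sum(n_meth) /
    sum(n_meth + n_unmeth) over the strand's sites.
    """
    if strand not in ("L", "H"):
        raise ValueError(f"strand must be 'L' or 'H', got {strand!r}")
    sub = fu_sites[fu_sites["molecule_strand"] == strand]
    n_meth = int(sub["n_meth"].sum())
    n_total = int(sub["coverage_called"].sum())
    if n_total == 0:
        raise CalibrationError(
            f"FU control has zero called calls on strand {strand}; cannot calibrate"
        )
    lo, hi = proportion_confint(n_meth, n_total, alpha=0.05, method="wilson")
    return BackgroundModel(
        strand=strand,
        fpr=n_meth / n_total,
        n_meth_calls=n_meth,
        n_total_calls=n_total,
        ci95=(float(lo), float(hi)),
    )


def detect_above_background(
    sites: pd.DataFrame, model: BackgroundModel, alpha: float = 0.05
) -> pd.DataFrame:
    """Call sites detectably methylated above the FU background.

    Per site on the model's strand: exact binomial tail
    p = P(X >= n_meth | n = coverage_called, p = fpr); BH correction across
    the strand's sites; detected iff q < alpha and beta > fpr.
    """
    sub = sites[sites["molecule_strand"] == model.strand].reset_index(drop=True)
    result = sub[["chrom", "pos", "molecule_strand", "beta", "coverage_called"]].copy()
    if not len(sub):
        result["p_binomial"] = []
        result["q_bh"] = []
        result["detected"] = []
        return result
    n_meth = sub["n_meth"].to_numpy()
    cov = sub["coverage_called"].to_numpy()
    # sf(k-1) = P(X >= k); beta == 0 gives p = 1 exactly
    p = stats.binom.sf(n_meth - 1, cov, model.fpr)
    q = stats.false_discovery_control(p, method="bh")
    result["p_binomial"] = p
    result["q_bh"] = q
    result["detected"] = (q < alpha) & (result["beta"].to_numpy() > model.fpr)
    return result
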