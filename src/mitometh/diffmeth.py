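"""Site-level differential methylation via a beta-binomial arcsine Wald test.

The test follows the dispersion-shrinkage design used for sequencing count
data. Per replicate at a site with ``X`` methylated calls out of ``N``
called reads, the continuity-corrected proportion p = (X+0.5)/(N+1) is
mapped through the variance-stabilizing arcsine link Y = arcsin(2p-1).
Under a beta-binomial model with dispersion phi, the replicate variance on
the Y scale is approximately

    v = (1 + (N-1) * phi) / N

independent of the mean — the point of the link. Group means are
inverse-variance weighted means of Y; the Wald statistic is their
difference over its standard error, with a two-sided normal p-value and
Benjamini-Hochberg correction across sites. Effect sizes are reported back
on the proportion scale via p = (sin(m)+1)/2.

Dispersion is estimated per site by method of moments from replicate
variability and shrunk toward the cross-site median with weight lambda —
a pragmatic stabilizer for the handful of replicates typical of these
designs. A paired variant regresses Y on [intercept, patient indicators,
group] by weighted least squares and tests the group coefficient, absorbing
per-patient baselines. Global distribution shifts between two samples are
assessed by Mann-Whitney (unpaired) or Wilcoxon signed-rank (paired) tests.

Significance gating follows the two-threshold convention: a site is a DML
only if |diff| >= delta (default 0.05) and the (raw or FDR-adjusted)
p-value is below the threshold (default 0.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

KEY_COLS = ["chrom", "pos", "molecule_strand"]


@dataclass
class DMLConfig:
    """Tunables of the differential methylation test.

    delta: minimum proportion-scale effect size (0.05 default; 0.10 is the
    stricter preset used for negative-control comparisons). p_threshold:
    significance cutoff. smoothing_on/smoothing_window: coverage-weighted
    proportion smoothing over +-window/2 bp (off by default for the short,
    deeply covered mitochondrial genome). shrinkage_weight: lambda in [0,1]
    pulling per-site dispersions toward their cross-site median.
    """

    delta: float = 0.05
    p_threshold: float = 0.05
    use_fdr: bool = False
    smoothing_on: bool = False
    smoothing_window: float = 500.0
    shrinkage_weight: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must be in [0, 1)")
        if not 0.0 <= self.shrinkage_weight <= 1.0:
            raise ValueError("shrinkage_weight must be in [0, 1]")


def smooth_proportions(
    sites: pd.DataFrame,
    window: float = 500.0,
    circular: bool = True,
    genome_length: int | None = None,
) -> pd.DataFrame:
    """Coverage-weighted smoothing of beta over +-window/2 bp per strand.

    Returns a copy of ``sites`` with a ``beta_smooth`` column. On a circular
    chromosome the window wraps; ``genome_length`` is then required.
    """
    if circular and genome_length is None:
        raise ValueError("genome_length required for circular smoothing")
    half = window / 2.0
    out = sites.copy()
    out["beta_smooth"] = np.nan
    for _, idx in out.groupby(["chrom", "molecule_strand"], sort=False).groups.items():
        grp = out.loc[idx].sort_values("pos")
        pos = grp["pos"].to_numpy(dtype=float)
        w = grp["coverage_called"].to_numpy(dtype=float)
        wb = w * grp["beta"].to_numpy(dtype=float)
        if circular:
            ext_pos = np.concatenate([pos - genome_length, pos, pos + genome_length])
            ext_w = np.tile(w, 3)
            ext_wb = np.tile(wb, 3)
        else:
            ext_pos, ext_w, ext_wb = pos, w, wb
        order = np.argsort(ext_pos)
        ext_pos, ext_w, ext_wb = ext_pos[order], ext_w[order], ext_wb[order]
        cw = np.concatenate([[0.0], np.cumsum(ext_w)])
        cwb = np.concatenate([[0.0], np.cumsum(ext_wb)])
        lo = np.searchsorted(ext_pos, pos - half, side="left")
        hi = np.searchsorted(ext_pos, pos + half, side="right")
        sm = (cwb[hi] - cwb[lo]) / (cw[hi] - cw[lo])
        out.loc[grp.index, "beta_smooth"] = sm
    return out


def _phi_mom(X: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Per-site method-of-moments beta-binomial dispersion from replicates.

    X, N are (sites x replicates). Sites with < 2 replicates or a
    degenerate pooled mean get NaN.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = np.atleast_2d(np.asarray(N, dtype=float))
    n_rep = X.shape[1]
    phi = np.full(X.shape[0], np.nan)
    if n_rep < 2:
        return phi
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = X / N
        p_bar = X.sum(axis=1) / N.sum(axis=1)
        pq = p_bar * (1 - p_bar)
        s2 = p_hat.var(axis=1, ddof=1)
        mean_inv_n = (1.0 / N).mean(axis=1)
        est = (s2 - pq * mean_inv_n) / (pq * (1.0 - mean_inv_n))
    ok = pq > 0
    phi[ok] = np.clip(est[ok], 0.0, 0.99)
    phi[~ok] = 0.0
    return phi


def estimate_dispersion(
    X: np.ndarray, N: np.ndarray, shrinkage_weight: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site dispersion phi, shrunk toward the cross-site median.

    Returns ``(phi_shrunk, phi_raw)``. With a single replicate no per-site
    estimate exists; every site then gets the cross-site median of the raw
    estimates (0 if none exist), with a warning.
    """
    phi_raw = _phi_mom(X, N)
    valid = np.isfinite(phi_raw)
    if not valid.any():
        warnings.warn(
            "no site has >=2 replicates; dispersion fixed to 0 for all sites"
        )
        return np.zeros_like(phi_raw), phi_raw
    med = float(np.median(phi_raw[valid]))
    lam = shrinkage_weight
    shrunk = np.where(valid, lam * med + (1 - lam) * phi_raw, med)
    if (~valid).any():
        warnings.warn(
            f"{int((~valid).sum())} sites lack replicate variance; "
            "dispersion fixed to the cross-site median"
        )
    return shrunk, phi_raw


def _arcsine(X: np.ndarray, N: np.ndarray) -> np.ndarray:
    p_hat = (X + 0.5) / (N + 1.0)
    return np.arcsin(2.0 * p_hat - 1.0)


def _y_variance(N: np.ndarray, phi: np.ndarray) -> np.ndarray:
    # delta method for Y = arcsin(2p-1): (dY/dp)^2 = 1/(p(1-p)), which
    # cancels the mean term of the beta-binomial variance of p-hat
    return (1.0 + (N - 1.0) * phi[:, None]) / N


def _from_arcsine(m: np.ndarray) -> np.ndarray:
    return (np.sin(m) + 1.0) / 2.0


def _align_counts(tables: list[pd.DataFrame]) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Inner-join replicate site tables; returns (keys, X, N) matrices."""
    keys = tables[0][KEY_COLS]
    for t in tables[1:]:
        keys = keys.merge(t[KEY_COLS], on=KEY_COLS, how="inner")
    keys = keys.drop_duplicates().reset_index(drop=True)
    X = np.empty((len(keys), len(tables)))
    N = np.empty_like(X)
    for j, t in enumerate(tables):
        m = keys.merge(t, on=KEY_COLS, how="left")
        X[:, j] = m["n_meth"].to_numpy()
        N[:, j] = m["coverage_called"].to_numpy()
    return keys, X, N


def _pooled_phi(
    X1, N1, X2, N2, shrinkage_weight: float
) -> np.ndarray:
    """Combine per-group MoM dispersions (weighted by df), then shrink."""
    phi1 = _phi_mom(X1, N1)
    phi2 = _phi_mom(X2, N2)
    df1, df2 = max(X1.shape[1] - 1, 0), max(X2.shape[1] - 1, 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        raw = np.nansum(
            np.column_stack([phi1 * df1, phi2 * df2]), axis=1
        ) / np.nansum(
            np.column_stack([np.isfinite(phi1) * df1, np.isfinite(phi2) * df2]),
            axis=1,
        )
    valid = np.isfinite(raw)
    if not valid.any():
        warnings.warn("no replicate variance in either group; dispersion set to 0")
        return np.zeros_like(raw)
    med = float(np.median(raw[valid]))
    lam = shrinkage_weight
    return np.where(valid, lam * med + (1 - lam) * raw, med)


def dml_test(
    group1: list[pd.DataFrame],
    group2: list[pd.DataFrame],
    config: DMLConfig | None = None,
) -> pd.DataFrame:
    """Two-group beta-binomial arcsine Wald test per site.

    ``group1``/``group2`` are lists of replicate site tables (columns
    chrom, pos, molecule_strand, n_meth, coverage_called). Sites are tested
    only where present in every replicate of both groups; missing sites are
    skipped and logged. Returns one row per tested site with group means on
    the proportion scale, diff = mu1 - mu2, the Wald statistic, two-sided
    p, BH fdr and the delta/p significance call.
    """
    config = config or DMLConfig()
    keys1, X1, N1 = _align_counts(group1)
    keys2, X2, N2 = _align_counts(group2)
    keys = keys1.merge(keys2, on=KEY_COLS, how="inner")
    n_union = len(
        pd.concat([keys1, keys2]).drop_duplicates()
    )
    if n_union > len(keys):
        logger.info("%d sites missing from one group; skipped", n_union - len(keys))
    i1 = keys.merge(keys1.reset_index(), on=KEY_COLS)["index"].to_numpy()
    i2 = keys.merge(keys2.reset_index(), on=KEY_COLS)["index"].to_numpy()
    X1, N1, X2, N2 = X1[i1], N1[i1], X2[i2], N2[i2]

    phi = _pooled_phi(X1, N1, X2, N2, config.shrinkage_weight)
    stats_frame = _wald_two_group(X1, N1, X2, N2, phi)
    out = pd.concat([keys.reset_index(drop=True), stats_frame], axis=1)
    out["fdr"] = stats.false_discovery_control(out["p"], method="bh")
    out["significant"] = call_dml(
        out, config.delta, config.p_threshold, config.use_fdr
    )
    return out


def _wald_two_group(X1, N1, X2, N2, phi) -> pd.DataFrame:
    Y1, Y2 = _arcsine(X1, N1), _arcsine(X2, N2)
    v1, v2 = _y_variance(N1, phi), _y_variance(N2, phi)
    w1, w2 = 1.0 / v1, 1.0 / v2
    m1 = (Y1 * w1).sum(axis=1) / w1.sum(axis=1)
    m2 = (Y2 * w2).sum(axis=1) / w2.sum(axis=1)
    se = np.sqrt(1.0 / w1.sum(axis=1) + 1.0 / w2.sum(axis=1))
    wald = (m1 - m2) / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    mu1, mu2 = _from_arcsine(m1), _from_arcsine(m2)
    return pd.DataFrame(
        {
            "mu1": mu1,
            "mu2": mu2,
            "diff": mu1 - mu2,
            "diff_y": m1 - m2,
            "se_diff": se,
            "wald": wald,
            "p": p,
        }
    )


def _phi_paired(
    X: np.ndarray, N: np.ndarray, is_tumor: np.ndarray, shrinkage_weight: float
) -> np.ndarray:
    """Dispersion from the variance of within-pair arcsine differences.

    For pair i, d_i = Y_T - Y_N has variance v_T + v_N, i.e.
    (1/N_T + 1/N_N) + phi * (2 - 1/N_T - 1/N_N); patient main effects and
    any common group shift cancel in the pairwise difference, so only
    replicate-level overdispersion enters.
    """
    Y = _arcsine(X, N)
    d = Y[:, is_tumor == 1] - Y[:, is_tumor == 0]
    inv = 1.0 / N[:, is_tumor == 1] + 1.0 / N[:, is_tumor == 0]
    n_pairs = d.shape[1]
    if n_pairs < 2:
        warnings.warn(
            "a single pair provides no replicate variance; dispersion set to 0"
        )
        return np.zeros(X.shape[0])
    s2 = d.var(axis=1, ddof=1)
    mean_inv = inv.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (s2 - mean_inv) / (2.0 - mean_inv)
    raw = np.clip(raw, 0.0, 0.99)
    med = float(np.median(raw))
    lam = shrinkage_weight
    return lam * med + (1 - lam) * raw


def dml_test_paired(
    pairs: list[tuple[pd.DataFrame, pd.DataFrame]],
    config: DMLConfig | None = None,
) -> pd.DataFrame:
    """Paired (multifactor) test: WLS of Y on [intercept, patient, group].

    ``pairs`` is a list of (tumor, normal) site-table pairs, one per
    patient. Per site, arcsine-transformed proportions from all members are
    regressed on an intercept, patient indicators and the tumor/normal
    contrast, with weights 1/v; the Wald test is on the group coefficient.
    With a single pair the design degenerates to [intercept, group] (still
    full rank, but dispersion cannot be estimated and falls back to 0 with
    a warning). Sites with a rank-deficient design are skipped and logged.
    """
    config = config or DMLConfig()
    if len(pairs) < 1:
        raise ValueError("paired test requires at least 1 pair")
    tables = [t for pair in pairs for t in pair]  # T0, N0, T1, N1, ...
    keys, X, N = _align_counts(tables)
    if not len(keys):
        raise ValueError("no site is present in every member of every pair")
    n_pairs = len(pairs)
    n_obs = 2 * n_pairs
    is_tumor = np.tile([1.0, 0.0], n_pairs)
    patient = np.repeat(np.arange(n_pairs), 2)
    design = np.ones((n_obs, 1 + (n_pairs - 1) + 1))
    for j in range(1, n_pairs):
        design[:, j] = (patient == j).astype(float)
    design[:, -1] = is_tumor

    # dispersion from within-pair differences: patient baselines cancel,
    # so between-subject variability does not inflate phi
    phi = _phi_paired(X, N, is_tumor, config.shrinkage_weight)
    Y = _arcsine(X, N)
    V = _y_variance(N, phi)

    n_sites = len(keys)
    coef = np.full(n_sites, np.nan)
    se = np.full(n_sites, np.nan)
    m_normal = np.full(n_sites, np.nan)
    skipped = 0
    for s in range(n_sites):
        w = 1.0 / V[s]
        A = design * np.sqrt(w)[:, None]
        y = Y[s] * np.sqrt(w)
        ata = A.T @ A
        if np.linalg.matrix_rank(ata) < ata.shape[0]:
            skipped += 1
            continue
        ata_inv = np.linalg.inv(ata)
        b = ata_inv @ (A.T @ y)
        coef[s] = b[-1]
        se[s] = np.sqrt(ata_inv[-1, -1])
        wn = w[is_tumor == 0]
        m_normal[s] = (Y[s][is_tumor == 0] * wn).sum() / wn.sum()
    if skipped:
        logger.info("%d sites skipped (rank-deficient paired design)", skipped)

    ok = np.isfinite(coef)
    wald = coef / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    mu2 = _from_arcsine(m_normal)
    mu1 = _from_arcsine(m_normal + coef)
    out = pd.concat(
        [
            keys.reset_index(drop=True),
            pd.DataFrame(
                {
                    "mu1": mu1,
                    "mu2": mu2,
                    "diff": mu1 - mu2,
                    "diff_y": coef,
                    "se_diff": se,
                    "wald": wald,
                    "p": p,
                }
            ),
        ],
        axis=1,
    )[ok]
    out = out.reset_index(drop=True)
    out["fdr"] = stats.false_discovery_control(out["p"], method="bh")
    out["significant"] = call_dml(out, config.delta, config.p_threshold, config.use_fdr)
    return out


def call_dml(
    results: pd.DataFrame,
    delta: float = 0.05,
    p_threshold: float = 0.05,
    use_fdr: bool = False,
) -> pd.Series:
    """Significance gate: |diff| >= delta AND (p or fdr) < threshold."""
    pvals = results["fdr"] if use_fdr else results["p"]
    return (results["diff"].abs() >= delta) & (pvals < p_threshold)


def global_compare(a, b, paired: bool = False) -> tuple[float, float]:
    """Compare two beta distributions globally.

    Unpaired: Mann-Whitney U (exact for both n <= 25, otherwise normal
    approximation with continuity correction). Paired: Wilcoxon signed-rank
    on matched values; identical vectors return p = 1 by convention.
    Returns (statistic, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires matched vectors")
        d = a - b
        informative = d[d != 0]
        if a.size < 3:
            raise ValueError("need >= 3 observations for a global comparison")
        if informative.size == 0:
            return 0.0, 1.0
        if informative.size < 3:
            raise ValueError("need >= 3 informative (nonzero) paired differences")
        method = "exact" if informative.size <= 25 else "approx"
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                             alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if min(a.size, b.size) < 3:
        raise ValueError("need >= 3 observations per sample")
    method = "exact" if max(a.size, b.size) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)
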