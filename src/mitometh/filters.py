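"""Safety filters applied before comparative analyses.

Two sources of bias are screened out. NUMTs (nuclear copies of mitochondrial
DNA) produce short reads that misalign to the mitochondrial genome and carry
nuclear methylation levels; removing every read whose aligned span is below
the longest known NUMT (8798 bp) eliminates them, since a genuine
full-length mitochondrial molecule spans the whole ~16.5 kb circle. Coverage
differences are neutralized by keeping only sites with called coverage of at
least ``min_cov`` in every sample. A separate helper extracts the calls or
sites falling inside NUMT regions for a parallel, NUMT-only analysis.

Read spans on the circular genome are wrap-aware: the span is the shortest
arc containing all of the read's calls, so a full-length read whose
coordinates wrap past the origin is not penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .formats_io import Region

DEFAULT_MIN_READ_LENGTH = 8798
DEFAULT_MIN_COVERAGE = 10


@dataclass
class FilterReport:
    """Bookkeeping for one filter pass; counts reconcile with row counts."""

    n_input: int = 0
    n_removed_length: int = 0
    n_removed_coverage: int = 0
    n_in_numt_regions: int = 0
    thresholds: dict = field(default_factory=dict)


def _circular_span(points: np.ndarray, genome_length: int) -> int:
    """Shortest arc on the circle containing all points."""
    pts = np.unique(points % genome_length)
    if pts.size == 1:
        return 0
    gaps = np.diff(pts)
    wrap_gap = genome_length - pts[-1] + pts[0]
    return int(genome_length - max(gaps.max(initial=0), wrap_gap))


def read_spans(
    calls: pd.DataFrame, genome_length: int | None = None, circular: bool = True
) -> pd.Series:
    """Aligned span per read: max end - min start over its calls, wrap-aware."""
    if circular and genome_length is None:
        raise ValueError("genome_length is required for circular span computation")
    spans = {}
    for read_id, grp in calls.groupby("read_name", sort=False):
        pts = np.concatenate([grp["start"].to_numpy(), grp["end"].to_numpy()])
        if circular:
            spans[read_id] = _circular_span(pts, genome_length)
        else:
            spans[read_id] = int(pts.max() - pts.min())
    return pd.Series(spans, name="span", dtype=int)


def filter_read_length(
    calls: pd.DataFrame,
    min_len: int = DEFAULT_MIN_READ_LENGTH,
    genome_length: int | None = None,
    circular: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove all calls of reads whose aligned span is below ``min_len``.

    The boundary is inclusive on the survivor side: a span of exactly
    ``min_len`` is retained ("below 8798 bp" removes strictly shorter reads).
    """
    report = FilterReport(thresholds={"min_read_length": min_len})
    if not len(calls):
        return calls.copy(), report
    spans = read_spans(calls, genome_length, circular)
    keep_ids = set(spans.index[spans >= min_len])
    report.n_input = int(spans.size)
    report.n_removed_length = int(spans.size - len(keep_ids))
    survivors = calls[calls["read_name"].isin(keep_ids)].reset_index(drop=True)
    return survivors, report


def filter_coverage(
    site_tables: Mapping[str, pd.DataFrame], min_cov: int = DEFAULT_MIN_COVERAGE
) -> tuple[set[tuple], FilterReport]:
    """Keep site keys with called coverage >= min_cov in EVERY sample.

    A site absent from a sample has coverage 0 there and is removed. The
    boundary is inclusive: coverage exactly ``min_cov`` everywhere survives
    ("less than 10x" removes strictly lower coverage). Returns the retained
    (chrom, pos, molecule_strand) keys and a report.
    """
    if not site_tables:
        raise ValueError("filter_coverage needs at least one sample table")
    report = FilterReport(thresholds={"min_coverage": min_cov})
    key_cols = ["chrom", "pos", "molecule_strand"]
    all_keys: set[tuple] = set()
    per_sample: list[dict] = []
    for table in site_tables.values():
        cov = dict(
            zip(
                map(tuple, table[key_cols].itertuples(index=False)),
                table["coverage_called"],
            )
        )
        per_sample.append(cov)
        all_keys.update(cov)
    retained = {
        key
        for key in all_keys
        if all(cov.get(key, 0) >= min_cov for cov in per_sample)
    }
    report.n_input = len(all_keys)
    report.n_removed_coverage = len(all_keys) - len(retained)
    return retained, report


def apply_coverage_filter(
    site_tables: Mapping[str, pd.DataFrame], min_cov: int = DEFAULT_MIN_COVERAGE
) -> tuple[dict[str, pd.DataFrame], FilterReport]:
    """Convenience wrapper: subset every sample table to the retained keys."""
    retained, report = filter_coverage(site_tables, min_cov)
    key_cols = ["chrom", "pos", "molecule_strand"]
    out = {}
    for name, table in site_tables.items():
        mask = [
            tuple(k) in retained for k in table[key_cols].itertuples(index=False)
        ]
        out[name] = table[mask].reset_index(drop=True)
    return out, report


def _merged_intervals(regions: Iterable[Region]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.array(starts), np.array(ends))
    return merged


def numt_subset(
    table: pd.DataFrame, numt_regions: Iterable[Region], pos_col: str | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Subset calls or sites whose position falls inside any NUMT region.

    Uses half-open containment of the (single-base) position: pos in
    [start, end). ``pos_col`` defaults to 'pos' if present, else 'start'.
    """
    if pos_col is None:
        pos_col = "pos" if "pos" in table.columns else "start"
    chrom_col = "chrom" if "chrom" in table.columns else "chromosome"
    merged = _merged_intervals(numt_regions)
    mask = np.zeros(len(table), dtype=bool)
    pos = table[pos_col].to_numpy()
    chroms = table[chrom_col].to_numpy()
    for chrom, (starts, ends) in merged.items():
        on_chrom = chroms == chrom
        if not on_chrom.any():
            continue
        idx = np.searchsorted(starts, pos[on_chrom], side="right") - 1
        inside = (idx >= 0) & (pos[on_chrom] < ends[np.clip(idx, 0, None)])
        mask[np.flatnonzero(on_chrom)[inside]] = True
    report = FilterReport(
        n_input=len(table),
        n_in_numt_regions=int(mask.sum()),
        thresholds={"overlap": "position containment, half-open"},
    )
    return table[mask].reset_index(drop=True), report
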