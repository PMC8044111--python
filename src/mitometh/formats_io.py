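"""Readers and writers for the tabular formats the pipeline exchanges.

All coordinates are 0-based, half-open internally (BED-native). Methylation
call tables follow the nanopolish TSV dialect (11 columns, tab-separated,
'.' decimal, plain header row). Frequency tables serialize the modified
frequency with six decimals so round-trips are bit-stable.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd


class FormatError(ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class RowError(ValueError):
    """A single data row failed to parse; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class MotifMismatchError(ValueError):
    """Group sequence and reference disagree when splitting a motif group."""


METHCALL_COLUMNS = (
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "log_lik_methylated",
    "log_lik_unmethylated",
    "num_calling_strands",
    "num_motifs",
    "sequence",
)

FREQUENCY_COLUMNS = (
    "chromosome",
    "start",
    "end",
    "num_motifs_in_group",
    "called_sites",
    "called_sites_methylated",
    "methylated_frequency",
    "group_sequence",
)


@dataclass(frozen=True)
class MethCallRecord:
    """One per-read, per-motif-group methylation call with LLR evidence.

    ``llr`` is the natural-log likelihood ratio of the methylated over the
    unmethylated state; positive values support methylation. ``start`` and
    ``end`` are the 0-based positions of the first and last motif cytosine
    in the group.
    """

    chrom: str
    strand: str
    start: int
    end: int
    read_id: str
    llr: float
    ll_meth: float | None = None
    ll_unmeth: float | None = None
    n_motifs: int = 1
    context_seq: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.n_motifs < 1:
            raise ValueError(f"n_motifs must be >= 1, got {self.n_motifs}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.ll_meth is not None and self.ll_unmeth is not None:
            if abs(self.llr - (self.ll_meth - self.ll_unmeth)) > 1e-6:
                raise ValueError(
                    "llr inconsistent with ll_meth - ll_unmeth: "
                    f"{self.llr} vs {self.ll_meth} - {self.ll_unmeth}"
                )


@dataclass(frozen=True)
class FrequencyRow:
    """Per-site (or per-group) methylated-call frequency over called reads."""

    chrom: str
    start: int
    end: int
    n_motifs_in_group: int
    called_sites: int
    called_sites_methylated: int
    modified_frequency: float
    group_sequence: str = ""

    def __post_init__(self):
        if self.called_sites_methylated > self.called_sites:
            raise ValueError(
                f"called_sites_methylated ({self.called_sites_methylated}) > "
                f"called_sites ({self.called_sites})"
            )
        if not 0.0 <= self.modified_frequency <= 1.0:
            raise ValueError(
                f"modified_frequency outside [0,1]: {self.modified_frequency}"
            )
        if self.called_sites > 0:
            expected = self.called_sites_methylated / self.called_sites
            if abs(self.modified_frequency - expected) > 1e-6:
                raise ValueError(
                    f"modified_frequency {self.modified_frequency} != "
                    f"{self.called_sites_methylated}/{self.called_sites}"
                )


@dataclass(frozen=True)
class Region:
    """Genomic interval, 0-based half-open, tagged with the set it came from."""

    chrom: str
    start: int
    end: int
    name: str = ""
    set_label: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) <= start ({self.start})")


@dataclass(frozen=True)
class CtPair:
    """One qMSP measurement: Ct values from methylated and unmethylated primers."""

    sample_id: str
    locus_id: str
    ct_methylated: float
    ct_unmethylated: float

    def __post_init__(self):
        for label, ct in (("ct_m", self.ct_methylated), ("ct_u", self.ct_unmethylated)):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{label} must be finite and > 0, got {ct}")


def _check_header(header: list[str], required: Iterable[str], path) -> dict[str, int]:
    index = {name: i for i, name in enumerate(header)}
    for col in required:
        if col not in index:
            raise FormatError(f"{path}: missing required column {col!r}")
    return index


def read_methcall_tsv(path) -> Iterator[MethCallRecord]:
    """Stream per-read methylation calls from a nanopolish-dialect TSV.

    Yields one :class:`MethCallRecord` per data line, in file order.
    Raises :class:`FormatError` on a missing column and :class:`RowError`
    (with the line number) on an unparseable row.
    """
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        idx = _check_header(header, METHCALL_COLUMNS, path)
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                yield MethCallRecord(
                    chrom=row[idx["chromosome"]],
                    strand=row[idx["strand"]],
                    start=int(row[idx["start"]]),
                    end=int(row[idx["end"]]),
                    read_id=row[idx["read_name"]],
                    llr=float(row[idx["log_lik_ratio"]]),
                    ll_meth=float(row[idx["log_lik_methylated"]]),
                    ll_unmeth=float(row[idx["log_lik_unmethylated"]]),
                    n_motifs=int(row[idx["num_motifs"]]),
                    context_seq=row[idx["sequence"]],
                )
            except (ValueError, IndexError) as exc:
                raise RowError(str(exc), line_no) from exc


def methcalls_to_frame(records: Iterable[MethCallRecord]) -> pd.DataFrame:
    """Collect call records into the canonical 11-column DataFrame."""
    rows = [
        (
            r.chrom,
            r.strand,
            r.start,
            r.end,
            r.read_id,
            r.llr,
            r.llr if r.ll_meth is None else r.ll_meth,
            0.0 if r.ll_unmeth is None else r.ll_unmeth,
            1,
            r.n_motifs,
            r.context_seq,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=METHCALL_COLUMNS)


def frame_to_methcalls(frame: pd.DataFrame) -> Iterator[MethCallRecord]:
    for row in frame.itertuples(index=False):
        yield MethCallRecord(
            chrom=row.chromosome,
            strand=row.strand,
            start=int(row.start),
            end=int(row.end),
            read_id=row.read_name,
            llr=float(row.log_lik_ratio),
            ll_meth=float(row.log_lik_methylated),
            ll_unmeth=float(row.log_lik_unmethylated),
            n_motifs=int(row.num_motifs),
            context_seq=row.sequence,
        )


def write_methcall_tsv(calls, path) -> None:
    """Write calls (DataFrame or iterable of records) in the nanopolish dialect."""
    if not isinstance(calls, pd.DataFrame):
        calls = methcalls_to_frame(calls)
    calls.to_csv(path, sep="\t", index=False, columns=list(METHCALL_COLUMNS))


def _resolve_sequence(ref, chrom: str) -> str:
    if isinstance(ref, str):
        return ref
    seq = ref[chrom]
    return str(seq)


def split_motif_groups(record: MethCallRecord, ref) -> list[MethCallRecord]:
    """Split a grouped CpG call into single-site records inheriting its LLR.

    ``ref`` is either the chromosome sequence itself or a mapping from
    chromosome name to sequence (a ``pyfaidx.Fasta`` works). Positions of
    the individual CG motifs are located on the reference between the
    group's first and last motif, inclusive.
    """
    if record.n_motifs == 1:
        return [record]
    seq = _resolve_sequence(ref, record.chrom).upper()
    positions = [
        p
        for p in range(record.start, record.end + 1)
        if seq[p : p + 2] == "CG"
    ]
    if len(positions) != record.n_motifs:
        raise MotifMismatchError(
            f"expected {record.n_motifs} CG motifs in reference slice "
            f"{seq[record.start:record.end + 2]!r} (positions {record.start}-"
            f"{record.end}), found {len(positions)}; group sequence was "
            f"{record.context_seq!r}"
        )
    return [
        replace(
            record,
            start=p,
            end=p,
            n_motifs=1,
            context_seq=seq[max(p - 5, 0) : p + 6],
        )
        for p in positions
    ]


def write_frequency_tsv(rows: Iterable[FrequencyRow], path) -> None:
    """Write frequency rows; rejects rows with zero called sites."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FREQUENCY_COLUMNS)
        for row in rows:
            if row.called_sites == 0:
                raise ValueError(
                    f"row at {row.chrom}:{row.start} has called_sites == 0; "
                    "zero-coverage sites are omitted, not serialized"
                )
            writer.writerow(
                (
                    row.chrom,
                    row.start,
                    row.end,
                    row.n_motifs_in_group,
                    row.called_sites,
                    row.called_sites_methylated,
                    f"{row.modified_frequency:.6f}",
                    row.group_sequence,
                )
            )


def read_frequency_tsv(path) -> list[FrequencyRow]:
    """Read a frequency TSV back into validated rows."""
    rows: list[FrequencyRow] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        idx = _check_header(header, FREQUENCY_COLUMNS, path)
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                freq = float(row[idx["methylated_frequency"]])
                if not 0.0 <= freq <= 1.0:
                    raise ValueError(f"methylated_frequency outside [0,1]: {freq}")
                called = int(row[idx["called_sites"]])
                meth = int(row[idx["called_sites_methylated"]])
                # serialized with 6 decimals; re-derive to preserve invariant
                rows.append(
                    FrequencyRow(
                        chrom=row[idx["chromosome"]],
                        start=int(row[idx["start"]]),
                        end=int(row[idx["end"]]),
                        n_motifs_in_group=int(row[idx["num_motifs_in_group"]]),
                        called_sites=called,
                        called_sites_methylated=meth,
                        modified_frequency=meth / called if called else freq,
                        group_sequence=row[idx["group_sequence"]],
                    )
                )
            except ValueError as exc:
                raise RowError(str(exc), line_no) from exc
    return rows


def read_bed(path, set_label: str = "") -> list[Region]:
    """Read a BED3+ file into labeled, validated regions (0-based half-open)."""
    regions: list[Region] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RowError(f"expected >=3 BED columns, got {len(fields)}", line_no)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise RowError(str(exc), line_no) from exc
            if end <= start:
                raise RowError(f"end ({end}) <= start ({start})", line_no)
            regions.append(
                Region(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3] if len(fields) > 3 else "",
                    set_label=set_label,
                )
            )
    return regions


def write_bed(regions: Iterable[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


def read_ct_tsv(path) -> list[CtPair]:
    """Read qMSP Ct pairs (columns sample_id, locus_id, ct_m, ct_u)."""
    pairs: list[CtPair] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        idx = _check_header(header, ("sample_id", "locus_id", "ct_m", "ct_u"), path)
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                pairs.append(
                    CtPair(
                        sample_id=row[idx["sample_id"]],
                        locus_id=row[idx["locus_id"]],
                        ct_methylated=float(row[idx["ct_m"]]),
                        ct_unmethylated=float(row[idx["ct_u"]]),
                    )
                )
            except ValueError as exc:
                raise RowError(str(exc), line_no) from exc
    return pairs


def read_array_beta_tsv(path) -> pd.DataFrame:
    """Read a methylation-array beta table (probe_id, chrom, pos, beta)."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("probe_id", "chrom", "pos", "beta"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    bad = frame[(frame["beta"] < 0) | (frame["beta"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: {len(bad)} beta values outside [0,1]")
    return frame


def load_reference(fasta_path) -> Mapping[str, str]:
    """Load a FASTA reference as a chrom -> uppercase sequence mapping."""
    import pyfaidx

    fasta = pyfaidx.Fasta(str(fasta_path))
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}
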