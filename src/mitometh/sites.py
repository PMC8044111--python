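"""Strand-resolved per-site summaries of single-molecule methylation calls.

Per-read calls are thresholded on the log-likelihood ratio (methylated iff
llr >= t, unmethylated iff llr <= -t, ambiguous in between), then grouped by
(position, molecule strand) into counts and a beta value — the proportion of
methylated calls among called reads at the site. Ambiguous calls are counted
but excluded from the beta denominator; sites with no called reads are
omitted. Reference '+' maps to the mitochondrial light (L) strand by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .formats_io import MethCallRecord, methcalls_to_frame

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_LLR_THRESHOLD = 2.0


class ContextError(ValueError):
    """The queried position does not hold a cytosine on the given strand."""


def call_read_site(llr: float, threshold: float = DEFAULT_LLR_THRESHOLD) -> str:
    """Classify one read-level call: 'methylated', 'unmethylated' or 'ambiguous'.

    The boundary is inclusive: llr == threshold counts as methylated,
    llr == -threshold as unmethylated. Non-finite llr is ambiguous.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if not np.isfinite(llr):
        warnings.warn(f"non-finite llr ({llr}); treated as ambiguous")
        return "ambiguous"
    if llr >= threshold:
        return "methylated"
    if llr <= -threshold:
        return "unmethylated"
    return "ambiguous"


def call_read_sites(llr: np.ndarray, threshold: float = DEFAULT_LLR_THRESHOLD) -> np.ndarray:
    """Vectorized thresholding: +1 methylated, -1 unmethylated, 0 ambiguous."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    llr = np.asarray(llr, dtype=float)
    bad = ~np.isfinite(llr)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} non-finite llr values treated as ambiguous")
    out = np.zeros(llr.shape, dtype=np.int8)
    out[np.where(~bad & (llr >= threshold))] = 1
    out[np.where(~bad & (llr <= -threshold))] = -1
    return out


def assign_molecule_strand(record_strand: str, plus_is: str = "L") -> str:
    """Map a reference strand symbol (+/-) to the molecule strand (L/H)."""
    if plus_is not in ("L", "H"):
        raise ValueError(f"plus_is must be 'L' or 'H', got {plus_is!r}")
    other = "H" if plus_is == "L" else "L"
    if record_strand == "+":
        return plus_is
    if record_strand == "-":
        return other
    raise ValueError(f"unknown strand symbol {record_strand!r}")


def classify_context(
    seq: str,
    pos: int,
    molecule_strand: str = "L",
    plus_is: str = "L",
    circular: bool = True,
) -> tuple[str, str]:
    """Classify the cytosine at ``pos`` as CpG or CpH with a CAC/CAG subcontext.

    ``pos`` is a forward-reference coordinate; the base there must be 'C'
    for a molecule strand mapping to '+', or 'G' for one mapping to '-'
    (the cytosine then lives on the reverse strand). The trimer is read
    5'->3' on the molecule strand. Returns (context, subcontext) where
    context is 'CpG' or 'CpH' and subcontext is 'CAC', 'CAG', 'other' for
    CpH and 'NA' for CpG.
    """
    n = len(seq)
    ref_strand = "+" if molecule_strand == plus_is else "-"
    if ref_strand == "+":
        if seq[pos].upper() != "C":
            raise ContextError(f"position {pos} holds {seq[pos]!r}, expected 'C' (+)")
        if circular:
            trimer = "".join(seq[(pos + k) % n] for k in range(3)).upper()
        else:
            trimer = seq[pos : pos + 3].upper()
    else:
        if seq[pos].upper() != "G":
            raise ContextError(
                f"position {pos} holds {seq[pos]!r}, expected 'G' (reverse-strand C)"
            )
        if circular:
            raw = "".join(seq[(pos - k) % n] for k in range(3)).upper()
        else:
            raw = seq[max(pos - 2, 0) : pos + 1][::-1].upper()
        trimer = raw.translate(_COMPLEMENT)
    if len(trimer) >= 2 and trimer[1] == "G":
        return "CpG", "NA"
    if trimer in ("CAC", "CAG"):
        return "CpH", trimer
    return "CpH", "other"


def summarize_sites(
    calls,
    threshold: float = DEFAULT_LLR_THRESHOLD,
    ref=None,
    plus_is: str = "L",
    circular: bool = True,
) -> pd.DataFrame:
    """Aggregate single-site calls into a strand-resolved site table.

    ``calls`` is a nanopolish-dialect DataFrame or an iterable of
    single-site :class:`MethCallRecord` (grouped records must be split
    first). Returns one row per (chrom, pos, molecule_strand) with counts
    of methylated / unmethylated / ambiguous calls, called coverage, beta,
    and — when ``ref`` (chrom -> sequence mapping or a single sequence) is
    given — the CpG/CpH context and CAC/CAG subcontext.
    """
    if not isinstance(calls, pd.DataFrame):
        calls = methcalls_to_frame(calls)
    if len(calls) and (calls["num_motifs"] > 1).any():
        raise ValueError(
            "summarize_sites expects single-site calls; split motif groups first"
        )
    if not len(calls):
        return pd.DataFrame(
            columns=["chrom", "pos", "molecule_strand", "context", "subcontext",
                     "n_meth", "n_unmeth", "n_ambiguous", "coverage_called", "beta"]
        )
    codes = call_read_sites(calls["log_lik_ratio"].to_numpy(), threshold)
    frame = pd.DataFrame(
        {
            "chrom": calls["chromosome"].to_numpy(),
            "pos": calls["start"].to_numpy(),
            "strand": calls["strand"].to_numpy(),
            "meth": codes == 1,
            "unmeth": codes == -1,
            "amb": codes == 0,
        }
    )
    grouped = (
        frame.groupby(["chrom", "pos", "strand"], sort=True, observed=True)[
            ["meth", "unmeth", "amb"]
        ]
        .sum()
        .reset_index()
        .rename(columns={"meth": "n_meth", "unmeth": "n_unmeth", "amb": "n_ambiguous"})
    )
    grouped["coverage_called"] = grouped["n_meth"] + grouped["n_unmeth"]
    grouped = grouped[grouped["coverage_called"] > 0].reset_index(drop=True)
    grouped["beta"] = grouped["n_meth"] / grouped["coverage_called"]
    grouped["molecule_strand"] = [
        assign_molecule_strand(s, plus_is) for s in grouped["strand"]
    ]

    if ref is not None:
        contexts, subcontexts = [], []
        for chrom, pos, mol in zip(grouped["chrom"], grouped["pos"],
                                   grouped["molecule_strand"]):
            seq = ref if isinstance(ref, str) else str(ref[chrom])
            ctx, sub = classify_context(seq, int(pos), mol, plus_is, circular)
            contexts.append(ctx)
            subcontexts.append(sub)
        grouped["context"] = contexts
        grouped["subcontext"] = subcontexts
    else:
        grouped["context"] = "NA"
        grouped["subcontext"] = "NA"

    return grouped[
        ["chrom", "pos", "molecule_strand", "context", "subcontext",
         "n_meth", "n_unmeth", "n_ambiguous", "coverage_called", "beta"]
    ]


def write_site_summary_tsv(sites: pd.DataFrame, path) -> None:
    out = sites.copy()
    out["beta"] = out["beta"].map(lambda b: f"{b:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_site_summary_tsv(path) -> pd.DataFrame:
    sites = pd.read_csv(path, sep="\t")
    if ((sites["beta"] < 0) | (sites["beta"] > 1)).any():
        raise ValueError(f"{path}: beta values outside [0,1]")
    return sites
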