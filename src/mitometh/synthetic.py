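"""Synthetic single-molecule methylation calls on a circular mitochondrial genome.

The generator emulates the statistical structure of nanopore 5mC calling on
mtDNA without touching raw signal: reads are whole molecules linearized at an
enzymatic cut site, each representing either the heavy (H) or light (L)
strand; every cytosine the molecule covers receives a log-likelihood-ratio
call drawn from a two-component Gaussian emitter (positive mean if the true
state is methylated, negative otherwise). Control modes reproduce the
calibration samples used in practice:

* ``FU`` — whole-genome-amplified, fully unmethylated DNA (per-site
  methylation probability ε, default 0);
* ``FM`` — M.SssI-treated DNA: CpG sites near-fully methylated, with a
  fraction of reads escaping treatment entirely (enzyme inefficiency);
* ``tissue`` — arbitrary per-site, per-strand methylation probabilities.

NUMT decoy reads (nuclear mitochondrial inserts misaligned to mtDNA) are
emitted as linear sub-genome-length reads so the read-length filter can be
exercised against known truth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class ReadLengthModel:
    """Read lengths: a fraction of full-length molecules, the rest Gaussian."""

    full_length_fraction: float = 1.0
    mean: float = 12000.0
    sd: float = 2000.0
    min_length: int = 200


@dataclass
class EmissionModel:
    """Two-component Gaussian LLR emitter: N(+mu, sigma) vs N(-mu, sigma)."""

    mu: float = 4.0
    sigma: float = 2.5


@dataclass
class NumtDecoyConfig:
    """Linear decoy reads mimicking nuclear mitochondrial inserts."""

    count: int = 0
    length_bp: int = 8798
    meth_prob: float = 0.8


@dataclass
class SimConfig:
    """Full parameterization of the synthetic call generator."""

    genome_length: int = 16569
    cut_site: int = 0
    n_reads: int = 50
    read_length_model: ReadLengthModel = field(default_factory=ReadLengthModel)
    strand_h_fraction: float = 0.5
    site_meth_prob: float | Mapping[str, np.ndarray] | None = None
    fu_epsilon: float = 0.0
    fm_level: float = 1.0
    fm_failure_fraction: float = 0.05
    emission: EmissionModel = field(default_factory=EmissionModel)
    numt_decoys: NumtDecoyConfig = field(default_factory=NumtDecoyConfig)
    gc_content: float = 0.44
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        for name in ("strand_h_fraction", "fu_epsilon", "fm_level",
                     "fm_failure_fraction", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.numt_decoys.meth_prob <= 1.0:
            raise ValueError("numt_decoys.meth_prob must be in [0,1]")
        if self.numt_decoys.count > 0 and self.numt_decoys.length_bp >= self.genome_length:
            raise ValueError("numt_decoys.length_bp must be < genome_length")


@dataclass
class Reference:
    """A synthetic circular reference with pre-indexed cytosine positions."""

    seq: str
    circular: bool = True
    name: str = "chrM"

    def __post_init__(self):
        arr = np.frombuffer(self.seq.encode(), dtype="S1")
        self._is_c = arr == b"C"
        self._is_g = arr == b"G"

    def __len__(self) -> int:
        return len(self.seq)

    def cytosine_positions(self, strand: str) -> np.ndarray:
        """Forward-coordinate positions holding a C on the given reference strand."""
        if strand == "+":
            return np.flatnonzero(self._is_c)
        if strand == "-":
            return np.flatnonzero(self._is_g)
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    def cpg_positions(self, strand: str = "+") -> np.ndarray:
        """Positions of the CpG cytosine on the given strand (forward coords)."""
        n = len(self.seq)
        nxt = np.roll(self._is_g, -1) if self.circular else np.append(self._is_g[1:], False)
        fwd = np.flatnonzero(self._is_c & nxt)
        if strand == "+":
            return fwd
        # reverse-strand CpG C sits opposite the forward G of the same CG
        return (fwd + 1) % n if self.circular else fwd + 1

    def cph_positions(self, strand: str) -> np.ndarray:
        cs = self.cytosine_positions(strand)
        return np.setdiff1d(cs, self.cpg_positions(strand), assume_unique=True)

    def context(self, pos: int, strand: str) -> str:
        """Strand-aware trimer starting at the cytosine (5'->3')."""
        n = len(self.seq)
        if strand == "+":
            idx = [(pos + k) % n for k in range(3)]
            return "".join(self.seq[i] for i in idx)
        idx = [(pos - k) % n for k in range(3)]
        return "".join(self.seq[i] for i in idx).translate(_COMPLEMENT)


def make_reference(
    genome_length: int = 16569,
    seed: int = 0,
    gc_content: float = 0.44,
    alphabet: str = "ACGT",
    circular: bool = True,
    name: str = "chrM",
) -> Reference:
    """Generate a deterministic random circular reference sequence.

    ``alphabet`` can be overridden (e.g. to "AT") to produce degenerate
    references with no cytosines at all.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    rng = np.random.default_rng(seed)
    probs = {
        "A": (1 - gc_content) / 2,
        "T": (1 - gc_content) / 2,
        "C": gc_content / 2,
        "G": gc_content / 2,
    }
    letters = list(alphabet)
    p = np.array([probs[b] for b in letters])
    p = p / p.sum()
    seq = "".join(rng.choice(letters, size=genome_length, p=p))
    return Reference(seq=seq, circular=circular, name=name)


@dataclass
class SimTruth:
    """Ground truth for a simulated sample.

    ``reads`` has one row per read: read_id, molecule_strand (L/H), start,
    length, is_numt, fm_failure, n_true_meth. ``site_prob`` maps reference
    strand ('+'/'-') to the per-site methylation probability aligned with
    ``site_positions`` of the same strand.
    """

    reads: pd.DataFrame
    site_positions: dict[str, np.ndarray]
    site_prob: dict[str, np.ndarray]
    reference: Reference
    mode: str


def _site_prob_vectors(config: SimConfig, ref: Reference, mode: str) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for strand in "+-":
        pos = ref.cytosine_positions(strand)
        if mode == "FU":
            p = np.full(pos.size, config.fu_epsilon)
        elif mode == "FM":
            # M.SssI methylates CpG only; CpH stays at the FU floor
            p = np.full(pos.size, config.fu_epsilon)
            cpg = ref.cpg_positions(strand)
            p[np.isin(pos, cpg)] = config.fm_level
        elif mode == "tissue":
            smp = config.site_meth_prob
            if smp is None:
                p = np.full(pos.size, 0.01)
            elif np.isscalar(smp):
                p = np.full(pos.size, float(smp))
            else:
                p = np.asarray(smp[strand], dtype=float)
                if p.shape != pos.shape:
                    raise ValueError(
                        f"site_meth_prob[{strand!r}] has length {p.size}, "
                        f"expected {pos.size} (one per cytosine on that strand)"
                    )
        else:
            raise ValueError(f"mode must be FU, FM or tissue, got {mode!r}")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("site methylation probabilities must be in [0,1]")
        out[strand] = p
    return out


# molecule-strand convention: reference '+' carries the L strand by default
_STRAND_SYMBOL = {"L": "+", "H": "-"}


def simulate_calls(
    config: SimConfig,
    mode: str = "tissue",
    reference: Reference | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate per-read single-site methylation calls.

    Returns a nanopolish-dialect call table (one row per read x covered
    cytosine, ``num_motifs`` always 1) and the :class:`SimTruth` used to
    generate it. Fully reproducible from ``config.seed``.
    """
    mode = mode.upper() if mode.lower() in ("fu", "fm") else mode.lower()
    ref = reference if reference is not None else make_reference(
        config.genome_length, config.seed, config.gc_content
    )
    n = len(ref)
    rng = np.random.default_rng(config.seed)
    site_prob = _site_prob_vectors(config, ref, mode)
    site_pos = {s: ref.cytosine_positions(s) for s in "+-"}

    rlm = config.read_length_model
    em = config.emission

    chroms: list[np.ndarray] = []
    cols: dict[str, list[np.ndarray]] = {k: [] for k in
        ("strand", "start", "read", "llr")}
    truth_rows = []

    def emit(read_id, strand_sym, start, length, p_vec, positions, forced_unmeth=False):
        rel = (positions - start) % n
        covered = positions[rel < length] if length < n else positions
        if covered.size == 0:
            return 0
        p = p_vec if length >= n else p_vec[rel < length]
        states = np.zeros(covered.size, dtype=bool) if forced_unmeth else (
            rng.random(covered.size) < p
        )
        llr = rng.normal(0.0, em.sigma, covered.size) + em.mu * np.where(states, 1.0, -1.0)
        cols["strand"].append(np.full(covered.size, strand_sym))
        cols["start"].append(covered)
        cols["read"].append(np.full(covered.size, read_id))
        cols["llr"].append(llr)
        return int(states.sum())

    for i in range(config.n_reads):
        is_h = rng.random() < config.strand_h_fraction
        mol = "H" if is_h else "L"
        sym = _STRAND_SYMBOL[mol]
        if rng.random() < rlm.full_length_fraction:
            length = n
        else:
            length = int(np.clip(rng.normal(rlm.mean, rlm.sd), rlm.min_length, n))
        fm_fail = mode == "FM" and rng.random() < config.fm_failure_fraction
        read_id = f"sim_{mode.lower()}_{i:05d}"
        n_meth = emit(read_id, sym, config.cut_site, length,
                      site_prob[sym], site_pos[sym], forced_unmeth=fm_fail)
        truth_rows.append((read_id, mol, config.cut_site, length, False, fm_fail, n_meth))

    nd = config.numt_decoys
    for j in range(nd.count):
        is_h = rng.random() < 0.5
        mol = "H" if is_h else "L"
        sym = _STRAND_SYMBOL[mol]
        length = int(rng.integers(max(nd.length_bp // 2, 1), nd.length_bp + 1))
        start = int(rng.integers(0, n - length + 1))  # linear: no wrap
        positions = site_pos[sym]
        read_id = f"numt_{j:05d}"
        inside = positions[(positions >= start) & (positions < start + length)]
        p = np.full(inside.size, nd.meth_prob)
        states = rng.random(inside.size) < p
        llr = rng.normal(0.0, em.sigma, inside.size) + em.mu * np.where(states, 1.0, -1.0)
        cols["strand"].append(np.full(inside.size, sym))
        cols["start"].append(inside)
        cols["read"].append(np.full(inside.size, read_id))
        cols["llr"].append(llr)
        truth_rows.append((read_id, mol, start, length, True, False, int(states.sum())))

    truth = SimTruth(
        reads=pd.DataFrame(
            truth_rows,
            columns=["read_id", "molecule_strand", "start", "length",
                     "is_numt", "fm_failure", "n_true_meth"],
        ),
        site_positions=site_pos,
        site_prob=site_prob,
        reference=ref,
        mode=mode,
    )

    if not cols["start"]:
        warnings.warn("no cytosine sites covered by any read; empty call table")
        calls = pd.DataFrame(
            columns=["chromosome", "strand", "start", "end", "read_name",
                     "log_lik_ratio", "log_lik_methylated", "log_lik_unmethylated",
                     "num_calling_strands", "num_motifs", "sequence"]
        )
        return calls, truth

    strand_arr = np.concatenate(cols["strand"])
    start_arr = np.concatenate(cols["start"])
    read_arr = np.concatenate(cols["read"])
    llr_arr = np.concatenate(cols["llr"])

    # per-position strand-aware trimer contexts, built once per strand
    ctx = {}
    for s in "+-":
        lookup = np.empty(n, dtype="U3")
        for pos in site_pos[s]:
            lookup[pos] = ref.context(int(pos), s)
        ctx[s] = lookup
    seq_arr = np.where(
        strand_arr == "+", ctx["+"][start_arr], ctx["-"][start_arr]
    )

    calls = pd.DataFrame(
        {
            "chromosome": ref.name,
            "strand": strand_arr,
            "start": start_arr,
            "end": start_arr,
            "read_name": read_arr,
            "log_lik_ratio": llr_arr,
            "log_lik_methylated": llr_arr,
            "log_lik_unmethylated": 0.0,
            "num_calling_strands": 1,
            "num_motifs": 1,
            "sequence": seq_arr,
        }
    )
    return calls, truth


def simulate_cohort(
    config: SimConfig,
    n_pairs: int,
    effect_sites,
    delta_true: float,
    coverage: int | None = None,
    positions: np.ndarray | None = None,
    base_meth: float = 0.3,
    phi_between: float = 0.05,
    phi_within: float = 0.02,
    strand: str = "L",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate a paired tumor/normal cohort of per-site count tables.

    Per pair, a baseline methylation level is drawn per site from a Beta
    distribution (between-subject dispersion ``phi_between``) around
    ``base_meth``; the tumor member is shifted by ``delta_true`` at
    ``effect_sites`` only. Member-level proportions add beta-binomial
    overdispersion ``phi_within``; counts are binomial at ``coverage``.

    Returns ``(samples, truth)`` where ``samples`` maps sample ids
    (``P{j}_T`` / ``P{j}_N``) to site-summary-style frames and ``truth``
    lists each site's effect status and the shift actually applied
    (post-clipping).
    """
    if not 0.0 <= delta_true < 1.0:
        raise ValueError("delta_true must be in [0, 1)")
    rng = np.random.default_rng(config.seed)
    if positions is None:
        ref = make_reference(config.genome_length, config.seed, config.gc_content)
        positions = ref.cpg_positions("+")
    positions = np.asarray(positions)
    coverage = config.n_reads if coverage is None else coverage
    effect_sites = np.asarray(sorted(effect_sites), dtype=positions.dtype)
    if not np.isin(effect_sites, positions).all():
        raise ValueError("effect_sites must be a subset of simulated positions")
    is_effect = np.isin(positions, effect_sites)

    shifted = np.clip(base_meth + delta_true * is_effect, 0.0, 1.0)
    if np.any(base_meth + delta_true * is_effect > 1.0):
        warnings.warn("delta_true pushed probabilities above 1; clipped")

    def beta_draw(mean, phi, size):
        """Beta variates with the given mean and dispersion phi = 1/(a+b+1)."""
        mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
        if phi <= 0:
            return mean.copy()
        conc = 1.0 / phi - 1.0
        a = np.clip(mean * conc, 1e-6, None)
        b = np.clip((1.0 - mean) * conc, 1e-6, None)
        return rng.beta(a, b)

    samples: dict[str, pd.DataFrame] = {}
    n_sites = positions.size
    for j in range(n_pairs):
        baseline = beta_draw(base_meth, phi_between, n_sites)
        tumor_mean = np.clip(baseline + delta_true * is_effect, 0.0, 1.0)
        for tag, mean in (("N", baseline), ("T", tumor_mean)):
            p_rep = beta_draw(mean, phi_within, n_sites)
            x = rng.binomial(coverage, p_rep)
            samples[f"P{j}_{tag}"] = pd.DataFrame(
                {
                    "chrom": "chrM",
                    "pos": positions,
                    "molecule_strand": strand,
                    "n_meth": x,
                    "n_unmeth": coverage - x,
                    "n_ambiguous": 0,
                    "coverage_called": coverage,
                    "beta": x / coverage,
                }
            )
    truth = pd.DataFrame(
        {
            "pos": positions,
            "is_effect": is_effect,
            "delta_applied": shifted - base_meth,
        }
    )
    return samples, truth
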