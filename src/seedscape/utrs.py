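"""3'UTR sequence handling: loading, complexity/redundancy filters and
probe-to-gene collapse.

UTRs are mRNA-sense DNA strings (U converted to T on load). Before word
counting the collection is cleaned the way ranked-list enrichment tools
do: drop very short UTRs, drop low-complexity UTRs (a DUST-style triplet
score), collapse byte-identical duplicates, drop multimapping probes and
keep a single representative probe per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from Bio import SeqIO
from numba import njit

from .errors import ContractError, InputError, PipelineError

_VALID = set("ACGTN")

#: DUST-like scorer defaults: window length (nt) and score threshold.
DUST_WINDOW = 64
DUST_THRESHOLD = 2.0


@dataclass
class UtrSet:
    """Mapping gene_id -> uppercase DNA sequence over {A,C,G,T,N}."""

    records: dict[str, str]

    def __post_init__(self):
        for gid, seq in self.records.items():
            bad = set(seq) - _VALID
            if bad:
                raise InputError(
                    f"UTR for {gid} contains invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def length(self, gene_id: str) -> int:
        return len(self.records[gene_id])


def normalize_sequence(raw: str, name: str = "?") -> str:
    """Uppercase and convert RNA U to DNA T; reject other characters."""
    seq = str(raw).upper().replace("U", "T")
    for i, c in enumerate(seq):
        if c not in _VALID:
            raise InputError(
                f"record {name}: invalid character {c!r} at position {i + 1}")
    return seq


def read_utr_fasta(path) -> UtrSet:
    """Load a FASTA of 3'UTRs; record id (first token) is the gene id."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = rec.id
        if gid in records:
            raise InputError(f"duplicate gene id in FASTA: {gid}")
        seq = normalize_sequence(str(rec.seq), gid)
        if not seq:
            warnings.warn(f"dropping empty UTR record {gid}")
            continue
        records[gid] = seq
    return UtrSet(records)


def write_utr_fasta(utrs: UtrSet, path) -> None:
    with open(path, "w") as fh:
        for gid, seq in utrs.records.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


@njit(cache=True)
def _dust_mask(tri: np.ndarray, L: int, window: int,
               threshold: float) -> np.ndarray:
    masked = np.zeros(L, dtype=np.bool_)
    step = window // 2
    if step < 1:
        step = 1
    last_start = L - window if L > window else 0
    counts = np.zeros(64, dtype=np.int64)
    s = 0
    while True:
        wlen = min(window, L - s)
        n_tri_pos = wlen - 2
        if n_tri_pos >= 2:
            counts[:] = 0
            pairs = 0.0
            n_valid = 0
            for i in range(s, s + n_tri_pos):
                c = tri[i]
                if c >= 0:
                    pairs += counts[c]   # running sum of c*(c-1)/2
                    counts[c] += 1
                    n_valid += 1
            if n_valid >= 2 and pairs / (n_valid - 1) > threshold:
                masked[s:s + wlen] = True
        if s >= last_start:
            break
        s = min(s + step, last_start)
    return masked


def dust_fraction(seq: str, window: int = DUST_WINDOW,
                  threshold: float = DUST_THRESHOLD) -> float:
    """Fraction of a sequence covered by low-complexity windows.

    Windows of ``window`` nt (stepped by window/2, plus a final window
    anchored at the 3' end) are scored by the DUST triplet statistic
    sum_t c_t (c_t - 1) / 2 divided by (#valid triplets - 1); a window
    scoring above ``threshold`` marks all of its positions as
    low-complexity. Triplets containing N are ignored. Poly-nucleotide
    runs score ~ (#triplets)/2 and are fully masked; i.i.d. random
    sequence scores ~0.5.
    """
    L = len(seq)
    if L < 4:
        return 0.0
    from .kmers import encode_sequence
    codes = encode_sequence(seq).astype(np.int64)
    a, b, c = codes[:-2], codes[1:-1], codes[2:]
    tri = a * 16 + b * 4 + c
    tri[(a < 0) | (b < 0) | (c < 0)] = -1
    masked = _dust_mask(tri, L, window, threshold)
    return float(masked.mean())


def filter_utrs(utrs: UtrSet, min_len: int = 8,
                max_lc_fraction: float = 0.5) -> UtrSet:
    """Drop short UTRs, low-complexity UTRs and exact duplicates.

    Duplicate sequences keep the lexicographically smallest gene id.
    """
    if min_len < 8:
        raise ContractError("min_len must be >= 8 (shortest classified site)")
    seen: dict[str, str] = {}  # sequence -> keeper gene id
    kept: dict[str, str] = {}
    for gid in sorted(utrs.records):
        seq = utrs.records[gid]
        if len(seq) < min_len:
            continue
        if dust_fraction(seq) > max_lc_fraction:
            continue
        if seq in seen:
            continue
        seen[seq] = gid
        kept[gid] = seq
    if not kept:
        warnings.warn("filter_utrs: no UTRs survived filtering")
    # preserve original record order among keepers
    ordered = {g: utrs.records[g] for g in utrs.records if g in kept}
    return UtrSet(ordered)


@dataclass
class ProbeGeneMap:
    """probe_id -> gene_id with multimapping probes flagged for exclusion."""

    gene_of: dict[str, str]
    multimapped: set[str] = field(default_factory=set)

    def usable(self, probe_id: str) -> bool:
        return probe_id in self.gene_of and probe_id not in self.multimapped


def read_probe_gene_map(path) -> ProbeGeneMap:
    """TSV with columns ProbeID, GeneID; probes listed with more than one
    distinct gene are flagged as multimapped."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ProbeID", "GeneID"):
        if col not in df.columns:
            raise InputError(f"probe map lacks column '{col}'")
    gene_of: dict[str, str] = {}
    multi: set[str] = set()
    for probe, gene in zip(df["ProbeID"], df["GeneID"]):
        if probe in gene_of and gene_of[probe] != gene:
            multi.add(probe)
        gene_of.setdefault(probe, gene)
    return ProbeGeneMap(gene_of, multi)


def write_probe_gene_map(pgmap: ProbeGeneMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("ProbeID\tGeneID\n")
        for probe, gene in pgmap.gene_of.items():
            fh.write(f"{probe}\t{gene}\n")


def collapse_to_genes(ranked: pd.DataFrame, pgmap: ProbeGeneMap,
                      utrs: UtrSet) -> pd.DataFrame:
    """Collapse a probe-level ranked list to one probe per gene.

    Multimapped probes, probes without a gene assignment and genes whose
    UTR did not survive filtering are dropped. When several probes report
    the same gene, the probe with the highest mean intensity across all
    samples represents it (a treatment-agnostic choice that does not bias
    the fold-change ranks). Ranks are recomputed 1..n preserving the
    fc_signed order.
    """
    df = ranked.copy()
    keep_mask = df["probe_id"].map(pgmap.usable)
    df = df[keep_mask].copy()
    df["gene_id"] = df["probe_id"].map(pgmap.gene_of).astype("string")
    df = df[df["gene_id"].map(lambda g: g in utrs)]
    if df.empty:
        raise PipelineError("no genes left after probe->gene collapse")
    # per gene, keep highest mean_all (ties: smallest probe_id)
    df = df.sort_values(["mean_all", "probe_id"],
                        ascending=[False, True], kind="stable")
    df = df.drop_duplicates("gene_id", keep="first")
    df = df.sort_values(["fc_signed", "probe_id"], kind="stable",
                        ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[list(ranked.columns)]
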