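"""Seed-word derivation, target calling and list intersections.

The canonical site classes of miRNA targeting are built from the seed
(nucleotides 2-8 of the mature miRNA) and expressed as mRNA-sense DNA
words:

    6mer     rc(m[2..7])
    7mer-m8  rc(m[2..8])
    7mer-A1  rc(m[2..7]) + "A"
    8mer     rc(m[2..8]) + "A"

where rc is reverse complement into DNA and positions are 1-based on the
mature sequence. Both 7-mers and the 6-mer are substrings of the 8mer,
so class counts nest: every 8mer gene is also a 7mer-m8, 7mer-A1 and
6mer gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, InputError
from .utrs import UtrSet

_RNA = set("ACGU")
_DNA_COMP = {"A": "T", "C": "G", "G": "C", "U": "A"}

SITE_CLASSES = ("six", "seven_m8", "seven_A1", "eight")


def reverse_complement_to_dna(rna: str) -> str:
    """Reverse complement of an RNA string, written in the DNA alphabet."""
    return "".join(_DNA_COMP[c] for c in reversed(rna))


def rna_reverse_complement(rna: str) -> str:
    """Reverse complement within the RNA alphabet (antagomir -> mature)."""
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    return "".join(comp[c] for c in reversed(rna))


@dataclass(frozen=True)
class SeedWordSet:
    """The four seed-complementary words of one miRNA."""

    mirna_id: str
    mature: str
    six: str
    seven_m8: str
    seven_A1: str
    eight: str

    def __post_init__(self):
        if not (self.six in self.seven_m8 and self.six in self.seven_A1
                and self.six in self.eight):
            raise ContractError("6mer must be a substring of the longer words")
        if not (self.seven_m8 in self.eight and self.seven_A1 in self.eight):
            raise ContractError("both 7mers must be substrings of the 8mer")

    @property
    def seven_mers(self) -> tuple[str, str]:
        return (self.seven_m8, self.seven_A1)

    def word(self, site_class: str) -> str:
        return getattr(self, site_class)


def derive_seed_words(mirna_id: str, mature: str) -> SeedWordSet:
    """Build the 6mer/7mer-m8/7mer-A1/8mer words from a mature miRNA."""
    mature = mature.strip().upper().replace("T", "U")
    if len(mature) < 8:
        raise InputError("mature miRNA must be at least 8 nt")
    if set(mature) - _RNA:
        raise InputError(
            f"mature miRNA has non-RNA characters: {sorted(set(mature) - _RNA)}")
    six = reverse_complement_to_dna(mature[1:7])     # nts 2..7
    seven_m8 = reverse_complement_to_dna(mature[1:8])  # nts 2..8
    return SeedWordSet(mirna_id, mature, six, seven_m8,
                       six + "A", seven_m8 + "A")


def count_overlapping(haystack: str, needle: str) -> int:
    """Occurrences of needle in haystack, overlaps allowed."""
    n = 0
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


TARGET_COLUMNS = [
    "gene_id", "rank", "fc_signed",
    "has_six", "has_seven_m8", "has_seven_A1", "has_eight",
    "n_six", "n_seven_m8", "n_seven_A1", "n_eight",
    "predicted_by",
]


def call_targets(ranked: pd.DataFrame, utrs: UtrSet, words: SeedWordSet,
                 T: int) -> pd.DataFrame:
    """Seed-bearing genes among the T most down-regulated.

    Rows are the genes with rank <= T whose UTR contains at least one
    occurrence of the 6mer; per-class flags/counts come from overlapping
    substring occurrence counts. A gene may carry several classes.
    """
    if T > len(ranked):
        raise ContractError("cutoff T exceeds the ranked list length")
    head = ranked[ranked["rank"] <= T]
    rows = []
    for _, r in head.iterrows():
        gid = str(r["gene_id"])
        seq = utrs.records.get(gid)
        if seq is None:
            raise ContractError(f"ranked gene {gid} has no UTR")
        n_six = count_overlapping(seq, words.six)
        if n_six == 0:
            continue
        counts = {c: count_overlapping(seq, words.word(c)) for c in SITE_CLASSES}
        rows.append({
            "gene_id": gid, "rank": int(r["rank"]),
            "fc_signed": float(r["fc_signed"]),
            **{f"has_{c}": counts[c] > 0 for c in SITE_CLASSES},
            **{f"n_{c}": counts[c] for c in SITE_CLASSES},
            "predicted_by": "",
        })
    table = pd.DataFrame(rows, columns=TARGET_COLUMNS)
    return table.sort_values("rank", ignore_index=True) if len(table) else table


def class_counts(table: pd.DataFrame) -> dict[str, int]:
    """Per-class gene counts (the 602/238/310/120 analogue)."""
    if len(table) == 0:
        return {c: 0 for c in SITE_CLASSES}
    return {c: int(table[f"has_{c}"].sum()) for c in SITE_CLASSES}


@dataclass
class OverlapReport:
    """Prediction-overlap and known-target triage summary."""

    n_called: int
    per_source: dict[str, int] = field(default_factory=dict)
    union: int = 0
    triage_within: list[str] = field(default_factory=list)
    triage_down_beyond: list[str] = field(default_factory=list)
    triage_up_or_unchanged: list[str] = field(default_factory=list)
    triage_not_evaluable: list[str] = field(default_factory=list)

    @property
    def union_fraction(self) -> float:
        return self.union / self.n_called if self.n_called else float("nan")


def intersect_predictions(table: pd.DataFrame,
                          sources: dict[str, set[str]]) -> OverlapReport:
    """Overlap the called targets with external prediction gene lists.

    Matching is case-insensitive exact on gene symbols. Updates the
    table's ``predicted_by`` column in place (comma-separated source
    names) and returns the per-source / union counts.
    """
    if len(sources) != len(set(sources)):
        raise ContractError("prediction source names must be unique")
    called = [str(g).upper() for g in table["gene_id"]]
    norm_sources = {name: {g.upper() for g in genes}
                    for name, genes in sources.items()}
    report = OverlapReport(n_called=len(table))
    union_hits = set()
    labels = []
    for g in called:
        hits = [name for name, genes in norm_sources.items() if g in genes]
        labels.append(",".join(hits))
        if hits:
            union_hits.add(g)
    for name, genes in norm_sources.items():
        report.per_source[name] = sum(g in genes for g in called)
    report.union = len(union_hits)
    if len(table):
        table["predicted_by"] = labels
    return report


def triage_known_targets(ranked: pd.DataFrame, T: int, known: list[str],
                         expressed: set[str],
                         report: OverlapReport | None = None) -> OverlapReport:
    """Partition a published-target list against the ranked list.

    Known genes absent from the expressed set are not evaluable; the rest
    split into within-cutoff (rank <= T, boundary inclusive),
    down-regulated beyond the cutoff (fc_signed < -1), and
    up-regulated/unchanged (fc_signed >= +1).
    """
    if report is None:
        report = OverlapReport(n_called=0)
    expressed_u = {g.upper() for g in expressed}
    by_gene = {str(g).upper(): (int(r), float(f)) for g, r, f in
               zip(ranked["gene_id"], ranked["rank"], ranked["fc_signed"])}
    for gene in known:
        gu = gene.upper()
        if gu not in expressed_u or gu not in by_gene:
            report.triage_not_evaluable.append(gene)
            continue
        rank, fc = by_gene[gu]
        if rank <= T:
            report.triage_within.append(gene)
        elif fc < -1:
            report.triage_down_beyond.append(gene)
        else:
            report.triage_up_or_unchanged.append(gene)
    return report


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; '#' comments and blank lines ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def write_target_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
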