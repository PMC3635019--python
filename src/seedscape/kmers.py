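"""Overlapping k-mer counting over UTR collections.

Words are encoded as base-4 integers (A=0, C=1, G=2, T=3, most
significant digit first) so a whole collection's counts fit in a sparse
genes x 4^k matrix. Windows containing N are skipped and excluded from
the valid-window totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .errors import ContractError

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_CODE_BASE = np.array(list("ACGT"))


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes (N -> -1)."""
    out = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(128, -2, dtype=np.int8)
    for b, c in _BASE_CODE.items():
        table[ord(b)] = c
    codes = table[out]
    if (codes == -2).any():
        raise ContractError("sequence contains characters outside {A,C,G,T,N}")
    return codes


def word_to_code(word: str) -> int:
    code = 0
    for c in word:
        code = code * 4 + _BASE_CODE[c]
    return code


def code_to_word(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of all valid (N-free) windows of length k."""
    L = codes.size
    if L < k:
        return np.empty(0, dtype=np.int64)
    n_win = L - k + 1
    valid = np.ones(n_win, dtype=bool)
    word = np.zeros(n_win, dtype=np.int64)
    for j in range(k):
        col = codes[j:j + n_win]
        valid &= col >= 0
        word = word * 4 + col
    return word[valid]


@dataclass
class WordCounts:
    """Per-gene occurrence counts of all k-mers in a UTR collection.

    ``matrix`` is a CSR matrix of shape (n_genes, 4^k); ``windows`` holds
    each gene's number of valid windows, so for N-free genes the row sum
    of ``matrix`` equals length - k + 1.
    """

    k: int
    gene_ids: list[str]
    matrix: sparse.csr_matrix          # (n_genes, 4**k) int64
    windows: np.ndarray                # (n_genes,) int64

    @property
    def total_windows(self) -> int:
        return int(self.windows.sum())

    @property
    def totals(self) -> np.ndarray:
        """Total occurrences of every word over all genes (length 4^k)."""
        return np.asarray(self.matrix.sum(axis=0)).ravel().astype(np.int64)

    @property
    def n_distinct_words(self) -> int:
        """Number of distinct words actually present in the collection."""
        return int((self.totals > 0).sum())

    def per_gene(self, gene_id: str) -> dict[str, int]:
        """Word -> count mapping for one gene."""
        i = self.gene_ids.index(gene_id)
        row = self.matrix.getrow(i).tocoo()
        return {code_to_word(int(c), self.k): int(v)
                for c, v in zip(row.col, row.data)}

    def word_total(self, word: str) -> int:
        return int(self.totals[word_to_code(word)])


def count_words(utrs, k: int, gene_ids: list[str] | None = None) -> WordCounts:
    """Count overlapping k-mer occurrences in every UTR.

    ``gene_ids`` fixes the row order (default: UtrSet record order); every
    requested gene must be present in the collection.
    """
    if k not in (6, 7, 8):
        raise ContractError("k must be one of 6, 7, 8")
    if gene_ids is None:
        gene_ids = list(utrs.records)
    missing = [g for g in gene_ids if g not in utrs.records]
    if missing:
        raise ContractError(f"genes without UTRs: {missing[:5]}")
    rows, cols, data = [], [], []
    windows = np.zeros(len(gene_ids), dtype=np.int64)
    for i, gid in enumerate(gene_ids):
        codes = encode_sequence(utrs.records[gid])
        w = window_codes(codes, k)
        windows[i] = w.size
        if w.size:
            uniq, cnt = np.unique(w, return_counts=True)
            rows.append(np.full(uniq.size, i, dtype=np.int64))
            cols.append(uniq)
            data.append(cnt.astype(np.int64))
    if rows:
        mat = sparse.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(gene_ids), 4 ** k), dtype=np.int64).tocsr()
    else:
        mat = sparse.csr_matrix((len(gene_ids), 4 ** k), dtype=np.int64)
    return WordCounts(k, list(gene_ids), mat, windows)


def export_counts_tsv(counts: WordCounts, path) -> None:
    """Debug export: one (gene, word, count) row per non-zero cell."""
    coo = counts.matrix.tocoo()
    with open(path, "w") as fh:
        fh.write("gene_id\tword\tcount\n")
        for i, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{counts.gene_ids[i]}\t{code_to_word(int(c), counts.k)}\t{int(v)}\n")
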