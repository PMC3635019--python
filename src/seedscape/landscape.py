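"""Signed hypergeometric word-enrichment landscapes over ranked gene lists.

For every word w and every cutpoint t along a fold-change-ranked gene
list, the landscape value is the signed -log10 of the smaller exact
hypergeometric tail of the word's occurrence count in the leading t
genes, drawn from the whole list's occurrence pool:

    X ~ Hypergeometric(N, K, n)
    N = total valid windows over all genes     (population)
    K = total occurrences of w                 (successes)
    n = valid windows in the leading t genes   (draws)
    k = occurrences of w in the leading t genes

Positive values mean enrichment among the most down-regulated genes,
negative values depletion. The Bonferroni bound -log10(alpha / W) over
the W words tested marks family-wise significance, and the cutoff used
to delimit responsive genes is the first local maximum of the focal
words' profile that exceeds that bound — the peak closest to the start
of the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

from . import _hyper
from .errors import ContractError
from .kmers import WordCounts, word_to_code

#: Scores are computed from log-space tails, which are finite for every
#: admissible input, so no magnitude cap is applied by default; pass a
#: finite cap to ``compute_landscape`` for plot-friendly clipping.
SCORE_CAP = math.inf


@dataclass(frozen=True)
class HypergeomInput:
    """One landscape cell: population/draw counts for a single word."""

    N: int      # total word occurrences over all genes
    K: int      # total occurrences of the focal word
    n: int      # word occurrences in the leading set
    k_obs: int  # focal-word occurrences in the leading set

    def __post_init__(self):
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ContractError("need 0 <= K <= N and 0 <= n <= N")
        if not (max(0, self.n + self.K - self.N) <= self.k_obs
                <= min(self.K, self.n)):
            raise ContractError("k_obs outside hypergeometric support")


def signed_hypergeom_score(h: HypergeomInput) -> float:
    """Signed -log10 of the smaller exact tail (0 when the tails tie)."""
    s = _hyper.signed_scores(
        np.array([h.k_obs], dtype=np.int64), np.array([h.N], dtype=np.int64),
        np.array([h.K], dtype=np.int64), np.array([h.n], dtype=np.int64),
        SCORE_CAP)
    return float(s[0])


@dataclass(frozen=True)
class CutpointScheme:
    """Gene-rank positions at which the landscape is evaluated."""

    cutpoints: tuple[int, ...]

    def __post_init__(self):
        cp = self.cutpoints
        if not cp or cp[0] != 0:
            raise ContractError("first cutpoint must be 0")
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise ContractError("cutpoints must be strictly increasing")

    @classmethod
    def regular(cls, n_genes: int, step: int = 25) -> "CutpointScheme":
        """Every ``step`` genes plus both endpoints."""
        if n_genes < 1 or step < 1:
            raise ContractError("need n_genes >= 1 and step >= 1")
        pts = list(range(0, n_genes, step))
        if pts[-1] != n_genes:
            pts.append(n_genes)
        return cls(tuple(pts))

    @property
    def n_genes(self) -> int:
        return self.cutpoints[-1]


def multiple_testing_bound(alpha: float, W: int) -> float:
    """Bonferroni bound on the -log10 scale: -log10(alpha / W)."""
    if not 0 < alpha < 1:
        raise ContractError("alpha must be in (0, 1)")
    if W < 1:
        raise ContractError("W must be >= 1")
    return -math.log10(alpha / W)


@dataclass
class LandscapeGrid:
    """word x cutpoint signed significances plus the word-family bound."""

    k: int
    words: list[str]
    cutpoints: CutpointScheme
    scores: np.ndarray        # (n_words, n_cutpoints)
    bound: float
    alpha: float
    W: int

    def profile(self, word: str) -> np.ndarray:
        try:
            i = self.words.index(word)
        except ValueError:
            raise ContractError(f"word {word} not in landscape") from None
        return self.scores[i]

    def focal_profile(self, focal_words) -> np.ndarray:
        """Pointwise max of the focal words' profiles."""
        rows = [self.profile(w) for w in focal_words]
        return np.max(np.vstack(rows), axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores.T, columns=self.words)
        df.insert(0, "cutpoint", list(self.cutpoints.cutpoints))
        return df


def compute_landscape(ranked: pd.DataFrame, counts: WordCounts,
                      scheme: CutpointScheme,
                      words: list[str] | None = None,
                      alpha: float = 0.05,
                      W: int | None = None,
                      cap: float = SCORE_CAP) -> LandscapeGrid:
    """Evaluate the landscape over a ranked gene list.

    ``words`` restricts the computed profiles (e.g. to the focal seed
    words); the multiple-testing bound always uses ``W`` = number of
    distinct words present in the collection unless overridden, so a
    restricted grid keeps the same family-wise bound as the full one.
    Prefix sums over the ranked order make the pass linear in the number
    of non-zero gene/word count cells.
    """
    gene_order = ranked["gene_id"].tolist()
    if pd.isna(gene_order).any():
        raise ContractError("ranked list is probe-level; collapse to genes first")
    pos = {g: i for i, g in enumerate(counts.gene_ids)}
    missing = [g for g in gene_order if g not in pos]
    if missing:
        raise ContractError(f"ranked genes without counts: {missing[:5]}")
    if len(gene_order) != len(counts.gene_ids):
        raise ContractError("counts cover genes absent from the ranked list")
    if scheme.n_genes != len(gene_order):
        raise ContractError("cutpoint scheme endpoint != number of genes")

    perm = np.array([pos[g] for g in gene_order])
    mat = counts.matrix[perm]                     # rows in ranked order
    windows = counts.windows[perm]

    totals = counts.totals
    if words is None:
        word_codes = np.flatnonzero(totals > 0)
        word_strs = [_code_to_word_cached(int(c), counts.k) for c in word_codes]
    else:
        word_strs = list(words)
        word_codes = np.array([word_to_code(w) for w in word_strs], dtype=np.int64)
        if any(len(w) != counts.k for w in word_strs):
            raise ContractError("word length does not match counts.k")
    if W is None:
        W = counts.n_distinct_words
    bound = multiple_testing_bound(alpha, W)

    cp = np.array(scheme.cutpoints, dtype=np.int64)
    mat_sub = mat[:, word_codes].tocsr()
    # sum count rows within each cutpoint segment, then prefix-sum;
    # keeps memory at n_cutpoints x n_words instead of genes x words
    seg = np.zeros((len(cp), len(word_codes)), dtype=np.int64)
    for i in range(1, len(cp)):
        seg[i] = np.asarray(
            mat_sub[cp[i - 1]:cp[i]].sum(axis=0)).ravel()
    k_obs = np.cumsum(seg, axis=0)                # (n_cut, n_words)
    n_prefix = np.concatenate([[0], np.cumsum(windows)])[cp]
    N = counts.total_windows
    K = totals[word_codes]

    n_cut, n_words = k_obs.shape
    scores = _hyper.signed_scores(
        k_obs.ravel(order="F"),
        np.full(n_cut * n_words, N, dtype=np.int64),
        np.repeat(K.astype(np.int64), n_cut),
        np.tile(n_prefix.astype(np.int64), n_words),
        cap,
    ).reshape(n_words, n_cut)

    return LandscapeGrid(counts.k, word_strs, scheme, scores,
                         bound, alpha, int(W))


def _code_to_word_cached(code: int, k: int) -> str:
    from .kmers import code_to_word
    return code_to_word(code, k)


@dataclass(frozen=True)
class PeakResult:
    """Outcome of the leading-peak cutoff rule."""

    cutoff: int | None          # gene-rank position, None if no peak
    peak_value: float | None
    bound: float
    message: str

    @property
    def significant(self) -> bool:
        return self.cutoff is not None


def leading_peak_cutoff(grid: LandscapeGrid, focal_words) -> PeakResult:
    """First local maximum of the focal profile that exceeds the bound.

    The profile rises then falls around a local maximum; plateaus resolve
    to their first cutpoint. The earliest qualifying peak wins even if a
    later one is higher — the conservative "peak closest to the start of
    the ranking" rule.
    """
    f = grid.focal_profile(focal_words)
    cp = grid.cutpoints.cutpoints
    # collapse plateaus to runs of distinct values
    starts = [0]
    for i in range(1, len(f)):
        if f[i] != f[starts[-1]]:
            starts.append(i)
    vals = [f[i] for i in starts]
    for j in range(1, len(vals) - 1):
        if vals[j] > vals[j - 1] and vals[j] > vals[j + 1]:
            if vals[j] > grid.bound:
                idx = starts[j]
                return PeakResult(cp[idx], float(f[idx]), grid.bound,
                                  f"peak at rank {cp[idx]}")
    return PeakResult(None, None, grid.bound, "no significant peak")


def export_landscape_tsv(grid: LandscapeGrid, path,
                         focal_words=(), top: int | None = None) -> None:
    """Plot-ready TSV: rows = cutpoints, columns = words.

    ``top`` restricts the export to the ``top`` words by max |S| plus the
    focal words (mirrors how landscape figures display a handful of
    extreme background words).
    """
    if top is not None:
        order = np.argsort(-np.abs(grid.scores).max(axis=1))
        keep = [grid.words[i] for i in order[:top]]
        for w in focal_words:
            if w not in keep:
                keep.append(w)
        df = grid.to_frame()[["cutpoint"] + keep]
    else:
        df = grid.to_frame()
    df.to_csv(path, sep="\t", index=False)
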