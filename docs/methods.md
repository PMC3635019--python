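# Methods

## Overview

`seedscape` implements the ranked-list word-enrichment approach to
miRNA target identification from transfection expression data. The
reasoning is: over-expressing a miRNA destabilises the mRNAs it
targets, so after ranking all expressed genes from most down- to most
up-regulated, the k-mers complementary to the miRNA's seed should pile
up among the leading (most down-regulated) genes — and no other k-mer
should. The pipeline quantifies that pile-up with an exact
hypergeometric statistic evaluated along the ranking, chooses a
conservative gene cutoff at the first significant peak of the seed
words' profile, and reports the seed-bearing genes above it as putative
targets.

The method detects only effects on mRNA stability; targets repressed
purely at the translational level are invisible to it by design.

## Expression preprocessing

Input is a probe × sample intensity table with per-cell detection
flags and a two-group design (treated = miRNA-transfected, control =
negative-control-transfected; the emulated design is 3 vs 4
replicates).

1. **Flooring** — every value below 1.0 (including negatives produced
   by background subtraction in scanner software) is set to 1.0.
2. **Quantile normalization** — classic order-statistic averaging: the
   value at rank r in each column becomes the mean over columns of the
   r-th order statistics. Tied values within a column receive the mean
   of the normalized values of their tied ranks. After normalization
   every column has bit-identical sorted values.
3. **Detection filter** — probes detected in at least one sample are
   kept; the flag column is taken at face value (no re-derivation of
   scanner flag logic). For real single-channel array exports, the
   reader maps a `gIsWellAboveBG`-style column to the flag.
4. **Ranking** — per probe, signed linear fold change:
   `fc = m_t/m_c` if `m_t ≥ m_c`, else `-(m_c/m_t)`, with `m_t`, `m_c`
   arithmetic means of normalized linear intensities. Under this
   convention `|fc| ≥ 1` always, equality maps to +1, and `fc < -1.15`
   means a ≥15% reduction. Probes sort ascending by `fc`, ties broken
   by probe id so reruns are bit-identical. Group means are computed
   centered on the first replicate so that a probe with identical
   values in both groups lands exactly on the +1 boundary; whether
   fold change should instead be computed on log-scale means is a
   genuinely open choice — linear means are the default here and the
   switch is a one-line change in `fold_change_rank`.

## UTR filtering and probe collapse

3′UTRs arrive as mRNA-sense sequence (RNA converted to DNA on load).
Before counting, the collection is cleaned:

- **Length** — UTRs shorter than `min_len` (default 8 nt, the shortest
  classified site) are dropped.
- **Low complexity** — a DUST-style scorer: windows of 64 nt (stepped
  by 32, final window anchored at the 3′ end) are scored by
  `Σ_t c_t(c_t−1)/2 / (T−1)` over triplet counts `c_t` (`T` = valid
  triplets; triplets containing N are ignored). Windows scoring above
  2.0 are masked; UTRs with masked fraction above `max_lc_fraction`
  (default 0.5) are dropped. A homopolymer masks completely
  (fraction 1.0); i.i.d. random sequence scores ≈0.5, far below the
  threshold.
- **Redundancy** — byte-identical duplicate sequences keep only the
  lexicographically smallest gene id.
- **Probe collapse** — probes mapping to more than one gene are
  excluded; when several probes report one gene, the probe with the
  highest mean normalized intensity across *all* samples represents it.
  Intensity is treatment-agnostic, so this choice cannot bias the
  fold-change ranking. Ranks are recomputed 1..n on the surviving
  gene-level list.

## The enrichment landscape

For word length k ∈ {6, 7, 8}, overlapping k-mer occurrences are
counted in every UTR; windows containing N are skipped and excluded
from the totals. For a word w and a cutpoint t (evaluated every 25
genes by default, plus both endpoints):

    X ~ Hypergeometric(N, K, n)
    N = total valid windows over all ranked genes
    K = total occurrences of w
    n = valid windows in the leading t genes
    k = occurrences of w in the leading t genes

    S(w, t) = +(−log10 P[X ≥ k])  if the enrichment tail is smaller
              −(−log10 P[X ≤ k])  if the depletion tail is smaller
              0                   on ties

The statistic is over *occurrences*, not per-gene presence, which makes
`n` and `N` word-count margins rather than gene counts. Both tails are
computed exactly — no normal or saddlepoint approximation — by
log-space summation with a ratio recurrence, always summing on the
short side of the distributional mode and taking the complement for
the long side (relative truncation 1e-17 per tail). The summation is
compiled with numba because a full landscape needs ~10⁷ tail
evaluations; generic discrete-distribution routines are orders of
magnitude too slow at that scale. Agreement with exact rational
enumeration on small instances is ≤3e-15 absolute in p.

Because tails live in log space, S is finite for every admissible
input and **no magnitude cap is applied**. An earlier capped variant
(|S| ≤ 320) was removed: in strong spike-in conditions the focal
profile saturates at the cap, and the peak rule below then fires at
the start of the saturated plateau — up to ~175 ranks before the true
peak. A `cap` parameter remains on `compute_landscape` for
plot-friendly clipping only.

S(w, 0) = S(w, n_genes) = 0 identically (degenerate margins), and the
enrichment tail in the leading t genes equals the depletion tail of
the complementary trailing set (hypergeometric symmetry) — both are
asserted against the enumeration oracle in tests.

### Multiple testing and the cutoff

The family-wise bound is Bonferroni over the word family:
`B = −log10(α / W)` with α = 0.05 and W defaulting to the number of
distinct words actually present in the collection for that k (≤ 4^k;
W is configurable). For W = 16,384 the bound is 5.515.

The **focal words** are the miRNA's two seed-complementary 7-mers
(7mer-m8 and 7mer-A1 words). Their pointwise-maximum profile f(t) is
scanned left to right; the cutoff T is the cutpoint of the first local
maximum of f that exceeds B (rises then falls; plateaus resolve to
their first cutpoint; an earlier lower peak beats a later higher one).
This is the conservative "peak closest to the start of the ranking"
rule. If no local maximum clears the bound the pipeline reports no
significant peak and stops. The profile is not smoothed — determinism
without hidden parameters.

## Seed words and target calling

With rc = reverse complement into DNA and 1-based positions on the
mature miRNA (so positions 2–8 are the seed):

    6mer     rc(m[2..7])         7mer-A1  rc(m[2..7]) + A
    7mer-m8  rc(m[2..8])         8mer     rc(m[2..8]) + A

For miR-221 (mature = reverse complement of its antagomir) these are
TGTAGC, TGTAGCA, ATGTAGC, ATGTAGCA. Every class word contains the
6mer, and both 7-mers are substrings of the 8mer, so per-gene class
flags nest structurally: every 8mer gene is also counted in both 7mer
classes and the 6mer class. Site classes are overlapping presence
flags, not mutually exclusive best-site types, matching how published
class counts overlap.

A gene is **called** when it ranks at or above T and its UTR contains
at least one 6mer occurrence (overlapping occurrences counted).
Prediction lists and known-target lists are plain one-symbol-per-line
files, matched case-insensitively with no alias resolution. Known
targets triage into: within cutoff (rank ≤ T), down-regulated beyond
the cutoff (fc < −1), and up-regulated/unchanged (fc ≥ +1); genes
absent from the expressed universe are not evaluable.

## Over-representation analysis

A transparent stand-in for commercial pathway tools: for each gene set
(GMT format), p = P[X ≥ overlap] with
X ~ Hypergeometric(universe, set ∩ universe, selected). The universe
defaults to the post-filter ranked gene list — expression-detected
genes are the valid background, not the genome. The significance flag
uses raw p < 0.05 (the convention of the tools this emulates);
Benjamini–Hochberg adjusted values are reported alongside because the
original tools' correction method is unspecified.

## Synthetic experiments

The generator emulates the study conditions so the whole pipeline is
verifiable without downloads:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 10,000 | genes ≈ detected, UTR-mappable collection |
| `utr_len_median` / `utr_len_log_sd` | 500 nt / 0.6 | log-normal UTR lengths |
| `base_composition` | A/T 0.29, C/G 0.21 | AU-rich background, order-0 Markov |
| `n_treated` / `n_control` | 3 / 4 | replicate design |
| `base_mu` / `sigma_gene` / `sigma_rep` | 8 / 1.5 / 0.25 | log2 intensity location and spreads |
| `effect` (six / seven / eight) | −0.3 / −0.6 / −1.0 | per-site log2 down-shift |

Per gene g: location `mu_g ~ N(base_mu, sigma_gene)`; control
replicates `~ N(mu_g, sigma_rep)`; treated replicates
`~ N(mu_g + shift_g, sigma_rep)` with `shift_g` the sum of per-site
class effects (≤ 0); intensities are `2^log2`, detection flags all
true. With the default effects, 8mer-site targets sit at fold change
≈ −2, crossing the −1.15 regime with margin. Target genes receive
their class word at uniform random non-overlapping UTR positions
(UTRs too short to host the sites are redrawn, or error per config).
With `purge_background_sites`, chance 6mer occurrences in non-target
genes are resampled away (bounded retries), guaranteeing a clean null.
Every stage draws from a per-stage child stream of one seed, so runs
are bit-reproducible and stages can be rerun independently.

What the simulator does *not* model: probe-level array artifacts
(spatial effects, background), translational-repression-only targets,
realistic UTR sequence correlation (dinucleotide/motif structure
beyond order ≤ 1), and expression-dependent detection. Passing
spike-in tests therefore demonstrates the statistical machinery —
ranking, counting, exact tails, peak rule, calling — under a clean
generative model, not robustness to array pathology.

### Benchmark conditions

- **Strong spike-in**: 12,000 genes, 600 targets with one 8mer site
  each (−1 log2), 3 vs 4 replicates. Both focal 7-mers clear the
  Bonferroni bound; across seeds the first peak falls at ranks
  600–625 with recall ≥ 0.97 of the 600 truth targets.
- **Null**: 10,000 genes, no targets, chance seed occurrences
  retained. Across 50 seeds, the focal words never cleared the bound
  (0/50) — Bonferroni over ~16k words is conservative.
- The demo analysis (`analysis/01`–`05`) uses a mixed class spectrum
  (120 × 8mer, 190 × 7mer-m8, 120 × 7mer-A1, 170 × 6mer) whose weaker
  6mer-only targets produce the realistic situation where the
  conservative first peak (rank 425) selects fewer genes than the 600
  implanted, with high precision (≈0.99) at moderate recall (≈0.63).

Problem sizes in tests and in `scripts/acceptance.py` are the
benchmark conditions above; the acceptance script's 50-run null and
12,000-gene spike-in complete in a few minutes on one CPU.

## Numerical and degenerate-input choices

- Quantile normalization tolerates all-constant columns (ties average).
- `n = 0` or `t = n_genes` cutpoints score exactly 0 for every word.
- Peak detection on an all-flat or all-below-bound profile reports
  "no significant peak" rather than guessing.
- Zero-gene simulations raise a structured pipeline error.
- Empty target tables and empty prediction sources are legal and give
  zero overlaps.
- k-mer window conservation: for N-free UTRs the per-gene counts sum
  to length − k + 1; N voids exactly the windows containing it.

## Known limitations

- The low-complexity and redundancy filters are this package's own
  concrete choices (DUST triplet score over 64-nt windows, threshold
  2.0, fraction 0.5; byte-identical duplicate removal); other tools'
  unpublished filter variants will keep slightly different gene sets.
- W, the word-family size behind the Bonferroni bound, is the number
  of distinct words observed; published bounds from other tools are
  not reproducible from their figure legends and may use a different
  family definition.
- Occurrence-based margins treat a 2-site gene as two draws; per-gene
  presence margins are a documented alternative not implemented in the
  landscape (presence is used in target calling).
- Symbol matching in list intersections is exact (case-insensitive);
  no alias/ortholog resolution.
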