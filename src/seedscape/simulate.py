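"""Synthetic miRNA-transfection experiments with known truth.

Emulates the study design the pipeline targets: ~10^4 genes on a
two-group array (3 treated vs 4 control replicates), log-normal UTR
lengths over an AU-rich background, a block of true targets whose UTRs
carry implanted seed sites and whose treated-group means are shifted
down in log2 space, and optionally a purged background in which every
chance occurrence of the focal 6mer is scrambled out of non-target
genes (a clean null for type-I-error checks).

Everything is deterministic given ``SimConfig.seed``; each stage draws
from its own child stream so the stages can also be rerun independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, PipelineError
from .expression import (CONTROL, TREATED, ExpressionMatrix, SampleDesign,
                         detection_filter, floor_and_quantile_normalize,
                         fold_change_rank, write_expression_table)
from .kmers import count_words
from .landscape import (CutpointScheme, compute_landscape,
                        leading_peak_cutoff)
from .targets import SITE_CLASSES, SeedWordSet, call_targets
from .utrs import ProbeGeneMap, UtrSet, collapse_to_genes, filter_utrs, \
    write_probe_gene_map, write_utr_fasta

_BASES = np.array(list("ACGT"))

#: per-site log2 down-shifts by site class; an 8mer site represses more
#: than a 7mer site, which represses more than a 6mer site.
DEFAULT_EFFECT = {"six": -0.3, "seven_m8": -0.6, "seven_A1": -0.6,
                  "eight": -1.0}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic experiment."""

    n_genes: int = 10_000
    utr_len_median: float = 500.0     # nt, log-normal median
    utr_len_log_sd: float = 0.6       # sd of ln(length)
    utr_min_len: int = 30
    markov_order: int = 0
    base_composition: tuple[float, float, float, float] = (0.29, 0.21,
                                                           0.21, 0.29)
    transition: np.ndarray | None = None   # 4x4, rows sum to 1 (order 1)
    site_spec: dict[str, tuple[int, int]] = field(default_factory=dict)
    effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT))
    base_mu: float = 8.0              # log2 intensity location
    sigma_gene: float = 1.5           # gene-to-gene log2 spread
    sigma_rep: float = 0.25           # replicate log2 noise
    n_treated: int = 3
    n_control: int = 4
    purge_background_sites: bool = False
    on_short: str = "regenerate"      # or "error"
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0:
            raise ContractError("n_genes must be >= 0")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ContractError("base composition must sum to 1")
        for cls in self.site_spec:
            if cls not in SITE_CLASSES:
                raise ContractError(f"unknown site class {cls!r}")
        if self.n_true_targets > self.n_genes:
            raise ContractError("more targets requested than genes")
        if any(v > 0 for v in self.effect.values()):
            raise ContractError("class shifts must be <= 0 (down-shifts)")
        if min(self.sigma_gene, self.sigma_rep) < 0:
            raise ContractError("spreads must be >= 0")

    @property
    def n_true_targets(self) -> int:
        return sum(n for n, _ in self.site_spec.values())

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream per pipeline stage."""
        return np.random.default_rng([int(self.seed), stage])


def strong_config(seed: int = 0) -> SimConfig:
    """Strong spike-in: 12,000 genes, 600 targets with one 8mer site
    each, -1 log2 shift, 3 vs 4 replicates."""
    return SimConfig(n_genes=12_000, site_spec={"eight": (600, 1)},
                     seed=seed)


def null_config(seed: int = 0, purge: bool = False) -> SimConfig:
    """No targets; chance seed occurrences retained unless purged."""
    return SimConfig(site_spec={}, purge_background_sites=purge, seed=seed)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def generate_background_utrs(cfg: SimConfig) -> UtrSet:
    """Draw n_genes background UTRs from the configured Markov model."""
    rng = cfg.rng(1)
    if cfg.n_genes == 0:
        return UtrSet({})
    lengths = np.maximum(
        cfg.utr_min_len,
        np.round(np.exp(rng.normal(np.log(cfg.utr_len_median),
                                   cfg.utr_len_log_sd,
                                   cfg.n_genes))).astype(int))
    comp = np.asarray(cfg.base_composition)
    if cfg.markov_order == 0:
        total = int(lengths.sum())
        draws = rng.choice(4, total, p=comp)
        seqs = []
        off = 0
        for L in lengths:
            seqs.append("".join(_BASES[draws[off:off + L]]))
            off += L
    elif cfg.markov_order == 1:
        trans = (np.asarray(cfg.transition) if cfg.transition is not None
                 else np.tile(comp, (4, 1)))
        if trans.shape != (4, 4) or np.any(np.abs(trans.sum(1) - 1) > 1e-9):
            raise ContractError("transition must be 4x4 with rows summing to 1")
        cum = np.cumsum(trans, axis=1)
        n = cfg.n_genes
        max_len = int(lengths.max())
        state = rng.choice(4, n, p=comp)
        chars = np.zeros((n, max_len), dtype=np.int8)
        chars[:, 0] = state
        u = rng.random((n, max_len))
        for j in range(1, max_len):
            state = (u[:, j][:, None] > cum[state]).sum(axis=1)
            chars[:, j] = state
        seqs = ["".join(_BASES[chars[i, :lengths[i]]]) for i in range(n)]
    else:
        raise ContractError("markov_order must be 0 or 1")
    return UtrSet(dict(zip(_gene_ids(cfg.n_genes), seqs)))


TRUTH_COLUMNS = ["gene_id", "is_target", "site_class", "n_sites",
                 "true_log2_shift"]


def _place_non_overlapping(rng, L: int, word_len: int, n_sites: int):
    """Uniform random non-overlapping site start positions, or None."""
    for _ in range(200):
        starts = np.sort(rng.integers(0, L - word_len + 1, n_sites))
        if n_sites == 1 or np.all(np.diff(starts) >= word_len):
            return starts
    return None


def _draw_sequence(rng, L: int, comp: np.ndarray) -> str:
    return "".join(_BASES[rng.choice(4, L, p=comp)])


def implant_sites(utrs: UtrSet, words: SeedWordSet,
                  cfg: SimConfig) -> tuple[UtrSet, pd.DataFrame]:
    """Implant seed sites into designated target genes; record the truth.

    Classes in ``site_spec`` claim disjoint gene subsets chosen uniformly
    at random. With ``purge_background_sites`` every chance occurrence of
    the focal 6mer in non-target genes is resampled away (bounded
    retries), guaranteeing a site-free background.
    """
    rng = cfg.rng(2)
    comp = np.asarray(cfg.base_composition)
    gene_ids = list(utrs.records)
    if cfg.n_true_targets > len(gene_ids):
        raise ContractError("site_spec requests more targets than genes")
    chosen = list(rng.choice(len(gene_ids), cfg.n_true_targets,
                             replace=False)) if cfg.n_true_targets else []
    records = dict(utrs.records)
    truth_rows = []
    target_set = set()
    idx = 0
    for cls, (n_cls, per_gene) in cfg.site_spec.items():
        word = words.word(cls)
        for _ in range(n_cls):
            gid = gene_ids[chosen[idx]]
            idx += 1
            target_set.add(gid)
            seq = records[gid]
            starts = _place_non_overlapping(rng, len(seq), len(word), per_gene)
            while starts is None or len(seq) < per_gene * len(word):
                if cfg.on_short == "error":
                    raise PipelineError(
                        f"UTR of {gid} too short for {per_gene} "
                        f"{len(word)}-nt sites")
                seq = _draw_sequence(
                    rng, max(len(seq) * 2, per_gene * len(word) * 4), comp)
                starts = _place_non_overlapping(rng, len(seq), len(word),
                                                per_gene)
            s = list(seq)
            for p in starts:
                s[p:p + len(word)] = word
            records[gid] = "".join(s)
            truth_rows.append((gid, True, cls, per_gene,
                               per_gene * cfg.effect[cls]))
    if cfg.purge_background_sites:
        six = words.six
        for gid in gene_ids:
            if gid in target_set:
                continue
            seq = records[gid]
            for _ in range(200):
                i = seq.find(six)
                if i < 0:
                    break
                seq = (seq[:i] + _draw_sequence(rng, len(six), comp)
                       + seq[i + len(six):])
            else:
                raise PipelineError(f"could not purge 6mer from {gid}")
            if six in seq:
                raise PipelineError(f"could not purge 6mer from {gid}")
            records[gid] = seq
    shifts = {gid: 0.0 for gid in gene_ids}
    classes = {gid: "" for gid in gene_ids}
    nsites = {gid: 0 for gid in gene_ids}
    for gid, _, cls, n, shift in truth_rows:
        shifts[gid] = shift
        classes[gid] = cls
        nsites[gid] = n
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_target": [g in target_set for g in gene_ids],
        "site_class": [classes[g] for g in gene_ids],
        "n_sites": [nsites[g] for g in gene_ids],
        "true_log2_shift": [shifts[g] for g in gene_ids],
    })
    return UtrSet(records), truth


def default_design(cfg: SimConfig) -> SampleDesign:
    ids = [f"miR_{i + 1}" for i in range(cfg.n_treated)] + \
          [f"NC_{i + 1}" for i in range(cfg.n_control)]
    groups = {s: (TREATED if s.startswith("miR_") else CONTROL) for s in ids}
    return SampleDesign(tuple(ids), groups)


def probe_map_for(truth: pd.DataFrame) -> ProbeGeneMap:
    """One probe per gene (P00001 -> G00001, ...)."""
    gene_of = {g.replace("G", "P", 1): g for g in truth["gene_id"]}
    return ProbeGeneMap(gene_of, set())


def simulate_expression(truth: pd.DataFrame, cfg: SimConfig) -> ExpressionMatrix:
    """Replicate intensity matrix with the truth's log2 down-shifts.

    Gene locations are Normal(base_mu, sigma_gene) in log2; control
    replicates add Normal(0, sigma_rep) noise, treated replicates
    additionally the gene's true shift. Intensities are 2^log2-value and
    every detection flag is true.
    """
    rng = cfg.rng(3)
    genes = truth["gene_id"].tolist()
    if not genes:
        raise PipelineError("no genes to simulate")
    design = default_design(cfg)
    n = len(genes)
    mu = rng.normal(cfg.base_mu, cfg.sigma_gene, n)
    shift = truth["true_log2_shift"].to_numpy()
    log2 = np.empty((n, cfg.n_treated + cfg.n_control))
    for j in range(cfg.n_treated):
        log2[:, j] = rng.normal(mu + shift, cfg.sigma_rep)
    for j in range(cfg.n_control):
        log2[:, cfg.n_treated + j] = rng.normal(mu, cfg.sigma_rep)
    values = np.exp2(log2)
    probes = [g.replace("G", "P", 1) for g in genes]
    detected = np.ones_like(values, dtype=bool)
    return ExpressionMatrix(probes, values, detected, design)


def write_synthetic_inputs(outdir, utrs: UtrSet, truth: pd.DataFrame,
                           expr: ExpressionMatrix,
                           pgmap: ProbeGeneMap) -> dict[str, Path]:
    """Write the standard pipeline inputs so synthetic and real data are
    consumed identically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "utr_fasta": outdir / "utrs.fasta",
        "probe_map": outdir / "probe_map.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression_table(expr, paths["expression"])
    write_utr_fasta(utrs, paths["utr_fasta"])
    write_probe_gene_map(pgmap, paths["probe_map"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def simulate_experiment(cfg: SimConfig, words: SeedWordSet):
    """Run all three generators; returns (utrs, truth, expr, pgmap)."""
    utrs = generate_background_utrs(cfg)
    if len(utrs) == 0:
        raise PipelineError("zero-gene simulation config")
    utrs, truth = implant_sites(utrs, words, cfg)
    expr = simulate_expression(truth, cfg)
    return utrs, truth, expr, probe_map_for(truth)


def end_to_end_benchmark(cfg: SimConfig, words: SeedWordSet,
                         k: int = 7, cutpoint_step: int = 25,
                         alpha: float = 0.05,
                         full_grid: bool = True) -> dict:
    """Simulate, run the whole pipeline, and score it against the truth.

    Reports the chosen cutoff vs the number of true targets, recall and
    precision of the called targets, whether both focal 7mers exceed the
    Bonferroni bound, and (with ``full_grid``) the largest |S| among
    non-focal words.
    """
    utrs, truth, expr, pgmap = simulate_experiment(cfg, words)
    norm = detection_filter(floor_and_quantile_normalize(expr))
    ranked_probes = fold_change_rank(norm)
    kept_utrs = filter_utrs(utrs)
    ranked = collapse_to_genes(ranked_probes, pgmap, kept_utrs)
    gene_order = ranked["gene_id"].tolist()
    counts = count_words(kept_utrs, k, gene_ids=gene_order)
    scheme = CutpointScheme.regular(len(gene_order), cutpoint_step)
    focal = list(words.seven_mers)
    grid = compute_landscape(ranked, counts, scheme,
                             words=None if full_grid else focal,
                             alpha=alpha)
    peak = leading_peak_cutoff(grid, focal)
    focal_above = sum(bool(grid.profile(w).max() > grid.bound)
                      for w in focal)
    true_targets = set(truth.loc[truth["is_target"], "gene_id"])
    metrics = {
        "n_genes_ranked": len(gene_order),
        "n_true_targets": len(true_targets),
        "bound": grid.bound,
        "W": grid.W,
        "focal_words_above_bound": focal_above,
        "peak_cutoff": peak.cutoff,
        "peak_value": peak.peak_value,
        "recall": 0.0,
        "precision": float("nan"),
        "n_called": 0,
    }
    if full_grid:
        nonfocal = [i for i, w in enumerate(grid.words) if w not in focal]
        metrics["max_nonfocal_abs_S"] = float(
            np.abs(grid.scores[nonfocal]).max()) if nonfocal else 0.0
    if peak.cutoff is not None:
        table = call_targets(ranked, kept_utrs, words, peak.cutoff)
        called = set(table["gene_id"])
        hit = len(called & true_targets)
        metrics["n_called"] = len(called)
        metrics["recall"] = (hit / len(true_targets)
                             if true_targets else 0.0)
        metrics["precision"] = hit / len(called) if called else float("nan")
    return metrics
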