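"""End-to-end orchestration: config in, artifacts and a run summary out.

A single YAML config drives every stage. Inputs are either real files
(expression TSV, UTR FASTA, probe map TSV) or a ``synthetic`` block, in
which case the generators write the same input files first and the rest
of the pipeline consumes them identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, PipelineError, SeedscapeError
from .expression import (SampleDesign, detection_filter,
                         floor_and_quantile_normalize, fold_change_rank,
                         read_expression_table, write_ranked_list)
from .kmers import count_words
from .landscape import (CutpointScheme, compute_landscape,
                        export_landscape_tsv, leading_peak_cutoff)
from .ora import ora, read_gmt, write_ora_table
from .simulate import SimConfig, simulate_experiment, write_synthetic_inputs
from .targets import (call_targets, class_counts, derive_seed_words,
                      intersect_predictions, read_gene_list,
                      triage_known_targets, write_target_table)
from .utrs import (collapse_to_genes, filter_utrs, read_probe_gene_map,
                   read_utr_fasta)


@dataclass
class RunSummary:
    """Machine-readable mirror of the pipeline's headline counts."""

    n_probes: int = 0
    n_probes_detected: int = 0
    n_genes_after_filter: int = 0
    chosen_cutoff: int | None = None
    peak_value: float | None = None
    bound: float = 0.0
    n_words_tested: int = 0
    n_targets: int = 0
    class_counts: dict = field(default_factory=dict)
    prediction_overlaps: dict = field(default_factory=dict)
    union_overlap: int = 0
    triage: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = ""
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def validate(self) -> None:
        cc = self.class_counts
        if cc:
            if not (cc["eight"] <= cc["seven_m8"] <= cc["six"]
                    and cc["eight"] <= cc["seven_A1"] <= cc["six"]
                    and cc["six"] == self.n_targets):
                raise PipelineError("site-class counts violate nesting")


def load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    path = Path(config)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _design_from_config(cfg: dict) -> SampleDesign:
    design = cfg.get("design")
    if not design:
        raise ConfigError("config lacks a 'design' section (sample -> group)")
    return SampleDesign.from_mapping(design)


def _sim_config(cfg: dict) -> SimConfig:
    block = dict(cfg.get("synthetic", {}))
    if "site_spec" in block:
        block["site_spec"] = {c: tuple(v)
                              for c, v in block["site_spec"].items()}
    if "seed" not in block and "seed" in cfg:
        block["seed"] = cfg["seed"]
    if "base_composition" in block:
        block["base_composition"] = tuple(block["base_composition"])
    return SimConfig(**block)


def _mirna_words(cfg: dict):
    mirna = cfg.get("mirna")
    if not mirna or "mature" not in mirna:
        raise ConfigError("config lacks mirna.mature (RNA string)")
    return derive_seed_words(mirna.get("id", "miRNA"), mirna["mature"])


def run_pipeline(config, outdir) -> RunSummary:
    """Execute every stage; on failure remove partial outputs.

    Stage order: (synthetic inputs) -> expression prep -> UTR filters and
    probe collapse -> word counting and landscape -> leading-peak cutoff
    -> target calls, prediction overlap, known-target triage ->
    over-representation analysis (optional). Idempotent given identical
    inputs and seed.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary = RunSummary(config=cfg, version=__version__,
                         seed=cfg.get("seed"))

    def _artifact(name: str, path: Path) -> Path:
        written.append(path)
        summary.artifacts[name] = str(path)
        return path

    try:
        words = _mirna_words(cfg)

        if "synthetic" in cfg:
            _stage = "synthetic_data"
            sim_cfg = _sim_config(cfg)
            utrs_all, truth, expr, pgmap = simulate_experiment(sim_cfg, words)
            in_dir = outdir / "inputs"
            paths = write_synthetic_inputs(in_dir, utrs_all, truth, expr,
                                           pgmap)
            for name, p in paths.items():
                _artifact(f"input_{name}", p)
            design = expr.design
        else:
            _stage = "expression_prep"
            inputs = cfg.get("inputs") or {}
            for key in ("expression", "utr_fasta", "probe_map"):
                if key not in inputs:
                    raise ConfigError(f"config inputs lacks '{key}'")
                if not Path(inputs[key]).exists():
                    raise ConfigError(
                        f"input file not found: {inputs[key]} ({key})")
            design = _design_from_config(cfg)
            expr = read_expression_table(inputs["expression"], design)
            utrs_all = read_utr_fasta(inputs["utr_fasta"])
            pgmap = read_probe_gene_map(inputs["probe_map"])

        _stage = "expression_prep"
        summary.n_probes = expr.n_probes
        detected = detection_filter(floor_and_quantile_normalize(expr))
        summary.n_probes_detected = detected.n_probes
        ranked_probes = fold_change_rank(detected)

        _stage = "utr_words"
        fcfg = cfg.get("filters", {})
        kept_utrs = filter_utrs(utrs_all,
                                min_len=fcfg.get("min_len", 8),
                                max_lc_fraction=fcfg.get("max_lc_fraction",
                                                         0.5))
        ranked = collapse_to_genes(ranked_probes, pgmap, kept_utrs)
        summary.n_genes_after_filter = len(ranked)
        write_ranked_list(ranked, _artifact("ranked_list",
                                            outdir / "ranked_list.tsv"))

        _stage = "landscape_core"
        lcfg = cfg.get("landscape", {})
        k = int(lcfg.get("k", 7))
        alpha = float(lcfg.get("alpha", 0.05))
        step = int(lcfg.get("cutpoint_step", 25))
        counts = count_words(kept_utrs, k,
                             gene_ids=ranked["gene_id"].tolist())
        scheme = CutpointScheme.regular(len(ranked), step)
        grid = compute_landscape(ranked, counts, scheme, alpha=alpha,
                                 W=lcfg.get("n_words"))
        focal = list(words.seven_mers) if k == 7 else [words.word(
            {6: "six", 7: "seven_m8", 8: "eight"}[k])]
        peak = leading_peak_cutoff(grid, focal)
        summary.bound = grid.bound
        summary.n_words_tested = grid.W
        summary.chosen_cutoff = peak.cutoff
        summary.peak_value = peak.peak_value
        export_landscape_tsv(grid,
                             _artifact("landscape",
                                       outdir / "landscape.tsv"),
                             focal_words=focal,
                             top=int(lcfg.get("export_top", 20)))
        side = {"bound": grid.bound, "alpha": grid.alpha, "W": grid.W,
                "k": grid.k, "chosen_cutoff": peak.cutoff,
                "focal_words": focal}
        p = _artifact("landscape_meta", outdir / "landscape.json")
        p.write_text(json.dumps(side, indent=2))

        _stage = "target_calls"
        if peak.cutoff is None:
            raise PipelineError("no significant peak in the focal profile")
        table = call_targets(ranked, kept_utrs, words, peak.cutoff)
        sources = {name: set(read_gene_list(path))
                   for name, path in (cfg.get("predictions") or {}).items()}
        report = intersect_predictions(table, sources)
        if cfg.get("known_targets"):
            known = read_gene_list(cfg["known_targets"])
            expressed = set(ranked["gene_id"])
            report = triage_known_targets(ranked, peak.cutoff, known,
                                          expressed, report)
        summary.n_targets = len(table)
        summary.class_counts = class_counts(table)
        summary.prediction_overlaps = report.per_source
        summary.union_overlap = report.union
        summary.triage = {
            "within_cutoff": report.triage_within,
            "down_beyond_cutoff": report.triage_down_beyond,
            "up_or_unchanged": report.triage_up_or_unchanged,
            "not_evaluable": report.triage_not_evaluable,
        }
        write_target_table(table, _artifact("target_table",
                                            outdir / "target_table.tsv"))

        _stage = "pathway_ora"
        if cfg.get("gene_sets"):
            collection = read_gmt(cfg["gene_sets"])
            ora_df = ora(set(table["gene_id"]), set(ranked["gene_id"]),
                         collection, alpha=alpha)
            write_ora_table(ora_df, _artifact("ora_table",
                                              outdir / "ora_table.tsv"))

        summary.validate()
        p = outdir / "summary.json"
        p.write_text(summary.to_json())
        summary.artifacts["summary"] = str(p)
        return summary
    except SeedscapeError as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise PipelineError(f"[{_stage}] {exc}") from exc
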