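"""Generate the synthetic transfection experiment used by the analysis.

Emulates the study design: 10,000 genes on a 3-treated vs 4-control
single-channel array, with 600 true targets carrying implanted
seed-complementary sites in a class mixture chosen to resemble the
published one (all targets carry the 6mer; subsets carry the 7mer-m8,
7mer-A1 or full 8mer). Also writes demo prediction lists (noisy
subsets of the truth, standing in for online target predictions,
synthetic by construction) and a synthetic gene-set collection for the
pathway step.

Writes results/synthetic/: expression.tsv, utrs.fasta, probe_map.tsv,
truth.tsv, predictions_*.txt, sets.gmt, config.yaml.
"""

from pathlib import Path

import numpy as np
import yaml

from seedscape import SimConfig, derive_seed_words
from seedscape.simulate import simulate_experiment, write_synthetic_inputs

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

MIR221 = "AGCUACAUUGUCUGCUGGGUUUC"   # reverse complement of the antagomir

cfg = SimConfig(
    n_genes=10_000,
    site_spec={"eight": (120, 1), "seven_m8": (190, 1),
               "seven_A1": (120, 1), "six": (170, 1)},
    seed=SEED,
)

words = derive_seed_words("miR-221", MIR221)
utrs, truth, expr, pgmap = simulate_experiment(cfg, words)
paths = write_synthetic_inputs(OUT, utrs, truth, expr, pgmap)

# demo prediction lists: noisy subsets of the truth plus random genes
rng = np.random.default_rng(SEED + 1)
targets = truth.loc[truth["is_target"], "gene_id"].tolist()
background = truth.loc[~truth["is_target"], "gene_id"].tolist()
for name, sens, n_noise in [("predictor_A", 0.5, 400),
                            ("predictor_B", 0.35, 700),
                            ("predictor_C", 0.25, 300)]:
    hits = rng.choice(targets, int(sens * len(targets)), replace=False)
    noise = rng.choice(background, n_noise, replace=False)
    p = OUT / f"predictions_{name}.txt"
    p.write_text("# synthetic prediction list\n"
                 + "\n".join(sorted(set(hits) | set(noise))) + "\n")
    print(f"wrote {p.name}: {int(sens * len(targets))} true + "
          f"{n_noise} noise genes")

# synthetic gene sets: one enriched in true targets, the rest random
lines = []
enriched = list(rng.choice(targets, 80, replace=False)) \
    + list(rng.choice(background, 40, replace=False))
lines.append("target_rich_set\tsynthetic\t" + "\t".join(enriched))
for i in range(9):
    members = rng.choice(truth["gene_id"], 120, replace=False)
    lines.append(f"random_set_{i}\tsynthetic\t" + "\t".join(members))
(OUT / "sets.gmt").write_text("\n".join(lines) + "\n")

config = {
    "seed": SEED,
    "mirna": {"id": "miR-221", "mature": MIR221},
    "inputs": {k: str(v) for k, v in paths.items() if k != "truth"},
    "design": {s: expr.design.group_of[s] for s in expr.design.sample_ids},
    "landscape": {"k": 7, "alpha": 0.05, "cutpoint_step": 25},
    "predictions": {n: str(OUT / f"predictions_{n}.txt")
                    for n in ("predictor_A", "predictor_B", "predictor_C")},
    "gene_sets": str(OUT / "sets.gmt"),
}
(OUT / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))

print(f"\nsimulated {cfg.n_genes} genes, {cfg.n_true_targets} true targets "
      f"({cfg.n_treated} treated vs {cfg.n_control} control replicates)")
print(f"inputs and config under {OUT}")
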