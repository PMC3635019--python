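"""Hypergeometric over-representation analysis against gene-set collections.

A transparent stand-in for commercial pathway tools: for each gene set
G in a collection, the overlap of the selected genes with G (both
intersected with the expressed-gene universe first) is scored by the
upper hypergeometric tail, with Benjamini-Hochberg adjusted p-values
reported alongside the raw-p significance flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._hyper import upper_tail_p
from .errors import ContractError, InputError


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. one pathway collection)."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self):
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise InputError(f"empty gene sets: {empty[:5]}")


def read_gmt(path, source: str = "") -> GeneSetCollection:
    """Standard GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise InputError(f"{path}:{ln}: GMT line needs >= 3 fields")
                continue
            name = parts[0]
            if name in sets:
                raise InputError(f"duplicate gene set name: {name}")
            genes = {g.upper() for g in parts[2:] if g}
            sets[name] = genes
    return GeneSetCollection(sets, source or str(path))


ORA_COLUMNS = ["set_name", "n_overlap", "n_set", "n_selected",
               "n_universe", "p", "p_adj", "significant"]


def ora(selected: set[str], universe: set[str],
        collection: GeneSetCollection, alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``selected`` in each set.

    The universe is the expressed-gene background; sets are intersected
    with it before testing. ``significant`` flags raw p < alpha (the
    convention of the pathway tools this emulates); BH-adjusted p values
    are reported alongside. Rows sorted ascending by p.
    """
    selected_u = {g.upper() for g in selected}
    universe_u = {g.upper() for g in universe}
    stray = selected_u - universe_u
    if stray:
        raise ContractError(
            f"selected genes outside the universe: {sorted(stray)[:5]}")
    n_universe = len(universe_u)
    n_selected = len(selected_u)
    rows = []
    for name, genes in collection.sets.items():
        in_universe = genes & universe_u
        n_set = len(in_universe)
        n_overlap = len(in_universe & selected_u)
        p = upper_tail_p(n_overlap, n_universe, n_set, n_selected)
        rows.append((name, n_overlap, n_set, n_selected, n_universe, p))
    df = pd.DataFrame(rows, columns=ORA_COLUMNS[:6])
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p"] < alpha
        df = df.sort_values(["p", "set_name"], kind="stable",
                            ignore_index=True)
    else:
        df["p_adj"] = []
        df["significant"] = []
    return df


def write_ora_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
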