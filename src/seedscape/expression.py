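"""Two-group expression preprocessing and fold-change ranking.

Emulates the single-channel microarray workflow used for miRNA
transfection experiments: negative intensities floored to 1.0, quantile
normalization across arrays, a keep-if-detected-anywhere probe filter,
and ranking by signed linear fold change (treated / control if the ratio
is >= 1, else the negated reciprocal, so that -1.15 means a 15%
reduction in the treated group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, InputError, PipelineError

TREATED = "treated"
CONTROL = "control"

RANKED_COLUMNS = [
    "rank", "gene_id", "probe_id", "fc_signed",
    "mean_treated", "mean_control", "mean_all",
]


@dataclass(frozen=True)
class SampleDesign:
    """Ordered samples and their treated/control assignment."""

    sample_ids: tuple[str, ...]
    group_of: Mapping[str, str]

    def __post_init__(self):
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConfigError("duplicate sample ids in design")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ConfigError(f"samples without a group: {missing}")
        bad = {s: g for s, g in self.group_of.items()
               if g not in (TREATED, CONTROL)}
        if bad:
            raise ConfigError(f"groups must be '{TREATED}' or '{CONTROL}': {bad}")
        if self.n_treated == 0 or self.n_control == 0:
            raise ConfigError("both groups must be non-empty")

    @property
    def treated_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == TREATED]

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == CONTROL]

    @property
    def n_treated(self) -> int:
        return len(self.treated_ids)

    @property
    def n_control(self) -> int:
        return len(self.control_ids)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SampleDesign":
        return cls(tuple(mapping), dict(mapping))

    def swapped(self) -> "SampleDesign":
        """Design with treated and control labels exchanged."""
        flip = {TREATED: CONTROL, CONTROL: TREATED}
        return SampleDesign(self.sample_ids,
                            {s: flip[g] for s, g in self.group_of.items()})


@dataclass
class ExpressionMatrix:
    """Probe-by-sample intensities with per-cell detection flags."""

    probe_ids: list[str]
    values: np.ndarray          # (n_probes, n_samples), float
    detected: np.ndarray        # same shape, bool
    design: SampleDesign

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        n_p, n_s = self.values.shape
        if self.detected.shape != self.values.shape:
            raise ContractError("values/detected shape mismatch")
        if n_p != len(self.probe_ids):
            raise ContractError("probe_ids length does not match values")
        if n_s != len(self.design.sample_ids):
            raise ContractError("sample count does not match design")
        if len(set(self.probe_ids)) != n_p:
            raise InputError("duplicate probe ids")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def read_expression_table(
    path,
    design: SampleDesign,
    probe_col: str = "ProbeID",
    detected_prefix: str = "Detected_",
) -> ExpressionMatrix:
    """Read a tab-separated probe x sample table.

    Expects one intensity column per declared sample and one boolean
    detection column per sample named ``<detected_prefix><sample>``.
    Raw values are preserved (flooring happens in normalization).
    """
    df = pd.read_csv(path, sep="\t", dtype={probe_col: str})
    if probe_col not in df.columns:
        raise InputError(f"missing probe column '{probe_col}' in {path}")
    for sid in design.sample_ids:
        if sid not in df.columns:
            raise ConfigError(f"expression table lacks column for sample '{sid}'")
        if detected_prefix + sid not in df.columns:
            raise ConfigError(
                f"expression table lacks detection column for sample '{sid}'")
    probes = df[probe_col].tolist()
    if len(set(probes)) != len(probes):
        dups = df[probe_col][df[probe_col].duplicated()].unique()
        raise InputError(f"duplicate probe ids: {list(dups)[:5]}")
    values = df[list(design.sample_ids)].to_numpy(dtype=float)
    det = df[[detected_prefix + s for s in design.sample_ids]]
    detected = det.to_numpy().astype(bool)
    return ExpressionMatrix(probes, values, detected, design)


def write_expression_table(
    x: ExpressionMatrix, path, probe_col: str = "ProbeID",
    detected_prefix: str = "Detected_",
) -> None:
    df = pd.DataFrame({probe_col: x.probe_ids})
    for j, sid in enumerate(x.design.sample_ids):
        df[sid] = x.values[:, j]
    for j, sid in enumerate(x.design.sample_ids):
        df[detected_prefix + sid] = x.detected[:, j].astype(int)
    df.to_csv(path, sep="\t", index=False)


def quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    """Classic quantile normalization with tie averaging.

    Value at rank r in every column becomes the mean over columns of each
    column's r-th order statistic; tied values within a column receive the
    mean of the normalized values of their tied ranks.
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    means = np.mean(np.take_along_axis(values, order, axis=0), axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        oj = order[:, j]
        sorted_col = col[oj]
        # average `means` over runs of equal values in this column
        run_starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        run_sums = np.add.reduceat(means, run_starts)
        run_lens = np.diff(np.r_[run_starts, n])
        run_means = run_sums / run_lens
        normalized_sorted = np.repeat(run_means, run_lens)
        out[oj, j] = normalized_sorted
    return out


def floor_and_quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Floor every value below 1.0 to 1.0, then quantile-normalize."""
    if x.values.shape[1] < 2:
        raise ContractError("quantile normalization needs >= 2 samples")
    floored = np.maximum(x.values, 1.0)
    return ExpressionMatrix(
        list(x.probe_ids), quantile_normalize_values(floored),
        x.detected.copy(), x.design)


def detection_filter(x: ExpressionMatrix) -> ExpressionMatrix:
    """Keep probes detected in at least one sample (row order preserved)."""
    keep = x.detected.any(axis=1)
    if not keep.any():
        raise PipelineError("no detected probes")
    probes = [p for p, k in zip(x.probe_ids, keep) if k]
    return ExpressionMatrix(probes, x.values[keep], x.detected[keep], x.design)


def _row_mean(a: np.ndarray) -> np.ndarray:
    """Row means centered on the first column, so a row of identical
    values averages to exactly that value (the fc = +1 boundary
    convention depends on it)."""
    anchor = a[:, 0]
    return anchor + (a - anchor[:, None]).mean(axis=1)


def signed_fold_change(mean_treated: np.ndarray,
                       mean_control: np.ndarray) -> np.ndarray:
    """Signed linear fold change: t/c when t >= c, else -(c/t)."""
    mt = np.asarray(mean_treated, dtype=float)
    mc = np.asarray(mean_control, dtype=float)
    up = mt >= mc
    return np.where(up, mt / mc, -(mc / mt))


def fold_change_rank(x: ExpressionMatrix) -> pd.DataFrame:
    """Rank probes from most down- to most up-regulated.

    Returns a ranked-list DataFrame (columns ``RANKED_COLUMNS``); at this
    stage ``gene_id`` is unset (probe-level list) and ``mean_all`` carries
    the across-all-samples mean used later for probe->gene collapse. Ties
    in fc_signed break by probe id so reruns are bit-identical.
    """
    t_idx = [x.design.sample_ids.index(s) for s in x.design.treated_ids]
    c_idx = [x.design.sample_ids.index(s) for s in x.design.control_ids]
    mt = _row_mean(x.values[:, t_idx])
    mc = _row_mean(x.values[:, c_idx])
    df = pd.DataFrame({
        "gene_id": pd.array([pd.NA] * x.n_probes, dtype="string"),
        "probe_id": x.probe_ids,
        "fc_signed": signed_fold_change(mt, mc),
        "mean_treated": mt,
        "mean_control": mc,
        "mean_all": x.values.mean(axis=1),
    })
    df = df.sort_values(["fc_signed", "probe_id"], kind="stable",
                        ignore_index=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def validate_ranked(df: pd.DataFrame) -> None:
    """Assert the ranked-list contract (used by downstream stages)."""
    if list(df.columns) != RANKED_COLUMNS:
        raise ContractError(f"ranked list columns must be {RANKED_COLUMNS}")
    n = len(df)
    if not np.array_equal(df["rank"].to_numpy(), np.arange(1, n + 1)):
        raise ContractError("rank must be 1..n with no gaps")
    fc = df["fc_signed"].to_numpy()
    if np.any(np.diff(fc) < 0):
        raise ContractError("entries must be sorted ascending by fc_signed")
    if np.any(np.abs(fc) < 1.0):
        raise ContractError("|fc_signed| must be >= 1 (signed convention)")


def write_ranked_list(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ranked_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": "string",
                                            "probe_id": str})
    validate_ranked(df)
    return df
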