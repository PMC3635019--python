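import math
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from seedscape import SampleDesign, ExpressionMatrix, derive_seed_words

MIR221_MATURE = "AGCUACAUUGUCUGCUGGGUUUC"


@pytest.fixture(scope="session")
def mir221_words():
    return derive_seed_words("miR-221", MIR221_MATURE)


@pytest.fixture
def two_group_design():
    return SampleDesign.from_mapping({
        "miR_1": "treated", "miR_2": "treated", "miR_3": "treated",
        "NC_1": "control", "NC_2": "control", "NC_3": "control",
        "NC_4": "control",
    })


def make_matrix(values, detected=None, design=None, probes=None):
    values = np.asarray(values, dtype=float)
    if design is None:
        n = values.shape[1]
        n_t = n // 2
        design = SampleDesign.from_mapping(
            {f"T{i}": "treated" for i in range(n_t)}
            | {f"C{i}": "control" for i in range(n - n_t)})
    if detected is None:
        detected = np.ones_like(values, dtype=bool)
    if probes is None:
        probes = [f"P{i:03d}" for i in range(values.shape[0])]
    return ExpressionMatrix(probes, values, np.asarray(detected, bool), design)


def hypergeom_tails_exact(k_obs, N, K, n):
    """Independent oracle: exact tails by rational enumeration."""
    denom = comb(N, n)
    lo, hi = max(0, n + K - N), min(K, n)
    p_enr = Fraction(sum(comb(K, x) * comb(N - K, n - x)
                         for x in range(k_obs, hi + 1)), denom)
    p_dep = Fraction(sum(comb(K, x) * comb(N - K, n - x)
                         for x in range(lo, k_obs + 1)), denom)
    return p_enr, p_dep


def signed_score_exact(k_obs, N, K, n):
    """Signed -log10 of the smaller exact tail, from the oracle."""
    p_enr, p_dep = hypergeom_tails_exact(k_obs, N, K, n)
    if p_enr < p_dep:
        return -math.log10(p_enr)
    if p_dep < p_enr:
        return math.log10(p_dep)
    return 0.0


def make_ranked(gene_ids, fcs=None):
    """Minimal gene-level ranked list for landscape/target tests."""
    n = len(gene_ids)
    if fcs is None:
        fcs = np.linspace(-3.0, 2.0, n)
        fcs = np.where(np.abs(fcs) < 1, np.sign(fcs + 1e-12) * 1.0, fcs)
        fcs = np.sort(fcs)
    return pd.DataFrame({
        "rank": np.arange(1, n + 1),
        "gene_id": pd.array(gene_ids, dtype="string"),
        "probe_id": [g.replace("G", "P", 1) for g in gene_ids],
        "fc_signed": fcs,
        "mean_treated": np.full(n, 100.0),
        "mean_control": np.full(n, 100.0),
        "mean_all": np.full(n, 100.0),
    })
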