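"""Landscape core: exact tails vs enumeration, the Bonferroni bound,
grid construction against a brute-force oracle, and the peak rule."""

import math

import numpy as np
import pytest
from scipy import sparse

from seedscape import (CutpointScheme, HypergeomInput, LandscapeGrid,
                       compute_landscape, leading_peak_cutoff,
                       multiple_testing_bound, signed_hypergeom_score)
from seedscape.errors import ContractError
from seedscape.kmers import WordCounts, word_to_code

from conftest import hypergeom_tails_exact, make_ranked, signed_score_exact


class TestSignedHypergeomScore:
    def test_full_draw_enrichment(self):
        # all 4 draws are successes: p_enr = C(5,4)*C(5,0)/C(10,4) = 5/210
        s = signed_hypergeom_score(HypergeomInput(N=10, K=5, n=4, k_obs=4))
        assert s == pytest.approx(-math.log10(5 / 210), abs=1e-12)

    def test_empty_leading_set_scores_zero(self):
        assert signed_hypergeom_score(
            HypergeomInput(N=10, K=5, n=0, k_obs=0)) == 0.0

    def test_zero_draw_depletion_symmetry(self):
        s_enr = signed_hypergeom_score(HypergeomInput(N=10, K=5, n=4, k_obs=4))
        s_dep = signed_hypergeom_score(HypergeomInput(N=10, K=5, n=4, k_obs=0))
        assert s_dep == pytest.approx(-s_enr, abs=1e-12)

    def test_invariant_violation_raises(self):
        with pytest.raises(ContractError):
            HypergeomInput(N=10, K=12, n=4, k_obs=0)
        with pytest.raises(ContractError):
            HypergeomInput(N=10, K=5, n=4, k_obs=5)

    def test_matches_enumeration_oracle_broadly(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            N = int(rng.integers(1, 13))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n + K - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            got = signed_hypergeom_score(HypergeomInput(N, K, n, k))
            assert got == pytest.approx(signed_score_exact(k, N, K, n),
                                        abs=1e-9)

    def test_complement_antisymmetry(self):
        # enrichment tail in the leading n equals depletion tail in the
        # trailing N - n (hypergeometric symmetry)
        rng = np.random.default_rng(13)
        for _ in range(100):
            N = int(rng.integers(2, 12))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n + K - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            p_enr, _ = hypergeom_tails_exact(k, N, K, n)
            _, p_dep_comp = hypergeom_tails_exact(K - k, N, K, N - n)
            assert p_enr == p_dep_comp

    def test_monotone_response_to_implanted_occurrences(self):
        # adding a focal occurrence to the leading set never lowers S
        rng = np.random.default_rng(17)
        for _ in range(500):
            N = int(rng.integers(2, 40))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n + K - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            s0 = signed_hypergeom_score(HypergeomInput(N, K, n, k))
            s1 = signed_hypergeom_score(
                HypergeomInput(N + 1, K + 1, n + 1, k + 1))
            assert s1 >= s0 - 1e-9


class TestMultipleTestingBound:
    @pytest.mark.parametrize("alpha,W,expected", [
        (0.05, 1, 1.3010299956639813),
        (0.05, 4096, 4.913389943631755),
        (0.05, 16384, 5.515449934959718),
    ])
    def test_log10_arithmetic(self, alpha, W, expected):
        assert multiple_testing_bound(alpha, W) == pytest.approx(expected,
                                                                 abs=1e-12)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ContractError):
            multiple_testing_bound(0.0, 10)
        with pytest.raises(ContractError):
            multiple_testing_bound(0.05, 0)


def dinucleotide_counts(seqs, gene_ids):
    """WordCounts for k=2 built by hand (small-instance oracle substrate)."""
    mat = np.zeros((len(seqs), 16), dtype=np.int64)
    windows = np.zeros(len(seqs), dtype=np.int64)
    for i, s in enumerate(seqs):
        for j in range(len(s) - 1):
            mat[i, word_to_code(s[j:j + 2])] += 1
            windows[i] += 1
    return WordCounts(2, list(gene_ids), sparse.csr_matrix(mat), windows)


class TestComputeLandscape:
    def test_zero_at_both_ends(self):
        seqs = ["ACGTAC", "GGCATT", "TTAACC", "ACACAC"]
        genes = [f"G{i}" for i in range(4)]
        counts = dinucleotide_counts(seqs, genes)
        ranked = make_ranked(genes)
        grid = compute_landscape(ranked, counts,
                                 CutpointScheme(cutpoints=(0, 2, 4)))
        np.testing.assert_array_equal(grid.scores[:, 0], 0.0)
        np.testing.assert_array_equal(grid.scores[:, -1], 0.0)

    def test_every_cell_matches_per_cutpoint_oracle(self):
        rng = np.random.default_rng(23)
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, int(rng.integers(2, 8)))])
                for _ in range(4)]
        genes = [f"G{i}" for i in range(4)]
        counts = dinucleotide_counts(seqs, genes)
        ranked = make_ranked(genes)
        scheme = CutpointScheme(cutpoints=(0, 2, 4))
        grid = compute_landscape(ranked, counts, scheme)
        N = counts.total_windows
        for wi, word in enumerate(grid.words):
            K = counts.word_total(word)
            for ci, t in enumerate(scheme.cutpoints):
                n = int(counts.windows[:t].sum())
                k_obs = int(counts.matrix[:t, word_to_code(word)].sum())
                expected = signed_score_exact(k_obs, N, K, n)
                assert grid.scores[wi, ci] == pytest.approx(expected,
                                                            abs=1e-9)

    def test_exhaustive_oracle_on_random_twelve_gene_lists(self):
        rng = np.random.default_rng(29)
        bases = np.array(list("ACGT"))
        for _ in range(5):
            n_genes = int(rng.integers(2, 13))
            seqs = ["".join(bases[rng.integers(0, 4,
                                               int(rng.integers(2, 6)))])
                    for _ in range(n_genes)]
            genes = [f"G{i}" for i in range(n_genes)]
            counts = dinucleotide_counts(seqs, genes)
            ranked = make_ranked(genes)
            cps = tuple(range(0, n_genes + 1))
            grid = compute_landscape(ranked, counts,
                                     CutpointScheme(cutpoints=cps))
            N = counts.total_windows
            for wi, word in enumerate(grid.words):
                K = counts.word_total(word)
                for ci, t in enumerate(cps):
                    n = int(counts.windows[:t].sum())
                    k_obs = int(counts.matrix[:t,
                                              word_to_code(word)].sum())
                    p_enr, p_dep = hypergeom_tails_exact(k_obs, N, K, n)
                    got = grid.scores[wi, ci]
                    if got > 0:
                        assert 10 ** (-got) == pytest.approx(float(p_enr),
                                                             abs=1e-9)
                    elif got < 0:
                        assert 10 ** got == pytest.approx(float(p_dep),
                                                          abs=1e-9)
                    else:
                        assert float(min(p_enr, p_dep)) == pytest.approx(
                            float(max(p_enr, p_dep)), abs=1e-9)

    def test_gene_mismatch_is_contract_error(self):
        counts = dinucleotide_counts(["ACGT"], ["G0"])
        ranked = make_ranked(["G0", "G1"])
        with pytest.raises(ContractError, match="G1"):
            compute_landscape(ranked, counts,
                              CutpointScheme(cutpoints=(0, 2)))


def grid_from_profile(values, bound):
    scheme = CutpointScheme(cutpoints=tuple(range(len(values))))
    return LandscapeGrid(7, ["W"], scheme,
                         np.asarray([values], dtype=float),
                         bound=bound, alpha=0.05, W=1)


class TestLeadingPeakCutoff:
    def test_single_peak(self):
        grid = grid_from_profile([0, 2, 6, 4, 3, 0], bound=4.2)
        res = leading_peak_cutoff(grid, ["W"])
        assert res.cutoff == 2 and res.peak_value == 6

    def test_earlier_lower_peak_wins(self):
        grid = grid_from_profile([0, 5, 3, 9, 2, 0], bound=4.2)
        res = leading_peak_cutoff(grid, ["W"])
        assert res.cutoff == 1 and res.peak_value == 5

    def test_all_below_bound_reports_no_peak(self):
        grid = grid_from_profile([0, 2, 3, 2, 0], bound=4.2)
        res = leading_peak_cutoff(grid, ["W"])
        assert res.cutoff is None and not res.significant
        assert "no significant peak" in res.message

    def test_plateau_resolves_to_first_cutpoint(self):
        grid = grid_from_profile([0, 3, 7, 7, 7, 2, 0], bound=4.2)
        res = leading_peak_cutoff(grid, ["W"])
        assert res.cutoff == 2

    def test_missing_focal_word_is_contract_error(self):
        grid = grid_from_profile([0, 1, 0], bound=1.0)
        with pytest.raises(ContractError):
            leading_peak_cutoff(grid, ["ABSENT"])
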