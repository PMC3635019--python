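"""Seed-word derivation, target calling, prediction overlap and triage."""

import numpy as np
import pytest

from seedscape import (UtrSet, call_targets, class_counts, derive_seed_words,
                       intersect_predictions, read_gene_list,
                       triage_known_targets)
from seedscape.errors import ContractError, InputError
from seedscape.targets import count_overlapping, rna_reverse_complement

from conftest import MIR221_MATURE, make_ranked


class TestDeriveSeedWords:
    def test_mir221_words_from_antagomir(self):
        # the mature miRNA is the reverse complement of the antagomir
        antagomir = "GAAACCCAGCAGACAAUGUAGCU"
        mature = rna_reverse_complement(antagomir)
        assert mature == MIR221_MATURE
        w = derive_seed_words("miR-221", mature)
        assert (w.six, w.seven_m8, w.seven_A1, w.eight) == \
            ("TGTAGC", "ATGTAGC", "TGTAGCA", "ATGTAGCA")

    def test_homopolymer(self):
        w = derive_seed_words("toy", "AAAAAAAA")
        assert (w.six, w.seven_m8, w.seven_A1, w.eight) == \
            ("TTTTTT", "TTTTTTT", "TTTTTTA", "TTTTTTTA")

    def test_substring_nesting_on_random_matures(self):
        rng = np.random.default_rng(31)
        bases = np.array(list("ACGU"))
        for _ in range(1000):
            mature = "".join(bases[rng.integers(0, 4,
                                                int(rng.integers(8, 25)))])
            w = derive_seed_words("m", mature)
            assert w.six in w.seven_m8 and w.six in w.seven_A1
            assert w.six in w.eight
            assert w.seven_m8 in w.eight and w.seven_A1 in w.eight
            assert w.seven_A1 == w.six + "A"
            assert w.eight == w.seven_m8 + "A"

    def test_seed_reverse_complement_involution(self):
        w = derive_seed_words("miR-221", MIR221_MATURE)
        seed = MIR221_MATURE[1:8]
        assert rna_reverse_complement(rna_reverse_complement(seed)) == seed
        # and the 7mer-m8 word is the DNA transliteration of rc(seed)
        assert w.seven_m8 == rna_reverse_complement(seed).replace("U", "T")

    @pytest.mark.parametrize("bad", ["ACGUACG", "ACGTXCGU"])
    def test_short_or_non_rna_rejected(self, bad):
        with pytest.raises(InputError):
            derive_seed_words("m", bad)


class TestCallTargets:
    def test_toy_flag_patterns(self, mir221_words):
        ranked = make_ranked(["G1", "G2", "G3"], fcs=[-3.0, -2.0, -1.5])
        utrs = UtrSet({"G1": "CCATGTAGCACC",   # 8mer -> all classes
                       "G2": "CCTGTAGCCC",     # 6mer only
                       "G3": "GGGGGG"})        # no site
        table = call_targets(ranked, utrs, mir221_words, T=3)
        assert table["gene_id"].tolist() == ["G1", "G2"]
        g1 = table.iloc[0]
        assert g1[["has_six", "has_seven_m8", "has_seven_A1",
                   "has_eight"]].tolist() == [True, True, True, True]
        g2 = table.iloc[1]
        assert g2[["has_six", "has_seven_m8", "has_seven_A1",
                   "has_eight"]].tolist() == [True, False, False, False]

    def test_words_absent_everywhere_gives_empty_table(self, mir221_words):
        ranked = make_ranked(["G1"], fcs=[-2.0])
        table = call_targets(ranked, UtrSet({"G1": "CCCCCCCCCC"}),
                             mir221_words, T=1)
        assert len(table) == 0

    def test_cutoff_restricts_rows(self, mir221_words):
        ranked = make_ranked(["G1", "G2"], fcs=[-3.0, -2.0])
        utrs = UtrSet({"G1": "AATGTAGCAA", "G2": "AATGTAGCAA"})
        table = call_targets(ranked, utrs, mir221_words, T=1)
        assert table["gene_id"].tolist() == ["G1"]
        with pytest.raises(ContractError):
            call_targets(ranked, utrs, mir221_words, T=3)

    def test_full_list_call_equals_plain_seed_scan(self, mir221_words):
        rng = np.random.default_rng(37)
        bases = np.array(list("ACGT"))
        genes = [f"G{i}" for i in range(30)]
        utrs = UtrSet({g: "".join(bases[rng.integers(0, 4, 60)])
                       for g in genes})
        ranked = make_ranked(genes)
        table = call_targets(ranked, utrs, mir221_words, T=len(genes))
        scan = sorted(g for g in genes
                      if mir221_words.six in utrs.records[g])
        assert sorted(table["gene_id"]) == scan

    def test_class_count_nesting(self, mir221_words):
        rng = np.random.default_rng(41)
        bases = np.array(list("ACGT"))
        genes = [f"G{i}" for i in range(200)]
        utrs = UtrSet({g: "".join(bases[rng.integers(0, 4, 120)])
                       for g in genes})
        ranked = make_ranked(genes)
        table = call_targets(ranked, utrs, mir221_words, T=len(genes))
        cc = class_counts(table)
        assert cc["eight"] <= cc["seven_m8"] <= cc["six"]
        assert cc["eight"] <= cc["seven_A1"] <= cc["six"]
        assert cc["six"] == len(table)

    def test_overlapping_occurrences_counted(self):
        assert count_overlapping("TTTTTT", "TTT") == 4
        assert count_overlapping("ABABA", "ABA") == 2


class TestIntersectPredictions:
    def test_hand_set_arithmetic(self, mir221_words):
        ranked = make_ranked(["A", "B", "C"], fcs=[-3.0, -2.0, -1.5])
        utrs = UtrSet({g: "AATGTAGCAA" for g in ["A", "B", "C"]})
        table = call_targets(ranked, utrs, mir221_words, T=3)
        report = intersect_predictions(
            table, {"source1": {"B", "C", "D"}, "source2": {"C", "E"}})
        assert report.per_source == {"source1": 2, "source2": 1}
        assert report.union == 2
        assert table.loc[table["gene_id"] == "C",
                         "predicted_by"].item() == "source1,source2"

    def test_empty_sources(self, mir221_words):
        ranked = make_ranked(["A"], fcs=[-2.0])
        table = call_targets(ranked, UtrSet({"A": "AATGTAGCAA"}),
                             mir221_words, T=1)
        report = intersect_predictions(table, {})
        assert report.union == 0 and report.per_source == {}
        assert (table["predicted_by"] == "").all()

    def test_source_equal_to_called_set(self, mir221_words):
        genes = ["A", "B"]
        ranked = make_ranked(genes, fcs=[-3.0, -2.0])
        table = call_targets(ranked,
                             UtrSet({g: "AATGTAGCAA" for g in genes}),
                             mir221_words, T=2)
        report = intersect_predictions(table, {"all": set(genes)})
        assert report.per_source["all"] == report.n_called == report.union


class TestTriageKnownTargets:
    def test_hand_partition(self):
        genes = ["A", "B", "C", "D", "E", "F", "G", "H"]
        fcs = [-4.0, -3.0, -2.5, -1.6, -1.3, 1.05, 1.4, 2.0]
        ranked = make_ranked(genes, fcs=fcs)
        known = ["A", "B", "C", "D", "E", "F", "NOTHERE"]
        report = triage_known_targets(ranked, T=3, known=known,
                                      expressed=set(genes))
        assert report.triage_within == ["A", "B", "C"]
        assert report.triage_down_beyond == ["D", "E"]
        assert report.triage_up_or_unchanged == ["F"]
        assert report.triage_not_evaluable == ["NOTHERE"]

    def test_rank_at_cutoff_is_within(self):
        ranked = make_ranked(["A", "B"], fcs=[-2.0, 1.5])
        report = triage_known_targets(ranked, T=1, known=["A"],
                                      expressed={"A", "B"})
        assert report.triage_within == ["A"]

    def test_slightly_up_gene_is_up_bucket(self):
        ranked = make_ranked(["A", "B"], fcs=[-2.0, 1.05])
        report = triage_known_targets(ranked, T=1, known=["B"],
                                      expressed={"A", "B"})
        assert report.triage_up_or_unchanged == ["B"]

    def test_partition_covers_all_evaluable(self):
        rng = np.random.default_rng(43)
        genes = [f"G{i}" for i in range(40)]
        fcs = np.sort(np.concatenate([-(1 + rng.random(20) * 3),
                                      1 + rng.random(20) * 2]))
        ranked = make_ranked(genes, fcs=fcs)
        known = list(rng.choice(genes, 15, replace=False))
        report = triage_known_targets(ranked, T=10, known=known,
                                      expressed=set(genes))
        buckets = (report.triage_within + report.triage_down_beyond
                   + report.triage_up_or_unchanged)
        assert sorted(buckets) == sorted(known)


class TestReadGeneList:
    def test_comments_and_blanks_ignored(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("# header\nRB1\n\nCTCF  # inline\nWEE1\n")
        assert read_gene_list(p) == ["RB1", "CTCF", "WEE1"]
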