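"""Coupling generalization: CDF selection, FCD scoring, CGF vectors, TPF."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from bioee.efcg import (
    CGFIndex,
    ContingencyCounts,
    CoocStats,
    FCDTable,
    build_cgf_index,
    build_fcd_table,
    cdf_score,
    cgf_vector,
    collect_cooccurrence,
    fcd_score,
    lexical_key,
    select_cdfs,
    tpf_features,
)
from bioee.errors import MappingError, UndefinedScoreError
from bioee.model import ProteinMention

from conftest import make_sentence


def brute_force_cdf(counts: ContingencyCounts) -> float:
    """Independent oracle: rebuild the instance lists and recount."""
    instances = ([("pos", True)] * counts.t + [("neg", True)] * counts.m +
                 [("pos", False)] * counts.n + [("neg", False)] * counts.k)
    t = sum(1 for lbl, has in instances if lbl == "pos" and has)
    m = sum(1 for lbl, has in instances if lbl == "neg" and has)
    n = sum(1 for lbl, has in instances if lbl == "pos" and not has)
    k = sum(1 for lbl, has in instances if lbl == "neg" and not has)
    return (t * k - m * n) ** 2 / ((t + m) * (k + n))


class TestCdfScore:
    def test_pure_feature_scores_hundred(self):
        assert cdf_score(ContingencyCounts(t=10, m=0, n=0, k=10)) == 100.0

    def test_class_independent_feature_scores_zero(self):
        assert cdf_score(ContingencyCounts(t=7, m=7, n=4, k=4)) == 0.0

    def test_label_swap_symmetry(self):
        rng = random.Random(0)
        for _ in range(200):
            t, m, n, k = (rng.randint(0, 30) for _ in range(4))
            if (t + m) == 0 or (k + n) == 0:
                continue
            a = cdf_score(ContingencyCounts(t, m, n, k))
            b = cdf_score(ContingencyCounts(m, t, k, n))
            assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_table_rejected(self):
        with pytest.raises(UndefinedScoreError):
            cdf_score(ContingencyCounts(t=0, m=0, n=5, k=5))


class TestSelectCdfs:
    def test_planted_cue_ranks_first(self):
        instances, labels = [], []
        for i in range(10):
            instances.append({"cue_A": 1.0, f"noise_{i}": 1.0})
            labels.append("pos")
        for i in range(10):
            instances.append({f"noise_{i}": 1.0})
            labels.append("neg")
        assert select_cdfs(instances, labels, k=3)[0] == "cue_A"

    def test_k_zero_returns_empty(self):
        assert select_cdfs([{"a": 1.0}, {}], ["x", "y"], k=0) == []

    def test_ties_break_lexicographically(self):
        instances = [{"b_feat": 1.0, "a_feat": 1.0}, {}]
        labels = ["pos", "neg"]
        assert select_cdfs(instances, labels, k=2) == ["a_feat", "b_feat"]

    def test_k_beyond_vocabulary_returns_everything(self):
        instances = [{"a": 1.0}, {"b": 1.0}]
        out = select_cdfs(instances, ["x", "y"], k=400)
        assert sorted(out) == ["a", "b"]


class TestFcdScore:
    def test_zero_cooccurrence_scores_zero(self):
        assert fcd_score(0, 9, 9, b=1.0) == 0.0

    def test_closed_form_one(self):
        assert fcd_score(9, 9, 9, b=1.0) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_half(self):
        assert fcd_score(99, 99, 99, b=1.0) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_cooccurrence(self):
        for ce in (9, 50, 200):
            scores = [fcd_score(co, ce, ce, 1.0) for co in range(0, ce + 1)]
            assert scores == sorted(scores)

    def test_zero_marginal_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            fcd_score(0, 0, 9, b=1.0)

    def test_nonpositive_smoothing_rejected(self):
        with pytest.raises(ValueError):
            fcd_score(1, 9, 9, b=0.0)


class TestLexicalKey:
    @pytest.mark.parametrize("item,key", [
        ("glbow:Token_In_Left_Location=gene", (("gene",),)),
        ("sloff:2_From_Tar=due to", (("due", "to"),)),
        ("ngw:a b c", (("a", "b", "c"),)),
        ("activ", (("activ",),)),
        ("clng:T1_Left^T2_Right^(7~9)=a b|c d", (("a", "b"), ("c", "d"))),
    ])
    def test_payload_extraction(self, item, key):
        assert lexical_key(item) == key


class TestCollectCooccurrence:
    def test_single_sentence_with_both_items(self):
        stats = collect_cooccurrence([["e1", "x", "c1"]], ["e1"], ["c1"])
        assert stats.count_e["e1"] == 1
        assert stats.count_c["c1"] == 1
        assert stats.co[("e1", "c1")] == 1

    def test_never_cooccurring_pair(self):
        stats = collect_cooccurrence([["e1"], ["c1"]], ["e1"], ["c1"])
        assert ("e1", "c1") not in stats.co
        assert stats.count_e["e1"] == 1 and stats.count_c["c1"] == 1

    def test_counts_match_independent_recount(self):
        rng = random.Random(3)
        vocab = [f"w{i}" for i in range(20)]
        corpus = [[rng.choice(vocab) for _ in range(6)] for _ in range(100)]
        stats = collect_cooccurrence(corpus, ["w1", "w2"], ["w3", "w4"])
        for e in ("w1", "w2"):
            assert stats.count_e.get(e, 0) == sum(1 for s in corpus if e in s)
            for c in ("w3", "w4"):
                expected = sum(1 for s in corpus if e in s and c in s)
                assert stats.co.get((e, c), 0) == expected

    def test_tsv_round_trip(self):
        stats = collect_cooccurrence([["a", "b"], ["a"]], ["a"], ["b"])
        again = CoocStats.from_tsv(stats.to_tsv())
        assert again == stats


class TestFcdTable:
    def test_all_zero_cooccurrence_gives_empty_table(self):
        stats = CoocStats(count_e={"e": 5}, count_c={"c": 5}, co={})
        assert len(build_fcd_table(stats, b=1.0)) == 0

    def test_closed_form_entries_appear_verbatim(self):
        stats = CoocStats(count_e={"e1": 9, "e2": 99}, count_c={"c1": 9, "c2": 99},
                          co={("e1", "c1"): 9, ("e2", "c2"): 99})
        table = build_fcd_table(stats, b=1.0)
        assert table.lookup("e1", "c1") == pytest.approx(1.0)
        assert table.lookup("e2", "c2") == pytest.approx(0.5)

    def test_absent_pair_looks_up_as_zero(self):
        assert FCDTable().lookup("e", "c") == 0.0

    def test_tsv_round_trip_preserves_scores(self):
        stats = CoocStats(count_e={"e1": 9}, count_c={"c1": 9}, co={("e1", "c1"): 4})
        table = build_fcd_table(stats, b=1.0)
        again = FCDTable.from_tsv(table.to_tsv())
        assert again.lookup("e1", "c1") == table.lookup("e1", "c1")


def hand_table():
    table = FCDTable()
    table.rows = {
        "f:r1=e1": {("c1", "pmi_mod"): 0.3},
        "f:r1=e2": {("c1", "pmi_mod"): 0.2, ("c2", "pmi_mod"): 0.5},
    }
    return table


class TestCgfVector:
    def test_empty_edf_set_gives_zero_vector(self):
        index = build_cgf_index(["f:r1=e1"], ["c1"])
        assert cgf_vector([], index, hand_table()) == {}

    def test_shared_root_sums_coupling_scores(self):
        index = build_cgf_index(["f:r1=e1", "f:r1=e2"], ["c1", "c2"])
        v = cgf_vector(["f:r1=e1", "f:r1=e2"], index, hand_table())
        assert v == {
            "cgf:(f:r1|c1|pmi_mod)": pytest.approx(0.5),
            "cgf:(f:r1|c2|pmi_mod)": pytest.approx(0.5),
        }

    def test_unmapped_edf_is_mapping_error(self):
        index = build_cgf_index(["f:r1=e1"], ["c1"])
        with pytest.raises(MappingError):
            cgf_vector(["f:r9=zzz"], index, hand_table())

    def test_dimension_is_product_of_axes(self):
        index = build_cgf_index(["f:r1=e1", "f:r2=e2", "f:r2=e3"], ["c1", "c2"])
        assert index.dimension == 2 * 2 * 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_additive_over_disjoint_edf_splits(self, seed):
        rng = random.Random(seed)
        edfs = [f"fam:r{rng.randint(1, 3)}=w{i}" for i in range(12)]
        table = FCDTable()
        for e in edfs:
            table.rows[e] = {(f"c{rng.randint(1, 4)}", "pmi_mod"): rng.random()}
        index = build_cgf_index(edfs, [f"c{i}" for i in range(1, 5)])
        subset = [e for e in edfs if rng.random() < 0.5]
        part_a = [e for e in subset if rng.random() < 0.5]
        part_b = [e for e in subset if e not in part_a]
        whole = cgf_vector(subset, index, table)
        merged: dict[str, float] = {}
        for part in (cgf_vector(part_a, index, table), cgf_vector(part_b, index, table)):
            for name, val in part.items():
                merged[name] = merged.get(name, 0.0) + val
        assert set(whole) == set(merged)
        for name in whole:
            assert whole[name] == pytest.approx(merged[name], abs=1e-12)


class TestTpf:
    def _sentence(self):
        return make_sentence([("PROTA", "prota", "NNP"), ("activ", "activ", "NN")])

    def _protein(self):
        return ProteinMention(id="T1", char_start=0, char_end=5, text="PROTA")

    def test_no_proteins_gives_empty_vector(self):
        assert tpf_features(self._sentence(), 1, [], None, None) == {}

    def test_scores_computed_separately_per_corpus(self):
        labeled = CoocStats(count_e={"activ": 9}, count_c={"prota": 9},
                            co={("activ", "prota"): 9})
        unlabeled = CoocStats(count_e={"activ": 99}, count_c={"prota": 99},
                              co={("activ", "prota"): 99})
        fv = tpf_features(self._sentence(), 1, [self._protein()], labeled, unlabeled)
        assert fv["tpf:max_labeled"] == pytest.approx(1.0)
        assert fv["tpf:max_unlabeled"] == pytest.approx(0.5)
        assert fv["tpf:max_labeled>=0.25"] == 1.0  # thermometer indicator

    def test_maximum_over_proteins(self):
        sent = make_sentence([("PROTA", "prota", "NNP"), ("PROTB", "protb", "NNP"),
                              ("activ", "activ", "NN")])
        prots = [ProteinMention("T1", 0, 5, "PROTA"), ProteinMention("T2", 6, 11, "PROTB")]
        stats = CoocStats(count_e={"activ": 9}, count_c={"prota": 9, "protb": 9},
                          co={("activ", "prota"): 2, ("activ", "protb"): 9})
        fv = tpf_features(sent, 2, prots, None, stats)
        assert fv["tpf:max_unlabeled"] == pytest.approx(1.0)

    def test_unseen_pair_scores_are_omitted_not_errors(self):
        stats = CoocStats()  # all counts zero: score undefined -> treated as 0
        fv = tpf_features(self._sentence(), 1, [self._protein()], stats, stats)
        assert fv == {}
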