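import pytest

from cardiomembrane.ranking import (
    consort_counts,
    rank_candidates,
    ranked_frame,
    score_candidate,
    select_novel_cardiac,
    top_candidates,
)
from cardiomembrane.types import (
    CRITERION_FLAGS,
    OrthoCluster,
    RankedCandidate,
    ValidationError,
)


def _cand(symbol, compartment="mitochondrion", **flags):
    cluster = OrthoCluster(f"H_{symbol}", f"M_{symbol}", symbol)
    return RankedCandidate(cluster=cluster, compartment=compartment, flags=flags)


class TestScore:
    def test_all_false_is_zero(self):
        assert score_candidate({f: False for f in CRITERION_FLAGS}) == 0.0

    def test_all_true_unit_weights(self):
        assert score_candidate({f: True for f in CRITERION_FLAGS}) == 7.0

    def test_partial_flags(self):
        flags = dict(
            zip(CRITERION_FLAGS, [True, True, False, False, True, True, True])
        )
        assert score_candidate(flags) == 5.0

    def test_custom_weights(self):
        flags = {"has_tm": True, "cardiac_enriched": True}
        assert score_candidate(flags, {"has_tm": 2.0, "cardiac_enriched": 0.5}) == 2.5

    def test_unknown_flag_in_weights(self):
        with pytest.raises(ValidationError):
            score_candidate({}, {"not_a_flag": 1.0})

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            score_candidate({}, {"has_tm": -1.0})


class TestRank:
    def test_descending_by_score(self):
        cands = [
            _cand("A", has_tm=True, cardiac_enriched=True, conserved=True),
            _cand("B", has_tm=True),
            _cand("C", has_tm=True, conserved=True),
        ]
        ranked = rank_candidates(cands)
        assert [c.gene_symbol for c in ranked] == ["A", "C", "B"]
        assert [c.rank for c in ranked] == [1, 2, 3]

    def test_ties_alphabetical(self):
        ranked = rank_candidates([_cand("ZZZ"), _cand("AAA"), _cand("MMM")])
        assert [c.gene_symbol for c in ranked] == ["AAA", "MMM", "ZZZ"]

    def test_single_candidate(self):
        assert rank_candidates([_cand("ONLY")])[0].rank == 1

    def test_ranks_are_permutation(self, rng):
        cands = [
            _cand(f"G{i:03d}", has_tm=bool(rng.integers(2)), conserved=bool(rng.integers(2)))
            for i in range(30)
        ]
        ranked = rank_candidates(cands)
        assert sorted(c.rank for c in ranked) == list(range(1, 31))
        scores = [c.score for c in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_stable_across_reruns(self):
        cands = [_cand("B", has_tm=True), _cand("A", has_tm=True)]
        r1 = rank_candidates(cands)
        r2 = rank_candidates(cands)
        assert [c.gene_symbol for c in r1] == [c.gene_symbol for c in r2]


class TestNovelSelection:
    def test_no_cardiac_enriched_input(self):
        assert select_novel_cardiac([_cand("A", no_cardiac_phenotype=True)]) == []

    def test_requires_both_flags(self):
        cands = [
            _cand("A", cardiac_enriched=True, no_cardiac_phenotype=True),
            _cand("B", cardiac_enriched=True, no_cardiac_phenotype=False),
            _cand("C", cardiac_enriched=False, no_cardiac_phenotype=True),
        ]
        assert [c.gene_symbol for c in select_novel_cardiac(cands)] == ["A"]

    def test_subset_and_monotone(self):
        base = [_cand("A", cardiac_enriched=False, no_cardiac_phenotype=True)]
        assert select_novel_cardiac(base) == []
        upgraded = [_cand("A", cardiac_enriched=True, no_cardiac_phenotype=True)]
        assert len(select_novel_cardiac(upgraded)) == 1


class TestTopCandidates:
    def test_score_cutoff_and_topk(self):
        ranked = rank_candidates(
            [_cand("A", has_tm=True, conserved=True), _cand("B", has_tm=True), _cand("C")]
        )
        assert [c.gene_symbol for c in top_candidates(ranked, min_score=1.0)] == ["A", "B"]
        assert [c.gene_symbol for c in top_candidates(ranked, top_k=1)] == ["A"]


class TestConsort:
    def test_empty_input_all_zero(self):
        table = consort_counts([])
        assert int(table.to_numpy().sum()) == 0

    def test_toy_hand_enumeration(self):
        cands = (
            [
                _cand(f"M{i}", "mitochondrion", cardiac_enriched=True, no_cardiac_phenotype=(i < 2))
                for i in range(3)
            ]
            + [_cand("M9", "mitochondrion")]
            + [
                _cand(f"N{i}", "nucleus", cardiac_enriched=(i == 0), no_cardiac_phenotype=True)
                for i in range(4)
            ]
            + [_cand("C1", "cytosol"), _cand("U1", "unclassified")]
        )
        table = consort_counts(cands)
        assert table.loc["mitochondrion"].tolist() == [4, 3, 2]
        assert table.loc["nucleus"].tolist() == [4, 1, 1]
        assert table.loc["cytosol"].tolist() == [1, 0, 0]
        assert table.loc["unclassified"].tolist() == [1, 0, 0]
        assert table["n_total"].sum() == len(cands)

    def test_partition_conservation(self, rng):
        comps = ["mitochondrion", "nucleus", "cytosol", "secreted"]
        cands = [
            _cand(f"G{i}", comps[int(rng.integers(4))], cardiac_enriched=bool(rng.integers(2)),
                  no_cardiac_phenotype=bool(rng.integers(2)))
            for i in range(50)
        ]
        table = consort_counts(cands)
        assert table["n_total"].sum() == 50
        assert (table["n_novel"] <= table["n_cardiac_enriched"]).all()
        assert (table["n_cardiac_enriched"] <= table["n_total"]).all()

    def test_unknown_compartment_rejected(self):
        with pytest.raises(ValidationError):
            consort_counts([_cand("A", "golgi")])


def test_ranked_frame_columns_and_order():
    ranked = rank_candidates([_cand("B", has_tm=True), _cand("A")])
    df = ranked_frame(ranked)
    assert list(df["rank"]) == [1, 2]
    assert df.columns[0] == "rank"
    assert set(CRITERION_FLAGS) <= set(df.columns)
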