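"""Medication text normalization, approximate matching, review, class rollup."""

import pandas as pd
import pytest

from p180 import (
    LevenshteinMatcher,
    MatchThresholds,
    TermLexicon,
    apply_review,
    classify_entries,
    map_to_classes,
    match_term,
    normalize_med_text,
    run_med_pipeline,
)
from p180.meds import STATUS_AUTO, STATUS_REJECTED, STATUS_REVIEW


@pytest.fixture(scope="module")
def lexicon():
    return TermLexicon.default()


class TestNormalization:
    @pytest.mark.parametrize(
        "raw, tokens",
        [
            ("Aricept 10mg QD", ["aricept"]),
            ("lisinopril/HCTZ 20-12.5", ["lisinopril", "hctz"]),
            ("Vitamin D 1000 IU", ["vitamin d"]),
            ("Metformin 500 mg BID", ["metformin"]),
            ("aspirin + dipyridamole", ["aspirin", "dipyridamole"]),
            ("fish oil 1 tab daily", ["fish oil"]),
        ],
    )
    def test_examples(self, raw, tokens):
        assert normalize_med_text(raw) == tokens

    def test_pure_dose_text_reduces_to_no_tokens(self):
        assert normalize_med_text("10mg qd") == []

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            normalize_med_text("   ")


class TestMatching:
    def test_exact_name_scores_one_and_auto_accepts(self, lexicon):
        cands = match_term("aricept", lexicon)
        assert cands[0].candidate == "aricept"
        assert cands[0].score == 1.0
        assert cands[0].status == STATUS_AUTO

    def test_transposition_scores_normalized_levenshtein(self, lexicon):
        cands = match_term("aricpet", lexicon)
        assert cands[0].candidate == "aricept"
        assert cands[0].score == pytest.approx(1 - 2 / 7, abs=1e-9)
        assert cands[0].status == STATUS_REVIEW

    def test_garbage_token_rejected(self, lexicon):
        cands = match_term("xzq9", lexicon)
        assert cands[0].status == STATUS_REJECTED

    def test_ranking_sorted_and_exact_outranks_misspelling(self, lexicon):
        cands = match_term("metformin", lexicon)
        scores = [c.score for c in cands]
        assert scores == sorted(scores, reverse=True)
        assert cands[0].score == 1.0
        assert all(c.score < 1.0 for c in cands[1:])

    def test_matcher_symmetric(self):
        m = LevenshteinMatcher()
        assert m.score("aricept", "aricpet") == m.score("aricpet", "aricept")

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            MatchThresholds(accept=0.3, review=0.5)


class TestReview:
    def _table(self, lexicon):
        meds = pd.DataFrame(
            [
                {"subject_id": "S1", "raw_text": "metfromin 500mg"},  # transposed
                {"subject_id": "S2", "raw_text": "lipitor 10mg"},
            ]
        )
        return classify_entries(meds, lexicon)

    def test_empty_review_changes_nothing(self, lexicon):
        table = self._table(lexicon)
        out = apply_review(table, pd.DataFrame(columns=["query", "action", "target"]))
        assert (out["status"] == table["status"]).all()

    def test_accept_as_routes_downstream_classes(self, lexicon):
        table = self._table(lexicon)
        assert (table.loc[table["token"] == "metfromin", "status"] == STATUS_REVIEW).all()
        review = pd.DataFrame(
            [{"query": "metfromin", "action": "accept_as", "target": "metformin"}]
        )
        out = apply_review(table, review)
        mat = map_to_classes(out, lexicon)
        assert bool(mat.loc["S1", "Biguanides"])

    def test_reviewing_auto_accepted_item_rejected(self, lexicon):
        table = self._table(lexicon)
        review = pd.DataFrame([{"query": "lipitor", "action": "reject", "target": ""}])
        with pytest.raises(ValueError, match="auto-accepted"):
            apply_review(table, review)

    def test_unknown_query_rejects_file(self, lexicon):
        table = self._table(lexicon)
        review = pd.DataFrame([{"query": "nosuchtoken", "action": "reject", "target": ""}])
        with pytest.raises(ValueError, match="unknown query"):
            apply_review(table, review)


class TestClassRollup:
    def test_single_drug_single_class(self, lexicon):
        meds = pd.DataFrame(
            [
                {"subject_id": "S1", "raw_text": "aricept 10mg"},
                {"subject_id": "S2", "raw_text": "10mg"},  # unparseable -> nothing
            ]
        )
        mat, _ = run_med_pipeline(meds, lexicon)
        assert bool(mat.loc["S1", "Anticholinesterases"])
        assert mat.loc["S1"].sum() == 1
        assert mat.loc["S2"].sum() == 0  # all-false row still present

    def test_multi_class_ingredient_sets_all_flags(self, lexicon):
        meds = pd.DataFrame([{"subject_id": "S1", "raw_text": "bupropion"}])
        mat, _ = run_med_pipeline(meds, lexicon)
        for cls in ("Aminoketone", "Norepinephrine Reuptake Inhibitor"):
            assert bool(mat.loc["S1", cls])

    def test_two_routes_to_one_class_stay_boolean(self, lexicon):
        meds = pd.DataFrame(
            [
                {"subject_id": "S1", "raw_text": "atorvastatin"},
                {"subject_id": "S1", "raw_text": "simvastatin"},
            ]
        )
        mat, _ = run_med_pipeline(meds, lexicon)
        assert mat.loc["S1", "HMG CoA reductase inhibitors"] == True  # noqa: E712

    def test_combination_product_contributes_union(self, lexicon):
        meds = pd.DataFrame([{"subject_id": "S1", "raw_text": "lisinopril/HCTZ 20-12.5"}])
        mat, _ = run_med_pipeline(meds, lexicon)
        assert bool(mat.loc["S1", "ACE inhibitors, plain"])
        assert bool(mat.loc["S1", "Thiazides, plain"])

    def test_adding_entries_is_monotone(self, lexicon):
        base = pd.DataFrame([{"subject_id": "S1", "raw_text": "aricept"}])
        more = pd.concat(
            [base, pd.DataFrame([{"subject_id": "S1", "raw_text": "metformin"}])],
            ignore_index=True,
        )
        m1, _ = run_med_pipeline(base, lexicon)
        m2, _ = run_med_pipeline(more, lexicon)
        assert (m2.loc["S1"] | ~m1.loc["S1"]).all()  # no true cell turned false

    def test_matrix_round_trips_through_class_lists(self, lexicon):
        meds = pd.DataFrame(
            [
                {"subject_id": "S1", "raw_text": "aricept"},
                {"subject_id": "S2", "raw_text": "metformin"},
                {"subject_id": "S3", "raw_text": "banana smoothie"},
            ]
        )
        mat, _ = run_med_pipeline(meds, lexicon)
        lists = {s: list(mat.columns[mat.loc[s]]) for s in mat.index}
        rebuilt = pd.DataFrame(False, index=mat.index, columns=mat.columns)
        for s, classes in lists.items():
            rebuilt.loc[s, classes] = True
        assert rebuilt.equals(mat)


def test_fixture_meds_reproduce_truth_matrix(reference_fixture):
    d, gt = reference_fixture
    paths = __import__("p180").cohort_paths(d)
    meds = pd.read_csv(paths["meds"], dtype=str)
    review = pd.read_csv(paths["med_review"], dtype=str)
    mat1, table1 = run_med_pipeline(meds, review=review)
    mat2, table2 = run_med_pipeline(meds, review=review)
    assert mat1.equals(mat2) and table1.equals(table2)  # deterministic rerun
    truth = pd.DataFrame(False, index=mat1.index, columns=mat1.columns)
    for subj, classes in gt.med_truth.items():
        if subj in truth.index:
            truth.loc[subj, classes] = True
    assert mat1.equals(truth)
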