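import pytest
from hypothesis import given, settings, strategies as st

from foodpix.catalogue import Catalogue
from foodpix.standfood import (
    DescriptionResult,
    MatchConfig,
    classify,
    describe,
    post_process,
    profile,
    retrieve_candidates,
    score_pair,
    standardize,
)


class TestRetrieveCandidates:
    def test_shared_noun_retrieves_all_holders(self, cat):
        codes = retrieve_candidates(profile("pasta"), cat)
        names = {cat[c].name for c in codes}
        assert {"fresh pasta", "dried pasta"} <= names

    def test_no_nouns_means_no_candidates(self, cat):
        assert retrieve_candidates(profile("French dressing"), cat) == []

    def test_unknown_noun_means_no_candidates(self, cat):
        # "water" is a recognized noun but no toy entry contains it
        q = profile("water")
        assert q.nouns == {"water"}
        assert retrieve_candidates(q, cat) == []


class TestScorePair:
    def test_identical_profiles_score_one(self):
        p = profile("fresh pasta")
        assert score_pair(p, p) == 1.0

    def test_disjoint_profiles_score_zero(self):
        assert score_pair(profile("tomato"), profile("pear")) == 0.0

    def test_partial_overlap_strictly_between(self):
        # query noun {pasta} vs candidate nouns {pasta} + adjective {fresh}:
        # w = 3*1 / (3*1 + 2*1) = 0.6
        w = score_pair(profile("pasta"), profile("fresh pasta"))
        assert w == pytest.approx(0.6)

    def test_symmetric(self, cat):
        a, b = profile("tomato sauce"), profile("tomato")
        assert score_pair(a, b) == score_pair(b, a)

    def test_bounded_for_all_catalogue_pairs(self, cat):
        for e1 in cat.entries:
            for e2 in cat.entries:
                w = score_pair(e1.profile, e2.profile)
                assert 0.0 <= w <= 1.0


class TestDescribe:
    def test_herring_resolves_by_levenshtein(self, cat):
        res = describe("herring", cat)
        assert res.method == "levenshtein"
        assert cat[res.best[0]].name == "herrings"
        assert res.distance == 1

    def test_french_dressing_resolves_to_salad_dressing(self, cat):
        res = describe("French dressing", cat)
        assert res.method == "levenshtein"
        assert cat[res.best[0]].name == "salad dressing"

    def test_pasta_top_alternates_are_fresh_and_dried(self, cat):
        res = describe("pasta", cat)
        assert res.method == "noun-index"
        top2 = {cat[c].name for c, _ in res.ranked[:2]}
        assert top2 == {"fresh pasta", "dried pasta"}

    def test_never_falls_back_when_index_has_candidates(self, cat):
        for entry in cat.entries:
            if entry.profile.nouns:
                assert describe(entry.name, cat).method == "noun-index"

    def test_weights_non_increasing(self, cat):
        for name in ("pasta", "tomato", "herring", "salad"):
            res = describe(name, cat)
            weights = [w for _, w in res.ranked]
            assert weights == sorted(weights, reverse=True)

    def test_deterministic(self, cat):
        assert describe("pasta", cat) == describe("pasta", cat)

    def test_empty_catalogue_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            describe("tomato", Catalogue(entries=[]))


class TestClassify:
    @pytest.mark.parametrize(
        "name,category",
        [
            ("tomato", "raw"),
            ("pear", "raw"),
            ("dried pasta", "derivative"),
            ("orange juice", "derivative"),
            ("smoked salmon", "derivative"),
            ("bread with butter", "simple composite"),
            ("rice with peas", "simple composite"),
            ("pasta salad with tuna and egg", "aggregated composite"),
            ("vegetable soup", "aggregated composite"),
        ],
    )
    def test_rule_set(self, name, category):
        assert classify(name) == category

    def test_blank_rejected(self):
        with pytest.raises(ValueError):
            classify("  ")


class TestPostProcess:
    def _desc(self, method, weight, category, distance=None):
        return DescriptionResult(
            best=("X1", weight),
            ranked=(("X1", weight),),
            method=method,
            category=category,
            distance=distance,
        )

    def test_agreement_keeps_classifier_flag_clear(self):
        cat_out, flagged = post_process("raw", self._desc("noun-index", 0.9, "raw"))
        assert (cat_out, flagged) == ("raw", False)

    def test_strong_match_overrides_classifier(self):
        cat_out, flagged = post_process(
            "raw", self._desc("noun-index", 0.8, "derivative")
        )
        assert (cat_out, flagged) == ("derivative", True)

    def test_weak_match_keeps_classifier(self):
        cat_out, flagged = post_process(
            "raw", self._desc("noun-index", 0.3, "derivative")
        )
        assert (cat_out, flagged) == ("raw", False)

    def test_close_levenshtein_match_overrides(self):
        cat_out, flagged = post_process(
            "raw", self._desc("levenshtein", 0.5, "derivative", distance=1)
        )
        assert (cat_out, flagged) == ("derivative", True)

    def test_distant_levenshtein_match_does_not(self):
        cat_out, flagged = post_process(
            "raw", self._desc("levenshtein", 0.1, "derivative", distance=6)
        )
        assert (cat_out, flagged) == ("raw", False)

    def test_threshold_configurable(self):
        cfg = MatchConfig(weight_threshold=0.2)
        cat_out, flagged = post_process(
            "raw", self._desc("noun-index", 0.3, "derivative"), cfg
        )
        assert (cat_out, flagged) == ("derivative", True)


class TestStandardize:
    def test_herring_full_chain(self, cat):
        food = standardize("herring", cat)
        assert cat[food.code].name == "herrings"
        assert food.description.method == "levenshtein"

    def test_pasta_carries_ranked_alternates(self, cat):
        food = standardize("pasta", cat)
        assert len(food.description.ranked) >= 2
        assert {cat[c].name for c, _ in food.description.ranked[:2]} == {
            "fresh pasta",
            "dried pasta",
        }

    def test_exact_name_dominance_over_whole_catalogue(self, cat):
        """A query verbatim equal to a catalogue name always wins that entry."""
        for entry in cat.entries:
            food = standardize(entry.name, cat)
            assert food.code == entry.code, entry.name

    def test_exact_match_weight_is_one_when_profiled(self, cat):
        food = standardize("dried pasta", cat)
        assert food.description.best[1] == 1.0

    def test_final_category_follows_post_processing_rules(self, cat):
        # classifier calls "salad dressing" a composite (recipe term), the
        # perfectly matched catalogue entry says derivative: strong match wins
        food = standardize("salad dressing", cat)
        assert food.classifier_category == "aggregated composite"
        assert food.final_category == "derivative"
        assert food.post_processed
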