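"""Filtering, URL normalization, dedup, flagging, review application."""

import random

import pytest

from biodata_inventory.exceptions import NormalizationError, ValidationError
from biodata_inventory.inventory import (
    InventoryConfig,
    apply_prediction_filters,
    deduplicate,
    flag_for_review,
    normalize_url,
    read_inventory,
    read_review,
    run_pipeline,
    validate_and_apply_review,
    write_inventory,
)
from biodata_inventory.records import (
    ArticlePrediction,
    BestNames,
    ClassificationResult,
    Mention,
    ReviewDecision,
)

from conftest import make_candidate, make_resource


def prediction(label="positive", names=("GoodDB",), urls=("http://good.org",), kinds=None):
    kinds = kinds or ["common"] * len(names)
    mentions = [Mention(n, k, 0.99) for n, k in zip(names, kinds)]
    return ArticlePrediction(
        pmid="1",
        classification=ClassificationResult(label, 0.99 if label == "positive" else 0.01),
        mentions=mentions,
        urls=list(urls),
    )


class TestNormalizeUrl:
    def test_scheme_and_trailing_slash_ignored(self):
        assert normalize_url("http://x.org/") == normalize_url("https://x.org") == "x.org"

    def test_different_hosts_stay_distinct(self):
        # two mirrors of the same resource keep separate keys
        a = normalize_url("http://appris.bioinfo.cnio.es")
        b = normalize_url("http://appris-tools.org")
        assert a != b

    def test_path_preserved_and_lowercased(self):
        assert normalize_url("x.org/A/b") == "x.org/a/b"

    @pytest.mark.parametrize("bad", ["", "   ", "http://", "not a url"])
    def test_incomplete_urls_raise(self, bad):
        with pytest.raises(NormalizationError):
            normalize_url(bad)


class TestApplyPredictionFilters:
    def test_positive_with_name_and_url_is_kept(self):
        kept, drops = apply_prediction_filters([prediction()])
        assert len(kept) == 1 and not drops

    def test_negative_classification_dropped(self):
        kept, drops = apply_prediction_filters([prediction(label="negative")])
        assert not kept and drops["classification"] == 1

    def test_three_urls_dropped_by_url_count_rule(self):
        pred = prediction(urls=("http://a.org", "http://b.org", "http://c.org"))
        kept, drops = apply_prediction_filters([pred])
        assert not kept and drops["url_count"] == 1

    def test_single_character_name_dropped(self):
        kept, drops = apply_prediction_filters([prediction(names=("X",))])
        assert not kept and drops["name_length"] == 1

    def test_no_mentions_dropped(self):
        kept, drops = apply_prediction_filters([prediction(names=())])
        assert not kept and drops["no_name"] == 1

    def test_record_without_complete_url_dropped(self):
        kept, drops = apply_prediction_filters([prediction(urls=())])
        assert not kept and drops["no_url"] == 1

    def test_best_prob_mirrors_best_name_confidence(self):
        (cand,), _ = apply_prediction_filters([prediction()])
        assert cand.best_prob == cand.best_names.best_name.confidence


class TestDeduplicate:
    def test_same_name_and_url_merge_keeping_latest_text(self):
        a = make_candidate("PDB", "http://pdb.org", pmid="1", date="2019-05-01", text="old")
        b = make_candidate("PDB", "https://pdb.org/", pmid="2", date="2021-05-01", text="new")
        (merged,) = deduplicate([a, b])
        assert sorted(merged.member_pmids) == ["1", "2"]
        assert merged.latest_title_abstract == "new"
        assert merged.latest_date == "2021-05-01"

    def test_name_comparison_is_case_sensitive(self):
        # distinctly cased names denote distinct resources
        a = make_candidate("Seed", "http://seed.org")
        b = make_candidate("SEED", "http://seed.org", pmid="2")
        assert len(deduplicate([a, b])) == 2

    def test_idempotent_on_its_own_output(self):
        cands = [
            make_candidate("A1", "http://a.org", pmid="1"),
            make_candidate("A1", "http://a.org/", pmid="2"),
            make_candidate("B2", "http://b.org", pmid="3"),
        ]
        once = deduplicate(cands)
        twice = deduplicate(once)
        assert {(r.best_name, r.url_key, tuple(sorted(r.member_pmids))) for r in once} == {
            (r.best_name, r.url_key, tuple(sorted(r.member_pmids))) for r in twice
        }

    def test_order_invariant_up_to_resource_ordering(self):
        rng = random.Random(4)
        cands = [
            make_candidate(f"N{i % 5}", f"http://n{i % 5}.org", pmid=str(i), date=f"20{10 + i}-01-01")
            for i in range(15)
        ]
        baseline = {
            (r.best_name, r.url_key, tuple(sorted(r.member_pmids)), r.latest_date)
            for r in deduplicate(cands)
        }
        for _ in range(20):
            rng.shuffle(cands)
            shuffled = {
                (r.best_name, r.url_key, tuple(sorted(r.member_pmids)), r.latest_date)
                for r in deduplicate(cands)
            }
            assert shuffled == baseline


class TestFlagForReview:
    def test_low_probability_flagged_strictly_below_threshold(self):
        low = make_resource("A1", "a.org", prob=0.90)
        boundary = make_resource("B2", "b.org", prob=0.978)
        flag_for_review([low, boundary])
        assert "low_prob" in low.flags
        assert "low_prob" not in boundary.flags

    def test_shared_url_flags_both_records(self):
        a = make_resource("FANTOM", "fantom.org")
        b = make_resource("FANTOM5", "fantom.org")
        flag_for_review([a, b])
        assert "duplicate_urls" in a.flags and "duplicate_urls" in b.flags
        assert "duplicate_names" not in a.flags

    def test_shared_name_flags_both_records(self):
        a = make_resource("APPRIS", "appris-tools.org")
        b = make_resource("APPRIS", "appris.bioinfo.cnio.es")
        flag_for_review([a, b])
        assert "duplicate_names" in a.flags and "duplicate_names" in b.flags

    def test_flags_are_additive(self):
        a = make_resource("X9", "x.org", prob=0.5)
        b = make_resource("X9", "x.org", prob=0.99, pmids=("2",))
        flag_for_review([a, b])
        assert a.flags == {"low_prob", "duplicate_names", "duplicate_urls"}


class TestReview:
    def setup_method(self):
        self.a = make_resource("A1", "a.org", prob=0.5)
        self.b = make_resource("A1", "b.org", pmids=("2",))
        self.c = make_resource("C3", "c.org", pmids=("3",))
        flag_for_review([self.a, self.b, self.c])

    def test_remove_drops_record(self):
        final = validate_and_apply_review(
            [self.a, self.b, self.c],
            [ReviewDecision(self.a.resource_id, "remove"),
             ReviewDecision(self.b.resource_id, "keep")],
        )
        assert {r.resource_id for r in final} == {self.b.resource_id, self.c.resource_id}

    def test_merge_moves_pmids_into_target(self):
        final = validate_and_apply_review(
            [self.a, self.b, self.c],
            [ReviewDecision(self.a.resource_id, f"merge:{self.b.resource_id}"),
             ReviewDecision(self.b.resource_id, "keep")],
        )
        target = next(r for r in final if r.resource_id == self.b.resource_id)
        assert set(target.member_pmids) == {"1", "2"}

    def test_pmids_conserved_minus_removed(self):
        decisions = [
            ReviewDecision(self.a.resource_id, "remove"),
            ReviewDecision(self.b.resource_id, f"merge:{self.c.resource_id}"),
        ]
        final = validate_and_apply_review([self.a, self.b, self.c], decisions)
        all_pmids = sorted(p for r in final for p in r.member_pmids)
        assert all_pmids == ["2", "3"]

    def test_unknown_action_value_is_validation_error(self):
        with pytest.raises(ValidationError, match="delete"):
            validate_and_apply_review(
                [self.a, self.b, self.c],
                [ReviewDecision(self.a.resource_id, "delete"),
                 ReviewDecision(self.b.resource_id, "keep")],
            )

    def test_decision_for_unknown_id_is_validation_error(self):
        with pytest.raises(ValidationError, match="unknown record"):
            validate_and_apply_review(
                [self.a, self.b, self.c],
                [ReviewDecision("feedbeef0000", "keep"),
                 ReviewDecision(self.a.resource_id, "keep"),
                 ReviewDecision(self.b.resource_id, "keep")],
            )

    def test_flagged_record_without_decision_is_validation_error(self):
        with pytest.raises(ValidationError, match="without a review decision"):
            validate_and_apply_review(
                [self.a, self.b, self.c], [ReviewDecision(self.a.resource_id, "keep")]
            )

    def test_merge_target_must_exist(self):
        with pytest.raises(ValidationError, match="target"):
            validate_and_apply_review(
                [self.a, self.b, self.c],
                [ReviewDecision(self.a.resource_id, "merge:feedbeef0000"),
                 ReviewDecision(self.b.resource_id, "keep")],
            )

    def test_partial_merge_merges_only_the_decided_record(self):
        final = validate_and_apply_review(
            [self.a, self.b, self.c],
            [ReviewDecision(self.a.resource_id, f"partial_merge:{self.c.resource_id}"),
             ReviewDecision(self.b.resource_id, "keep")],
        )
        assert {r.resource_id for r in final} == {self.b.resource_id, self.c.resource_id}
        target = next(r for r in final if r.resource_id == self.c.resource_id)
        assert set(target.member_pmids) == {"1", "3"}


class TestRunPipeline:
    def test_stage_counts_monotone_non_increasing(self, small_corpus, services):
        _, articles, _ = small_corpus
        _, report = run_pipeline(articles, services.backend)
        counts = report.counts()
        assert counts == sorted(counts, reverse=True)

    def test_rerun_is_deterministic(self, small_corpus, services):
        _, articles, _ = small_corpus
        res1, rep1 = run_pipeline(articles, services.backend)
        res2, rep2 = run_pipeline(articles, services.backend)
        assert rep1.stages == rep2.stages
        assert [r.resource_id for r in res1] == [r.resource_id for r in res2]

    def test_planted_duplicates_collapse_to_distinct_resources(self, small_corpus, services):
        spec, articles, truth = small_corpus
        resources, _ = run_pipeline(articles, services.backend)
        assert len(resources) == len(truth.resources)
        assert {(r.best_name, r.url_key) for r in resources} == truth.distinct_resource_keys()


def test_inventory_csv_roundtrip(tmp_path):
    a = make_resource("A1", "a.org", prob=0.5)
    b = make_resource("B2", "b.org", pmids=("2", "3"))
    flag_for_review([a, b])
    path = write_inventory([a, b], tmp_path / "inv.csv")
    back = read_inventory(path)
    assert [(r.resource_id, r.best_name, r.member_pmids, r.flags) for r in back] == [
        (a.resource_id, "A1", ["1"], {"low_prob"}),
        (b.resource_id, "B2", ["2", "3"], set()),
    ]


def test_read_review_requires_columns(tmp_path):
    path = tmp_path / "rev.csv"
    path.write_text("id,verdict\nx,keep\n")
    with pytest.raises(ValidationError):
        read_review(path)
    path.write_text("resource_id,action\nabc,remove\n")
    assert read_review(path) == [ReviewDecision("abc", "remove")]
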