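"""Metadata augmentation, URL protocol, archive, geolocation, funders."""

import pytest

from biodata_inventory.enrichment import (
    augment_metadata,
    check_url,
    enrich_inventory,
    funder_frequency,
    geolocate_ip,
    load_iso3166,
    match_countries,
    wayback_lookup,
)
from biodata_inventory.exceptions import EnrichmentError
from biodata_inventory.fixtures import (
    FixtureArchiveClient,
    FixtureGeoProvider,
    FixtureHttpClient,
)
from biodata_inventory.records import ArticleMetadata, UrlStatus

from conftest import make_resource


class StubMetadataClient:
    def __init__(self, data):
        self.data = data

    def metadata(self, pmid):
        return self.data.get(pmid)


class TestAugmentMetadata:
    def test_one_entry_per_pmid_with_listed_agencies(self):
        client = StubMetadataClient(
            {
                "1": {"agency": ["NIH"], "citedByCount": 5},
                "2": {"agency": ["ERC", "NIH"], "affiliation": ["EMBL, Germany"]},
            }
        )
        out = augment_metadata(["1", "2"], client)
        assert out["1"].agencies == ["NIH"] and out["1"].cited_by == 5
        assert out["2"].agencies == ["ERC", "NIH"]
        assert out["2"].affiliations == ["EMBL, Germany"]

    def test_unknown_pmid_yields_all_absent_entry(self):
        out = augment_metadata(["404"], StubMetadataClient({}))
        meta = out["404"]
        assert meta.agencies == [] and meta.affiliations == [] and meta.cited_by == 0

    def test_empty_pmid_list_rejected(self):
        with pytest.raises(ValueError):
            augment_metadata([], StubMetadataClient({}))

    def test_persistent_client_failure_raises_enrichment_error(self):
        class Failing:
            def metadata(self, pmid):
                raise ConnectionError("down")

        with pytest.raises(EnrichmentError):
            augment_metadata(["1"], Failing(), sleep=lambda _s: None)


class TestCheckUrl:
    def test_immediate_success_uses_one_attempt_and_no_delay(self):
        client = FixtureHttpClient({"http://x.org": 200})
        sleeps = []
        status = check_url("http://x.org", client, sleep=sleeps.append)
        assert status.alive and status.attempts == 1 and status.status_code == 200
        assert sleeps == []

    def test_two_timeouts_then_redirect_is_alive_after_three_attempts(self):
        client = FixtureHttpClient({"http://y.org": ["timeout", "timeout", 301]})
        sleeps = []
        status = check_url("http://y.org", client, sleep=sleeps.append)
        assert status.alive and status.attempts == 3 and status.status_code == 301
        assert sleeps == [1.0]  # one-second pause before the third attempt only

    def test_persistent_404_is_dead_with_status_recorded(self):
        client = FixtureHttpClient({"http://z.org": 404})
        status = check_url("http://z.org", client, sleep=lambda _s: None)
        assert not status.alive and status.status_code == 404 and status.attempts == 1

    def test_all_timeouts_leave_status_absent(self):
        client = FixtureHttpClient({"http://t.org": ["timeout"] * 3})
        status = check_url("http://t.org", client, sleep=lambda _s: None)
        assert not status.alive and status.status_code is None and status.attempts == 3

    def test_five_second_window_passed_to_every_attempt(self):
        client = FixtureHttpClient({"http://w.org": ["timeout", 200]})
        check_url("http://w.org", client, sleep=lambda _s: None)
        assert [t for _, t in client.calls] == [5.0, 5.0]


class TestWayback:
    def test_known_url_returns_snapshot(self):
        archive = FixtureArchiveClient({"http://x.org": "https://web.archive.org/web/1/x"})
        assert wayback_lookup("http://x.org", archive) == "https://web.archive.org/web/1/x"

    def test_dead_unarchived_url_yields_absent_without_submission(self):
        archive = FixtureArchiveClient()
        assert wayback_lookup("http://gone.org", archive, alive=False) is None
        assert archive.submissions == []

    def test_live_unarchived_url_submitted_exactly_once(self):
        archive = FixtureArchiveClient()
        snapshot = wayback_lookup("http://new.org", archive, alive=True)
        assert snapshot is not None
        assert archive.submissions == ["http://new.org"]

    def test_archive_failure_degrades_to_absent(self):
        class Broken:
            def latest_snapshot(self, url):
                raise ConnectionError("down")

        assert wayback_lookup("http://x.org", Broken()) is None


def live(url):
    return UrlStatus(url=url, attempts=1, status_code=200, alive=True)


class TestGeolocateIp:
    def test_first_provider_wins_and_second_not_called(self):
        p1 = FixtureGeoProvider("one", {".org": ("Japan", "JPN", 35.0, 139.0)})
        p2 = FixtureGeoProvider("two", {".org": ("Germany", "DEU", 52.0, 13.0)})
        geo = geolocate_ip(live("http://x.org"), [p1, p2], resolver=lambda h: h)
        assert geo.country == "Japan" and geo.provider == "one"
        assert p2.queries == []

    def test_fallback_to_second_provider(self):
        p1 = FixtureGeoProvider("one", {".edu": ("x", "XXX", 0, 0)})  # misses .org
        p2 = FixtureGeoProvider("two", {".org": ("Germany", "DEU", 52.0, 13.0)})
        geo = geolocate_ip(live("http://x.org"), [p1, p2], resolver=lambda h: h)
        assert geo.provider == "two"

    def test_status_gate_rejects_404(self):
        bad = UrlStatus(url="http://x.org", attempts=1, status_code=404, alive=False)
        with pytest.raises(ValueError):
            geolocate_ip(bad, [FixtureGeoProvider()], resolver=lambda h: h)

    def test_resolution_failure_yields_absent(self):
        def failing(host):
            raise OSError("no DNS")

        assert geolocate_ip(live("http://x.org"), [FixtureGeoProvider()], resolver=failing) is None


class TestMatchCountries:
    def test_country_name_found_in_affiliation(self):
        assert ("Japan", "JPN") in match_countries("Univ. of Tokyo, Japan")

    def test_new_mexico_substring_artifact_is_reproduced(self):
        hits = match_countries("Albuquerque, New Mexico, USA")
        assert ("Mexico", "MEX") in hits
        assert ("United States of America", "USA") in hits

    def test_informal_country_name_is_missed(self):
        # the table carries the formal name, so "South Korea" finds nothing
        hits = match_countries("Seoul, South Korea")
        assert all(alpha3 != "KOR" for _, alpha3 in hits)

    def test_alpha3_codes_match_only_as_standalone_uppercase_tokens(self):
        assert ("Germany", "DEU") in match_countries("funded by DEU grant")
        # lowercase "deu" must not trigger the DEU code (names still apply:
        # pick text free of country-name substrings)
        assert match_countries("the deus ex regno") == []

    def test_word_boundary_mode_suppresses_substring_artifact(self):
        hits = match_countries("Albuquerque, New Mexico", word_boundary=True)
        assert ("Mexico", "MEX") in hits  # "New Mexico" still contains word "Mexico"
        hits2 = match_countries("Oman", word_boundary=True)
        assert ("Oman", "OMN") in hits2
        assert match_countries("Romania", word_boundary=True) == [("Romania", "ROU")]

    def test_output_is_subset_of_table_and_deterministic(self):
        table = load_iso3166()
        names = {(e.name, e.alpha3) for e in table}
        text = "Partners in France, Brazil, and the United Kingdom (GBR)"
        hits = match_countries(text, table=table)
        assert set(hits) <= names
        assert hits == match_countries(text, table=table)

    def test_each_country_reported_once(self):
        hits = match_countries("Paris, France and Lyon, France")
        assert hits.count(("France", "FRA")) == 1


class TestFunderFrequency:
    def make_metadata(self, mapping):
        return {
            pmid: ArticleMetadata(pmid=pmid, agencies=list(agencies))
            for pmid, agencies in mapping.items()
        }

    def test_agency_on_three_resources_retained_with_count(self):
        resources = [make_resource(f"R{i}", f"r{i}.org", pmids=(str(i),)) for i in range(3)]
        meta = self.make_metadata({"0": ["NSF"], "1": ["NSF"], "2": ["NSF"]})
        table = funder_frequency(resources, meta)
        assert table.to_dict("records") == [{"agency": "NSF", "n_resources": 3}]

    def test_agency_below_min_count_dropped(self):
        resources = [make_resource(f"R{i}", f"r{i}.org", pmids=(str(i),)) for i in range(2)]
        meta = self.make_metadata({"0": ["ERC"], "1": ["ERC"]})
        assert funder_frequency(resources, meta).empty

    def test_repeat_mentions_within_one_resource_count_once(self):
        # same agency via two grants in one article + a second member article
        resources = [make_resource("R0", "r0.org", pmids=("1", "2"))]
        meta = self.make_metadata({"1": ["NIH", "NIH"], "2": ["NIH"]})
        table = funder_frequency(resources, meta, min_count=1)
        assert table.to_dict("records") == [{"agency": "NIH", "n_resources": 1}]

    def test_no_name_normalization_applied(self):
        resources = [make_resource(f"R{i}", f"r{i}.org", pmids=(str(i),)) for i in range(3)]
        meta = self.make_metadata({"0": ["NIH"], "1": ["N.I.H."], "2": ["NIH "]})
        table = funder_frequency(resources, meta, min_count=1)
        assert sorted(table["agency"]) == ["N.I.H.", "NIH", "NIH "]


def test_enrich_inventory_assembles_all_columns(small_corpus, services):
    from biodata_inventory.inventory import run_pipeline

    _, articles, _ = small_corpus
    resources, _ = run_pipeline(articles, services.backend)
    table = enrich_inventory(
        resources[:5],
        metadata_client=services.metadata,
        http_client=services.http,
        archive=services.archive,
        providers=services.geo_providers,
        resolver=services.resolver,
        sleep=lambda _s: None,
    )
    assert len(table) == 5
    assert table["url_alive"].all()
    assert (table["http_status"] == 200).all()
    assert table["wayback_url"].str.contains("web.archive.org").all()
    assert (table["ip_country"] == "United States of America").all()
    assert table["affiliation_countries"].str.len().gt(0).any()
    assert table["agencies"].str.len().gt(0).all()
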