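import pytest

from biodata_inventory.fixtures import CorpusSpec, fixture_services, generate_corpus
from biodata_inventory.records import (
    BestNames,
    CandidateRecord,
    Mention,
    ResourceRecord,
    resource_id_for,
)


@pytest.fixture(scope="session")
def small_corpus():
    """A 60-article synthetic corpus with 2 planted duplicate pairs."""
    spec = CorpusSpec(
        n_articles=60, positive_fraction=0.3, dup_pairs=2, multi_url_fraction=0.2, seed=7
    )
    articles, truth = generate_corpus(spec)
    return spec, articles, truth


@pytest.fixture()
def services(small_corpus):
    _, articles, truth = small_corpus
    return fixture_services(truth, articles)


def make_candidate(
    name: str,
    url: str,
    pmid: str = "1",
    prob: float = 0.99,
    kind: str = "common",
    date: str = "2020-01-01",
    text: str = "",
) -> CandidateRecord:
    mention = Mention(name, kind, prob)
    best = (
        BestNames(best_common=mention, best_name=mention)
        if kind == "common"
        else BestNames(best_full=mention, best_name=mention)
    )
    return CandidateRecord(
        pmid=pmid,
        best_names=best,
        urls=[url],
        best_prob=prob,
        title_abstract=text or f"about {name}",
        pub_date=date,
    )


def make_resource(
    name: str, url_key: str, prob: float = 0.99, pmids: tuple[str, ...] = ("1",)
) -> ResourceRecord:
    return ResourceRecord(
        resource_id=resource_id_for(name, url_key),
        best_name=name,
        best_common=name,
        best_full=None,
        url=f"http://{url_key}",
        url_key=url_key,
        member_pmids=list(pmids),
        best_prob=prob,
    )
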