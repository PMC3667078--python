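import random

import pytest
from hypothesis import HealthCheck, settings

from accmine.databases import Database
from accmine.jats import Article, Sentence, iter_corpus, load_article
from accmine.resolver import Whitelist, load_whitelist
from accmine.synthetic import CorpusSpec, generate_corpus, read_truth

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_article(texts, article_id="PMC1", year=2005, journal="J", zones=None):
    zones = zones or ["body"] * len(texts)
    sentences = tuple(
        Sentence(article_id, i, t, z, paragraph_index=i)
        for i, (t, z) in enumerate(zip(texts, zones))
    )
    return Article(article_id, year, journal, sentences,
                   has_back_matter=any(z != "body" for z in zones))


@pytest.fixture
def pdb_worked_example():
    """The homology-modelling sentence with a subchain suffix."""
    art = make_article(
        ["Hence in the present study, three templates (PDB IDs:1J4N, 1FX8 "
         "and 1RC2-B chain) were chosen for homology modelling."],
        article_id="PMC1866351", year=2007,
    )
    wl = Whitelist.from_pairs(
        [(Database.PDB, a) for a in ("1J4N", "1FX8", "1RC2")]
    )
    return art, wl


@pytest.fixture
def ena_worked_example():
    """The GenBank deposition sentence with an accession range."""
    art = make_article(
        ["Sequences specifically obtained for this study have been deposited "
         "in GenBank [GenBank: EF151088–EF151123 and EF153103]."],
        article_id="PMC1838906", year=2007,
    )
    pairs = [(Database.ENA, a) for a in ("EF151088", "EF151123", "EF153103")]
    # a complete whitelist for the expanded range as well
    pairs += [(Database.ENA, f"EF151{n:03d}") for n in range(88, 124)]
    return art, Whitelist.from_pairs(pairs)


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """A seeded 50-article synthetic corpus shared across tests."""
    out = tmp_path_factory.mktemp("corpus")
    spec = CorpusSpec(n_articles=50, seed=11)
    bundle = generate_corpus(spec, out)
    return bundle


@pytest.fixture(scope="session")
def corpus_articles(corpus):
    return [load_article(blob) for _, blob in iter_corpus(corpus.articles_dir)]


@pytest.fixture(scope="session")
def corpus_truth(corpus):
    return read_truth(corpus.truth_path)


@pytest.fixture(scope="session")
def corpus_whitelist(corpus):
    return load_whitelist(corpus.whitelist_path)


@pytest.fixture
def rng():
    return random.Random(12345)
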