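"""Corpus-level reporting: overlaps, fractions, trends, rates, journals."""

import pytest

from accmine.databases import Database
from accmine.jats import Mention
from accmine.stats import (
    LinkRecord,
    OverlapReport,
    annotated_fraction,
    citations_per_record,
    load_link_table,
    overlap,
    per_journal_report,
    per_year_stats,
    rate_stats,
)
from conftest import make_article


class TestOverlap:
    def test_basic_counts(self):
        rep = overlap({"x", "y"}, {"y", "z"})
        assert (rep.only_a, rep.only_b, rep.both) == (1, 1, 1)
        assert rep.total == 3

    def test_identity(self):
        rep = overlap({"x", "y"}, {"x", "y"})
        assert rep.only_a == rep.only_b == 0 and rep.both == 2

    def test_oracle_equivalence_on_random_sets(self, rng):
        universe = list(range(2000))
        a = set(rng.sample(universe, 500))
        b = set(rng.sample(universe, 500))
        rep = overlap(a, b)
        only_a = sum(1 for x in a if x not in b)
        only_b = sum(1 for x in b if x not in a)
        both = sum(1 for x in a if x in b)
        assert (rep.only_a, rep.only_b, rep.both) == (only_a, only_b, both)
        assert rep.total == len(a | b)

    def test_mention_keying(self):
        m1 = Mention(Database.ENA, "AY762362", "PMC1", "publisher")
        m2 = Mention(Database.ENA, "AY762362", "PMC2", "mined")
        pair = overlap([m1], [m2], key="pair")
        acc = overlap([m1], [m2], key="accession")
        assert (pair.only_a, pair.only_b, pair.both) == (1, 1, 0)
        assert (acc.only_a, acc.only_b, acc.both) == (0, 0, 1)

    def test_recovery_rate(self):
        rep = OverlapReport(only_a=13499 - 12170, only_b=26478, both=12170)
        assert rep.size_a == 13499
        assert round(100 * rep.recovery_of_a()) == 90


class TestAnnotatedFraction:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(9268, 410364, 2.26), (21119, 410364, 5.15), (0, 10, 0.0)],
    )
    def test_reported_fractions(self, num, den, expected):
        assert annotated_fraction(num, den) == expected

    def test_monotone_in_numerator(self):
        values = [annotated_fraction(n, 1000) for n in range(0, 1001, 50)]
        assert values == sorted(values)

    def test_errors(self):
        with pytest.raises(ValueError):
            annotated_fraction(1, 0)
        with pytest.raises(ValueError):
            annotated_fraction(11, 10)


class TestCitationsPerRecord:
    @pytest.mark.parametrize(
        "total,size,decimals,expected",
        [
            (39977, 86000, 2, 0.46),
            (160112, 266_000_000, 4, 0.0006),
            (9430, 540_000, 3, 0.017),
            (0, 100, 2, 0.0),
        ],
    )
    def test_reported_rates(self, total, size, decimals, expected):
        assert citations_per_record(total, size, decimals) == expected

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            citations_per_record(10, 0)

    def test_rate_stats_table(self):
        rows = rate_stats(
            {Database.PDB: 39977, Database.ENA: 160112},
            {Database.PDB: 86000, Database.ENA: 266_000_000},
            decimals={Database.PDB: 2, Database.ENA: 4},
        )
        assert {r.database: r.citations_per_record for r in rows} == {
            Database.PDB: 0.46,
            Database.ENA: 0.0006,
        }


def _mined(aid, db, acc):
    return Mention(db, acc, aid, "mined", "body", 0, None, True)


class TestPerYear:
    def test_totals_and_mean_over_citing_articles(self):
        arts = [
            make_article(["Text one here."], article_id="PMC1", year=2005),
            make_article(["Text two here."], article_id="PMC2", year=2005),
            make_article(["Text three here."], article_id="PMC3", year=2006),
        ]
        mentions = [
            _mined("PMC1", Database.ENA, "A10001"),
            _mined("PMC1", Database.ENA, "A10002"),
            _mined("PMC1", Database.ENA, "A10003"),
            _mined("PMC2", Database.ENA, "A10004"),
        ]
        df = per_year_stats(arts, mentions)
        row = df[(df.year == 2005) & (df.database == "ENA")].iloc[0]
        assert row.total_citations == 4
        assert row.n_citing_articles == 2
        assert row.mean_per_citing_article == 2.0
        # the 2006 article cites nothing: no row at all for 2006
        assert not (df.year == 2006).any()

    def test_incomplete_year_excluded_on_request(self):
        arts = [make_article(["Text."], article_id="PMC1", year=2012)]
        mentions = [_mined("PMC1", Database.ENA, "A10001")]
        assert per_year_stats(arts, mentions, exclude_years=[2012]).empty

    def test_yearless_articles_excluded(self):
        arts = [make_article(["Text."], article_id="PMC1", year=None)]
        mentions = [_mined("PMC1", Database.ENA, "A10001")]
        assert per_year_stats(arts, mentions).empty

    def test_synthetic_ledger_totals(self, corpus_articles, corpus_truth):
        mentions = [
            _mined(r.article_id, r.database, r.accession)
            for r in corpus_truth
            if not r.is_decoy
        ]
        df = per_year_stats(corpus_articles, mentions)
        year_of = {a.article_id: a.year for a in corpus_articles}
        for _, row in df.iterrows():
            expected = sum(
                1
                for r in corpus_truth
                if not r.is_decoy
                and r.database.value == row.database
                and year_of[r.article_id] == row.year
            )
            assert row.total_citations == expected


class TestPerJournal:
    def test_band_assignment(self):
        arts = [
            make_article(["Text."], article_id="PMC1", journal="Tagger"),
            make_article(["Text."], article_id="PMC2", journal="NonTagger"),
        ]
        pub = [
            Mention(Database.ENA, "A10001", "PMC1", "publisher"),
            Mention(Database.ENA, "A10002", "PMC1", "publisher"),
        ]
        mined = [
            _mined("PMC1", Database.ENA, "A10001"),
            _mined("PMC2", Database.ENA, "A10003"),
        ]
        df = per_journal_report(arts, pub, mined).set_index("journal")
        assert df.loc["Tagger"].band == "high"
        assert df.loc["Tagger"].publisher_fraction == 1.0
        assert df.loc["NonTagger"].band == "zero"
        assert df.loc["NonTagger"].publisher_fraction == 0.0

    def test_brute_force_recount_on_synthetic_corpus(
        self, corpus_articles, corpus_truth, corpus
    ):
        pub = [
            Mention(r.database, r.accession, r.article_id, "publisher")
            for r in corpus_truth
            if r.publisher_tagged
        ]
        mined = [
            _mined(r.article_id, r.database, r.accession)
            for r in corpus_truth
            if not r.is_decoy
        ]
        df = per_journal_report(corpus_articles, pub, mined)
        journal_of = {a.article_id: a.journal for a in corpus_articles}
        for _, row in df.iterrows():
            sup = {
                (r.database, r.accession, r.article_id)
                for r in corpus_truth
                if not r.is_decoy and journal_of[r.article_id] == row.journal
            }
            pubk = {
                (r.database, r.accession, r.article_id)
                for r in corpus_truth
                if r.publisher_tagged and journal_of[r.article_id] == row.journal
            }
            assert row.superset_citations == len(sup)
            assert row.publisher_citations == len(pubk)

    def test_high_policy_journals_band_high(self, corpus, corpus_articles, corpus_truth):
        pub = [
            Mention(r.database, r.accession, r.article_id, "publisher")
            for r in corpus_truth
            if r.publisher_tagged
        ]
        mined = [
            _mined(r.article_id, r.database, r.accession)
            for r in corpus_truth
            if not r.is_decoy
        ]
        df = per_journal_report(corpus_articles, pub, mined).set_index("journal")
        assert df.loc["Journal of Structured Archiving"].band == "high"
        assert df.loc["Annals of Untagged Biology"].band in ("zero", "none")


class TestLinkRecords:
    def test_direction_vocabulary(self):
        with pytest.raises(ValueError):
            LinkRecord(Database.ENA, "A10001", "PMC1", "sideways")

    def test_load_and_overlap(self, tmp_path):
        p = tmp_path / "links.tsv"
        p.write_text(
            "database\taccession\tarticle_id\tdirection\n"
            "ENA\tA10001\tPMC1\tarticle_to_db\n"
            "ENA\tA10001\tPMC1\tdb_to_article\n"
            "ENA\tA10002\tPMC2\tdb_to_article\n"
        )
        links = load_link_table(p)
        a2d = [l for l in links if l.direction == "article_to_db"]
        d2a = [l for l in links if l.direction == "db_to_article"]
        rep = overlap(a2d, d2a)
        assert (rep.only_a, rep.only_b, rep.both) == (0, 1, 1)
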