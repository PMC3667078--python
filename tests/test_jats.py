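"""JATS parsing, zoning, sentence segmentation and publisher-tag extraction."""

import re

import pytest
from hypothesis import given, strategies as st
from lxml import etree

from accmine.databases import Database
from accmine.jats import (
    ArticleRejected,
    DEFAULT_EXT_LINK_TYPES,
    SYNONYM_EXT_LINK_TYPES,
    extract_publisher_mentions,
    load_article,
    read_mentions_jsonl,
    read_mentions_tsv,
    segment_sentences,
    select_sentences,
    write_mentions_jsonl,
    write_mentions_tsv,
    iter_corpus,
    Mention,
)

MINIMAL = b"""<?xml version="1.0"?>
<article xmlns:xlink="http://www.w3.org/1999/xlink">
  <front>
    <journal-meta><journal-title-group><journal-title>Test J</journal-title></journal-title-group></journal-meta>
    <article-meta>
      <article-id pub-id-type="pmc">PMC42</article-id>
      <pub-date><year>2005</year></pub-date>
    </article-meta>
  </front>
  <body><p>First sentence here. Second sentence here.</p></body>
</article>
"""

FOOTNOTE_ONLY = b"""<?xml version="1.0"?>
<article>
  <front><article-meta><article-id pub-id-type="pmc">PMC43</article-id>
  <pub-date><year>2006</year></pub-date></article-meta></front>
  <body/>
  <back><fn-group><fn><p>The genome was deposited in GenBank under CP000155.</p></fn></fn-group></back>
</article>
"""


class TestLoadArticle:
    def test_minimal_document(self):
        art = load_article(MINIMAL)
        assert art.article_id == "PMC42"
        assert art.year == 2005
        assert art.journal == "Test J"
        assert [s.zone for s in art.sentences] == ["body", "body"]
        assert art.sentences[0].text == "First sentence here."

    def test_empty_body_with_footnote(self):
        art = load_article(FOOTNOTE_ONLY)
        assert [s.zone for s in art.sentences] == ["footnote"]
        assert art.has_back_matter

    def test_missing_article_id_rejected(self):
        with pytest.raises(ArticleRejected):
            load_article(b"<article><front/><body><p>Text here.</p></body></article>")

    def test_non_article_root_rejected(self):
        with pytest.raises(ArticleRejected):
            load_article(b"<note><p>Hi there.</p></note>")

    def test_malformed_xml(self):
        with pytest.raises(etree.XMLSyntaxError):
            load_article(b"<article><body>")

    def test_missing_year_kept_with_year_none(self, caplog):
        doc = MINIMAL.replace(b"<pub-date><year>2005</year></pub-date>", b"")
        art = load_article(doc)
        assert art.year is None
        assert len(art.sentences) == 2

    def test_reference_list_zone(self):
        doc = MINIMAL.replace(
            b"</body>",
            b"</body><back><ref-list><ref><mixed-citation>Someone 1999.</mixed-citation></ref></ref-list></back>",
        )
        art = load_article(doc)
        assert "reference_list" in {s.zone for s in art.sentences}


class TestSelectSentences:
    def test_zone_filtering(self):
        doc = MINIMAL.replace(
            b"</body>",
            b"</body><back><fn-group><fn><p>A footnote sentence.</p></fn></fn-group>"
            b"<ref-list><ref><mixed-citation>Ref here.</mixed-citation></ref></ref-list></back>",
        )
        art = load_article(doc)
        body_only = select_sentences(art, include_footnotes=False)
        with_fn = select_sentences(art, include_footnotes=True)
        assert [s.zone for s in body_only] == ["body", "body"]
        assert [s.zone for s in with_fn] == ["body", "body", "footnote"]
        # reference lists are never selected
        assert all(s.zone != "reference_list" for s in with_fn)
        assert set(s.index for s in body_only) <= set(s.index for s in with_fn)


class TestSegmentation:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("A done. B done.", ["A done.", "B done."]),
            ("See Fig. 2 for details.", ["See Fig. 2 for details."]),
            ("Samples from Smith et al. 2001 were reused.",
             ["Samples from Smith et al. 2001 were reused."]),
            ("", []),
            ("   ", []),
            ("One only", ["One only"]),
        ],
    )
    def test_examples(self, text, expected):
        assert segment_sentences(text) == expected

    @given(
        st.lists(
            st.text(alphabet="abcdefgh XYZ123", min_size=1, max_size=30).map(
                lambda s: s.strip()
            ).filter(bool),
            min_size=1,
            max_size=20,
        )
    )
    def test_character_conservation(self, pieces):
        text = ". ".join(pieces) + "."
        sentences = segment_sentences(text)
        assert all(s.strip() for s in sentences)
        squash = lambda s: re.sub(r"\s+", "", s)
        assert squash("".join(sentences)) == squash(text)


EXT_LINK_DOC = """<?xml version="1.0"?>
<article xmlns:xlink="http://www.w3.org/1999/xlink">
  <front><article-meta><article-id pub-id-type="pmc">PMC99</article-id>
  <pub-date><year>2010</year></pub-date></article-meta></front>
  <body><p>Structure <ext-link ext-link-type="pdb" xlink:href="1EWK">1EWK</ext-link>,
  sequence <ext-link ext-link-type="gen" xlink:href="AY762362">AY762362</ext-link>,
  protein <ext-link ext-link-type="spr" xlink:href="Q08943">Q08943</ext-link>,
  other <ext-link ext-link-type="uri" xlink:href="http://x.org">x</ext-link>.</p></body>
  <back><fn-group><fn><p>Also
  <ext-link ext-link-type="gen" xlink:href="CP000155">CP000155</ext-link>.</p></fn></fn-group></back>
</article>
""".encode()


class TestPublisherMentions:
    def test_core_type_codes(self):
        mentions, skipped = extract_publisher_mentions(EXT_LINK_DOC)
        got = {(m.database, m.accession) for m in mentions}
        assert got == {
            (Database.PDB, "1EWK"),
            (Database.ENA, "AY762362"),
            (Database.UNIPROT, "Q08943"),
            (Database.ENA, "CP000155"),
        }
        assert all(m.source == "publisher" and not m.validated for m in mentions)
        assert skipped == {"uri": 1}

    def test_footnote_zone_is_covered(self):
        mentions, _ = extract_publisher_mentions(EXT_LINK_DOC)
        zones = {m.accession: m.zone for m in mentions}
        assert zones["CP000155"] == "footnote"
        assert zones["1EWK"] == "body"

    def test_href_wins_over_disagreeing_text(self, caplog):
        doc = EXT_LINK_DOC.replace(b'xlink:href="1EWK">1EWK<', b'xlink:href="1EWK">9ZZZ<')
        mentions, _ = extract_publisher_mentions(doc)
        assert ("PDB", "1EWK") in {(m.database.value, m.accession) for m in mentions}

    def test_text_fallback_when_href_absent(self):
        doc = EXT_LINK_DOC.replace(b' xlink:href="AY762362"', b"")
        mentions, _ = extract_publisher_mentions(doc)
        assert (Database.ENA, "AY762362") in {(m.database, m.accession) for m in mentions}

    def test_synonym_type_map_extension(self):
        doc = EXT_LINK_DOC.replace(b'ext-link-type="gen"', b'ext-link-type="genbank"')
        default, skipped = extract_publisher_mentions(doc)
        assert "genbank" in skipped
        merged = dict(DEFAULT_EXT_LINK_TYPES) | dict(SYNONYM_EXT_LINK_TYPES)
        extended, _ = extract_publisher_mentions(doc, merged)
        assert (Database.ENA, "AY762362") in {(m.database, m.accession) for m in extended}


def test_mention_io_roundtrip(tmp_path):
    mentions = [
        Mention(Database.ENA, "AY762362", "PMC1", "mined", "body", 3, (10, 18), True, "cue-scope=sentence"),
        Mention(Database.PDB, "1EWK", "PMC2", "publisher", "footnote", None, None, False, ""),
    ]
    jp, tp = tmp_path / "m.jsonl", tmp_path / "m.tsv"
    write_mentions_jsonl(mentions, jp)
    write_mentions_tsv(mentions, tp)
    assert read_mentions_jsonl(jp) == mentions
    assert read_mentions_tsv(tp) == mentions


def test_synthetic_corpus_roundtrip(corpus, corpus_articles, corpus_truth):
    """Publisher extraction recovers exactly the generator's tagged pairs."""
    tagged = {
        (r.article_id, r.database, r.accession)
        for r in corpus_truth
        if r.publisher_tagged
    }
    got = set()
    for _, blob in iter_corpus(corpus.articles_dir):
        mentions, _ = extract_publisher_mentions(blob)
        got |= {(m.article_id, m.database, m.accession) for m in mentions}
    assert got == tagged
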