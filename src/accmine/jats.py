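"""Reading JATS/NLM XML articles into a zoned, sentence-segmented form.

An article is reduced to an ordered list of sentences, each labelled with
the zone it came from (front, body, back, footnote, reference_list), plus
the identifiers and publication metadata needed for corpus statistics.
Publisher-supplied structured accession citations (``ext-link`` elements)
are extracted separately and independently of sentence segmentation.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from lxml import etree

from .databases import Database
from .grammar import normalize_accession

logger = logging.getLogger(__name__)

XLINK_NS = "http://www.w3.org/1999/xlink"

ZONES = ("front", "body", "back", "footnote", "reference_list")

#: default mapping from ``ext-link-type`` codes to databases; the three codes
#: observed in publisher mark-up.  Synonym codes (genbank/embl/ddbj,
#: uniprot/swissprot) are shipped but disabled by default.
DEFAULT_EXT_LINK_TYPES: dict[str, Database] = {
    "pdb": Database.PDB,
    "gen": Database.ENA,
    "spr": Database.UNIPROT,
}

SYNONYM_EXT_LINK_TYPES: dict[str, Database] = {
    "genbank": Database.ENA,
    "embl": Database.ENA,
    "ddbj": Database.ENA,
    "uniprot": Database.UNIPROT,
    "swissprot": Database.UNIPROT,
}


class ArticleRejected(ValueError):
    """The document cannot be used as a corpus article (e.g. no PMC id)."""


@dataclass(frozen=True)
class Sentence:
    article_id: str
    index: int
    text: str
    zone: str
    paragraph_index: int = 0

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ValueError(f"unknown zone {self.zone!r}")
        if not self.text.strip():
            raise ValueError("sentence text is empty")


@dataclass(frozen=True)
class Article:
    article_id: str
    year: int | None
    journal: str | None
    sentences: tuple[Sentence, ...]
    has_back_matter: bool = False


@dataclass(frozen=True)
class Mention:
    """One accession citation, publisher-tagged or text-mined."""

    database: Database
    accession: str
    article_id: str
    source: str  # "publisher" | "mined"
    zone: str | None = None
    sentence_index: int | None = None
    char_span: tuple[int, int] | None = None
    validated: bool = False
    provenance: str = ""

    def key(self) -> tuple[str, Database, str]:
        return (self.article_id, self.database, self.accession)


@dataclass
class CorpusConfig:
    min_year: int | None = 1990
    abbreviations: tuple[str, ...] = ()


# --- sentence segmentation ---------------------------------------------------

#: tokens ending in "." that do not end a sentence
ABBREVIATIONS = (
    "fig", "figs", "et al", "al", "no", "nos", "e.g", "i.e", "cf", "vs",
    "dr", "prof", "st", "ca", "approx", "resp", "sp", "spp", "subsp",
)

_WS = re.compile(r"\s+")


def _normalize_ws(text: str) -> str:
    return _WS.sub(" ", text).strip()


_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(\[\"'])")


def segment_sentences(
    text: str, abbreviations: Iterable[str] = ABBREVIATIONS
) -> list[str]:
    """Split a plain-text paragraph into sentences.

    Rule-based and deterministic: split after sentence-final punctuation
    followed by whitespace and an upper-case/digit/bracket opener, then glue
    back splits whose left side ends in a guarded abbreviation.  Whitespace
    is normalized; non-whitespace characters are conserved.
    """
    text = _normalize_ws(text)
    if not text:
        return []
    raw = _BOUNDARY.split(text)
    guards = tuple(a.lower() for a in abbreviations)
    merged: list[str] = []
    for piece in raw:
        if merged and _ends_with_abbreviation(merged[-1], guards):
            merged[-1] = merged[-1] + " " + piece
        else:
            merged.append(piece)
    return [s for s in (p.strip() for p in merged) if s]


def _ends_with_abbreviation(chunk: str, guards: tuple[str, ...]) -> bool:
    if not chunk.endswith("."):
        return False
    stem = chunk[:-1].lower()
    return any(
        stem.endswith(g) and (len(stem) == len(g) or not stem[-len(g) - 1].isalnum())
        for g in guards
    )


# --- XML helpers -------------------------------------------------------------


def _parse(xml_document: bytes | str) -> etree._Element:
    if isinstance(xml_document, str):
        xml_document = xml_document.encode()
    try:
        root = etree.fromstring(xml_document)
    except etree.XMLSyntaxError as exc:
        raise etree.XMLSyntaxError(
            f"malformed XML: {exc}", None, exc.lineno, exc.position[1] if exc.position else 0
        ) from exc
    return root


def _element_text(elem: etree._Element, skip_tags: frozenset = frozenset()) -> str:
    """Text content with inline element boundaries replaced by spaces."""
    parts: list[str] = []

    def walk(e: etree._Element) -> None:
        if isinstance(e.tag, str) and e.tag in skip_tags:
            return
        if e.text:
            parts.append(e.text)
        for child in e:
            parts.append(" ")
            walk(child)
            parts.append(" ")
            if child.tail:
                parts.append(child.tail)

    walk(elem)
    return _normalize_ws("".join(parts))


def _find_pmc_id(root: etree._Element) -> str | None:
    for aid in root.iter("article-id"):
        if aid.get("pub-id-type") in ("pmc", "pmcid"):
            text = (aid.text or "").strip()
            if text:
                return text if text.upper().startswith("PMC") else f"PMC{text}"
    return None


def _find_year(root: etree._Element) -> int | None:
    meta = root.find(".//front/article-meta")
    scope = meta if meta is not None else root
    for pd in scope.iter("pub-date"):
        y = pd.find("year")
        if y is not None and y.text and y.text.strip().isdigit():
            return int(y.text.strip())
    return None


def _find_journal(root: etree._Element) -> str | None:
    jt = root.find(".//journal-meta//journal-title")
    if jt is not None:
        text = _element_text(jt)
        return text or None
    return None


def load_article(
    xml_document: bytes | str, config: CorpusConfig | None = None
) -> Article:
    """Parse one JATS document into a zoned, sentence-segmented Article.

    Body paragraphs (including section titles and figure/table captions) are
    segmented into ``body`` sentences; back-matter footnotes become
    ``footnote`` sentences; reference lists are zone-labelled
    ``reference_list``; any other back matter is zone ``back``.  A missing
    publication year yields ``year=None`` with a warning (such articles are
    minable but excluded from per-year statistics).
    """
    config = config or CorpusConfig()
    abbrevs = tuple(config.abbreviations) or ABBREVIATIONS
    root = _parse(xml_document)
    if root.tag != "article":
        raise ArticleRejected(f"root element is {root.tag!r}, expected 'article'")
    article_id = _find_pmc_id(root)
    if not article_id:
        raise ArticleRejected("document has no PMC article-id")
    year = _find_year(root)
    if year is None:
        logger.warning("article %s has no parseable publication year", article_id)
    journal = _find_journal(root)

    sentences: list[Sentence] = []
    para_counter = 0

    def add_block(text: str, zone: str) -> None:
        nonlocal para_counter
        sents = segment_sentences(text, abbrevs)
        if not sents:
            return
        for s in sents:
            sentences.append(
                Sentence(article_id, len(sentences), s, zone, para_counter)
            )
        para_counter += 1

    body = root.find("body")
    if body is not None:
        # figure/table captions contribute through their inner <p>/<title>
        # blocks and are zoned as body text
        for block in body.iter("p", "title"):
            add_block(_element_text(block), "body")

    back = root.find("back")
    has_back = back is not None and len(back) > 0
    if back is not None:
        for fn in back.iter("fn"):
            add_block(_element_text(fn), "footnote")
        for ref_list in back.iter("ref-list"):
            add_block(_element_text(ref_list), "reference_list")
        for block in back.iter("p"):
            if any(a.tag in ("fn", "ref-list") for a in block.iterancestors()):
                continue
            add_block(_element_text(block), "back")

    return Article(article_id, year, journal, tuple(sentences), has_back)


def select_sentences(article: Article, include_footnotes: bool = False) -> list[Sentence]:
    """Sentences eligible for mining.

    Body sentences only by default; reference lists are always excluded so
    the miner never annotates bibliographies.  ``include_footnotes=True``
    additionally admits back-matter footnotes.
    """
    zones = {"body"}
    if include_footnotes:
        zones.add("footnote")
    return [s for s in article.sentences if s.zone in zones]


# --- publisher-supplied structured citations ---------------------------------


def _zone_of(elem: etree._Element) -> str:
    for anc in [elem, *elem.iterancestors()]:
        tag = anc.tag if isinstance(anc.tag, str) else ""
        if tag == "fn":
            return "footnote"
        if tag == "ref-list":
            return "reference_list"
        if tag == "front":
            return "front"
        if tag == "back":
            return "back"
        if tag == "body":
            return "body"
    return "body"


def extract_publisher_mentions(
    xml_document: bytes | str,
    type_map: Mapping[str, Database] | None = None,
) -> tuple[list[Mention], dict[str, int]]:
    """Extract ``ext-link`` accession citations tagged by the publisher.

    One Mention per ``ext-link`` whose ``ext-link-type`` is in ``type_map``;
    the accession comes from ``xlink:href``, falling back to element text.
    All zones are covered (publisher tagging includes footnotes).  Returns
    the mentions plus a tally of skipped ``ext-link-type`` codes.
    """
    type_map = dict(DEFAULT_EXT_LINK_TYPES) if type_map is None else dict(type_map)
    root = _parse(xml_document)
    article_id = _find_pmc_id(root) or ""
    mentions: list[Mention] = []
    skipped: dict[str, int] = {}
    for el in root.iter("ext-link"):
        code = (el.get("ext-link-type") or "").lower()
        if code not in type_map:
            skipped[code] = skipped.get(code, 0) + 1
            continue
        db = type_map[code]
        href = el.get(f"{{{XLINK_NS}}}href") or el.get("href")
        text = _normalize_ws(el.text or "")
        raw = href if href else text
        if not raw:
            skipped[code] = skipped.get(code, 0) + 1
            continue
        if href and text and normalize_accession(href) != normalize_accession(text):
            logger.warning(
                "%s: ext-link href %r disagrees with text %r; using href",
                article_id, href, text,
            )
        mentions.append(
            Mention(
                database=db,
                accession=normalize_accession(raw),
                article_id=article_id,
                source="publisher",
                zone=_zone_of(el),
                validated=False,
            )
        )
    return mentions, skipped


# --- corpus ingestion and mention IO -----------------------------------------


def iter_corpus(paths: Iterable[Path] | Path) -> Iterator[tuple[Path, bytes]]:
    """Yield (path, raw XML) for a directory of articles or a list of files."""
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        files = sorted(root.glob("*.xml")) if root.is_dir() else [root]
    else:
        files = [Path(p) for p in paths]
    for f in files:
        yield f, f.read_bytes()


MENTION_COLUMNS = (
    "article_id", "database", "accession", "source", "zone",
    "sentence_index", "span_start", "span_end", "validated", "provenance",
)


def mention_to_record(m: Mention) -> dict:
    return {
        "article_id": m.article_id,
        "database": m.database.value,
        "accession": m.accession,
        "source": m.source,
        "zone": m.zone,
        "sentence_index": m.sentence_index,
        "span_start": m.char_span[0] if m.char_span else None,
        "span_end": m.char_span[1] if m.char_span else None,
        "validated": m.validated,
        "provenance": m.provenance,
    }


def mention_from_record(rec: Mapping) -> Mention:
    span = None
    if rec.get("span_start") is not None and rec.get("span_end") is not None:
        span = (int(rec["span_start"]), int(rec["span_end"]))
    si = rec.get("sentence_index")
    return Mention(
        database=Database.from_string(rec["database"]),
        accession=rec["accession"],
        article_id=rec["article_id"],
        source=rec.get("source", "mined"),
        zone=rec.get("zone") or None,
        sentence_index=int(si) if si is not None and si != "" else None,
        char_span=span,
        validated=bool(rec.get("validated", False)),
        provenance=rec.get("provenance", "") or "",
    )


def write_mentions_jsonl(mentions: Iterable[Mention], path: Path | str) -> None:
    with open(path, "w") as fh:
        for m in mentions:
            fh.write(json.dumps(mention_to_record(m)) + "\n")


def read_mentions_jsonl(path: Path | str) -> list[Mention]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(mention_from_record(json.loads(line)))
    return out


def write_mentions_tsv(mentions: Iterable[Mention], path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MENTION_COLUMNS) + "\n")
        for m in mentions:
            rec = mention_to_record(m)
            fh.write(
                "\t".join("" if rec[c] is None else str(rec[c]) for c in MENTION_COLUMNS)
                + "\n"
            )


def read_mentions_tsv(path: Path | str) -> list[Mention]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            values = line.rstrip("\n").split("\t")
            rec = {k: (v if v != "" else None) for k, v in zip(header, values)}
            if rec.get("validated") is not None:
                rec["validated"] = rec["validated"] == "True"
            out.append(mention_from_record(rec))
    return out
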