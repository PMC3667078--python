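"""The three-step accession-number annotation (ANA) algorithm.

Step 1 gates on article-level context: unless a trigger term (a database
cue word or "accession") occurs somewhere in the minable text, the article
is skipped outright.  Step 2 scans each sentence: the cue words present in
the sentence (or, by default, its enclosing paragraph) decide which
databases' shape grammars are applied, and every shape-matching token
becomes a candidate.  Step 3 validates candidates against the target
database; candidates not found there are removed, which is what eliminates
shape-matching decoys such as calendar years.

Two behaviours seen in practice are modelled explicitly: cross-database
rescue (a token carried by a GenBank cue but shaped like a UniProt
accession is reassigned to UniProt when that is the unique shape match and
validation succeeds) and accession ranges ("EF151088–EF151123"), which by
default contribute only their endpoints.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .databases import CORE_DATABASES, Database
from .grammar import (
    CueLexicon,
    PatternSpec,
    RANGE_MARKERS,
    RangeRejection,
    default_pattern_specs,
    expand_range,
    match_shapes,
    normalize_accession,
    text_tokens,
)
from .jats import Article, Mention, Sentence, select_sentences
from .resolver import Whitelist

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Pipeline configured inconsistently (e.g. validation without resolver)."""


@dataclass(frozen=True)
class AnaConfig:
    include_footnotes: bool = False
    expand_ranges: bool = False
    cue_scope: str = "sentence-then-paragraph"  # or "sentence"
    validation_enabled: bool = True
    enabled_databases: frozenset = CORE_DATABASES
    record_chain_suffix: bool = False

    def __post_init__(self) -> None:
        if not self.enabled_databases:
            raise ConfigurationError("enabled_databases must be non-empty")
        if self.cue_scope not in ("sentence", "sentence-then-paragraph"):
            raise ConfigurationError(f"unknown cue_scope {self.cue_scope!r}")


@dataclass(frozen=True)
class Candidate:
    database: Database
    token: str
    sentence: Sentence
    char_span: tuple[int, int]
    cue_scope: str  # "sentence" | "paragraph"
    provenance: str = ""


def detect_article_context(
    article: Article, lexicon: CueLexicon, include_footnotes: bool = False
) -> bool:
    """Step 1: does any article-level trigger term occur in minable text?"""
    terms = lexicon.article_terms
    return any(
        terms & text_tokens(s.text)
        for s in select_sentences(article, include_footnotes)
    )


def detect_sentence_context(sentence: Sentence, lexicon: CueLexicon) -> set:
    """Databases with at least one cue term present as a whole token."""
    tokens = text_tokens(sentence.text)
    return {db for db, cues in lexicon.sentence_cues.items() if cues & tokens}


_RANGE_GAP = re.compile(rf"^\s*[{RANGE_MARKERS}]\s*$")
_CHAIN_SUFFIX = re.compile(r"^-([A-Za-z])(?![A-Za-z0-9])")


def _find_ranges(
    matches: list[tuple[str, tuple[int, int]]], text: str
) -> list[tuple[int, int]]:
    """Indices (i, i+1) of consecutive same-database matches joined by a dash."""
    pairs = []
    for i in range(len(matches) - 1):
        gap = text[matches[i][1][1] : matches[i + 1][1][0]]
        if _RANGE_GAP.match(gap):
            pairs.append((i, i + 1))
    return pairs


def annotate_article(
    article: Article,
    config: AnaConfig | None = None,
    lexicon: CueLexicon | None = None,
    patterns: Mapping[Database, PatternSpec] | None = None,
    resolver: Whitelist | None = None,
) -> list[Mention]:
    """Run the full three-step annotation over one article.

    Returns mined Mentions ordered by sentence index then span start.  With
    ``validation_enabled`` every emitted mention passed the resolver lookup
    (``validated=True``); with validation off all candidates are emitted
    unvalidated.
    """
    config = config or AnaConfig()
    lexicon = (lexicon or CueLexicon()).restricted(config.enabled_databases)
    patterns = patterns or default_pattern_specs(config.enabled_databases)
    if config.validation_enabled and resolver is None:
        raise ConfigurationError("validation enabled but no resolver supplied")

    if not detect_article_context(article, lexicon, config.include_footnotes):
        return []

    selected = select_sentences(article, config.include_footnotes)
    sentence_cues = {s.index: detect_sentence_context(s, lexicon) for s in selected}
    paragraph_cues: dict[int, set] = {}
    for s in selected:
        paragraph_cues.setdefault(s.paragraph_index, set()).update(
            sentence_cues[s.index]
        )

    candidates: list[Candidate] = []
    for sent in selected:
        cued = set(sentence_cues[sent.index])
        scope = "sentence"
        if not cued and config.cue_scope == "sentence-then-paragraph":
            cued = set(paragraph_cues.get(sent.paragraph_index, ()))
            scope = "paragraph"
        cued &= config.enabled_databases
        if not cued:
            continue
        all_matches = {
            db: match_shapes(sent.text, db, patterns.get(db))
            for db in config.enabled_databases
        }
        cued_spans = {m[1] for db in cued for m in all_matches[db]}
        for db in sorted(cued, key=lambda d: d.value):
            matches = all_matches[db]
            for token, span in matches:
                prov = ""
                if config.record_chain_suffix:
                    m = _CHAIN_SUFFIX.match(sent.text[span[1] :])
                    if m:
                        prov = f"chain={m.group(1).upper()}"
                candidates.append(Candidate(db, token, sent, span, scope, prov))
            for i, j in _find_ranges(matches, sent.text):
                start_tok, end_tok = matches[i][0], matches[j][0]
                if not config.expand_ranges:
                    continue  # endpoints already emitted individually
                try:
                    full = expand_range(start_tok, end_tok, db, enabled=True)
                except RangeRejection as exc:
                    logger.debug("range rejected in %s: %s", sent.article_id, exc)
                    continue
                whole = (matches[i][1][0], matches[j][1][1])
                for acc in full[1:-1]:
                    candidates.append(
                        Candidate(db, acc, sent, whole, scope, "range")
                    )
        # cross-database rescue: a token that fails every cued database's
        # shapes but matches exactly one other enabled database is handed to
        # that database, subject to validation
        if config.validation_enabled:
            other_by_span: dict[tuple[int, int], list[tuple[Database, str]]] = {}
            for db in sorted(config.enabled_databases - cued, key=lambda d: d.value):
                for token, span in all_matches[db]:
                    if span in cued_spans:
                        continue
                    other_by_span.setdefault(span, []).append((db, token))
            for span, hits in other_by_span.items():
                if len(hits) == 1:
                    db, token = hits[0]
                    candidates.append(
                        Candidate(db, token, sent, span, scope, "rescued")
                    )

    return _validate(candidates, config, resolver)


def _validate(
    candidates: list[Candidate], config: AnaConfig, resolver: Whitelist | None
) -> list[Mention]:
    mentions: list[Mention] = []
    removed = 0
    for cand in candidates:
        accession = normalize_accession(cand.token)
        if config.validation_enabled:
            if not resolver.contains(cand.database, accession):
                removed += 1
                continue
            validated = True
        else:
            if cand.provenance == "rescued":
                continue  # rescue requires successful validation
            validated = False
        prov_bits = [p for p in (cand.provenance, f"cue-scope={cand.cue_scope}") if p]
        mentions.append(
            Mention(
                database=cand.database,
                accession=accession,
                article_id=cand.sentence.article_id,
                source="mined",
                zone=cand.sentence.zone,
                sentence_index=cand.sentence.index,
                char_span=cand.char_span,
                validated=validated,
                provenance=";".join(prov_bits),
            )
        )
    if removed:
        logger.debug("validation removed %d candidates", removed)
    # flag spans where several databases' mentions survived
    by_span: dict[tuple, set] = {}
    for m in mentions:
        by_span.setdefault((m.sentence_index, m.char_span), set()).add(m.database)
    mentions = [
        replace(m, provenance=(m.provenance + ";ambiguous").lstrip(";"))
        if len(by_span[(m.sentence_index, m.char_span)]) > 1
        else m
        for m in mentions
    ]
    mentions.sort(
        key=lambda m: (
            m.sentence_index if m.sentence_index is not None else -1,
            m.char_span if m.char_span else (-1, -1),
            m.database.value,
            m.accession,
        )
    )
    return mentions


def rescue_cross_database(
    token: str,
    cued_db: Database,
    active_dbs: Iterable[Database],
    patterns: Mapping[Database, PatternSpec] | None = None,
) -> Database | None:
    """Reassign a token that fails its cued database's shapes.

    Returns the unique other active database whose shapes match the whole
    token, or None when zero or several match (the candidate is dropped).
    """
    active = set(active_dbs)
    patterns = patterns or default_pattern_specs(active | {cued_db})
    def whole(db: Database) -> bool:
        hits = match_shapes(token, db, patterns.get(db))
        return any(t == token and span == (0, len(token)) for t, span in hits)

    if whole(cued_db):
        raise ValueError("token matches the cued database; rescue not applicable")
    alternatives = [db for db in sorted(active, key=lambda d: d.value)
                    if db is not cued_db and whole(db)]
    return alternatives[0] if len(alternatives) == 1 else None


def annotate_corpus(
    articles: Iterable[Article],
    config: AnaConfig | None = None,
    lexicon: CueLexicon | None = None,
    patterns: Mapping[Database, PatternSpec] | None = None,
    resolver: Whitelist | None = None,
) -> list[Mention]:
    out: list[Mention] = []
    for article in articles:
        out.extend(annotate_article(article, config, lexicon, patterns, resolver))
    return out
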