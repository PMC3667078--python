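"""Accession shape grammars and contextual cue vocabularies.

Each database has a small set of *shapes*: positional character-class
descriptions of what its accession numbers look like (e.g. an ENA nucleotide
accession is "two letters followed by six digits").  Shapes are stored
structurally as runs of character classes with repeat bounds, so the same
definition drives regex compilation, a position-by-position reference
checker used in tests, and random sampling of valid accessions.

Contextual cues are the trigger words ("genbank", "pdb", ...) that license
candidate generation for a database at the sentence level, plus the
article-level terms that gate the whole pipeline.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from .databases import Database

UPPER = frozenset(string.ascii_uppercase)
DIGIT = frozenset(string.digits)
ALNUM = UPPER | DIGIT


@dataclass(frozen=True)
class Segment:
    """A run of characters drawn from one class, repeated within bounds."""

    chars: frozenset
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.min_repeat < 1 or self.max_repeat < self.min_repeat:
            raise ValueError("invalid repeat bounds")

    def to_regex(self) -> str:
        cls = _charclass(self.chars)
        if self.min_repeat == self.max_repeat == 1:
            return cls
        if self.min_repeat == self.max_repeat:
            return f"{cls}{{{self.min_repeat}}}"
        return f"{cls}{{{self.min_repeat},{self.max_repeat}}}"


def _charclass(chars: frozenset) -> str:
    if chars == UPPER:
        return "[A-Z]"
    if chars == DIGIT:
        return "[0-9]"
    if chars == ALNUM:
        return "[A-Z0-9]"
    members = sorted(chars)
    # literal single character (may be a hyphen)
    if len(members) == 1:
        return re.escape(members[0])
    return "[" + "".join(re.escape(c) for c in members) + "]"


Shape = tuple  # tuple[Segment, ...]


def shape_regex(shape: Sequence[Segment]) -> str:
    return "".join(seg.to_regex() for seg in shape)


def shape_matches(shape: Sequence[Segment], token: str) -> bool:
    """Position-wise check that ``token`` is generated by ``shape``.

    Walks the segments recursively rather than going through the compiled
    regex; kept simple so it can serve as an independent reference.
    """

    def walk(pos: int, seg_idx: int) -> bool:
        if seg_idx == len(shape):
            return pos == len(token)
        seg = shape[seg_idx]
        for n in range(seg.min_repeat, seg.max_repeat + 1):
            end = pos + n
            if end > len(token):
                break
            if all(token[i] in seg.chars for i in range(pos, end)):
                if walk(end, seg_idx + 1):
                    return True
            else:
                break
        return False

    return walk(0, 0)


def _lit(s: str) -> list:
    return [Segment(frozenset(c)) for c in s]


def _ena_shape(n_letters: int, min_digits: int, max_digits: int | None = None) -> Shape:
    max_digits = min_digits if max_digits is None else max_digits
    return (
        Segment(UPPER, n_letters, n_letters),
        Segment(DIGIT, min_digits, max_digits),
    )


# Shape tables for the core databases.  ENA: a fixed count of letters
# followed by a fixed (or bounded) count of digits, five variants.  UniProt:
# six-character accessions in two first-letter classes.  PDB: one digit then
# three alphanumerics -- which deliberately also matches four-digit years;
# those survive shape matching and are weeded out by cues and validation.
_UNIPROT_FIRST_A = frozenset(set(string.ascii_uppercase) - set("OPQ"))
_UNIPROT_FIRST_B = frozenset("OPQ")

DEFAULT_SHAPES: dict[Database, tuple[Shape, ...]] = {
    Database.ENA: (
        _ena_shape(1, 5),
        _ena_shape(2, 6),
        _ena_shape(3, 5),
        _ena_shape(4, 8, 10),
        _ena_shape(5, 7),
    ),
    Database.UNIPROT: (
        (
            Segment(_UNIPROT_FIRST_A),
            Segment(DIGIT),
            Segment(UPPER),
            Segment(ALNUM, 2, 2),
            Segment(DIGIT),
        ),
        (
            Segment(_UNIPROT_FIRST_B),
            Segment(DIGIT),
            Segment(ALNUM, 3, 3),
            Segment(DIGIT),
        ),
    ),
    Database.PDB: ((Segment(DIGIT), Segment(ALNUM, 3, 3)),),
    # Extension databases: shapes follow the public identifier format
    # guidelines of each resource (provenance=external-guideline).
    Database.PFAM: (tuple(_lit("PF") + [Segment(DIGIT, 5, 5)]),),
    Database.INTERPRO: (tuple(_lit("IPR") + [Segment(DIGIT, 6, 6)]),),
    Database.ARRAYEXPRESS: (
        tuple(
            _lit("E-")
            + [Segment(UPPER, 4, 4)]
            + _lit("-")
            + [Segment(DIGIT, 1, 8)]
        ),
    ),
    Database.ENSEMBL: (
        (
            *_lit("ENS"),
            Segment(UPPER, 1, 6),  # optional species code folded into [1,6] letters incl. feature type
            Segment(DIGIT, 11, 11),
        ),
    ),
}


@dataclass(frozen=True)
class PatternSpec:
    """The shape grammar of one database."""

    database: Database
    shapes: tuple
    provenance: str = "paper"

    def compiled(self) -> re.Pattern:
        return _compiled_pattern(self.database, self.shapes)


def default_pattern_specs(
    databases: Iterable[Database] | None = None,
) -> dict[Database, PatternSpec]:
    dbs = list(databases) if databases is not None else list(Database)
    out = {}
    for db in dbs:
        prov = "paper" if db in (Database.ENA, Database.UNIPROT, Database.PDB) else "external-guideline"
        out[db] = PatternSpec(db, DEFAULT_SHAPES[db], prov)
    return out


_COMPILED_CACHE: dict[tuple, re.Pattern] = {}


def _compiled_pattern(database: Database, shapes: tuple) -> re.Pattern:
    key = (database, shapes)
    if key not in _COMPILED_CACHE:
        alternation = "|".join(f"(?:{shape_regex(s)})" for s in shapes)
        # Candidate tokens must be delimited by non-alphanumerics or string
        # boundaries; a shape never matches inside a longer alphanumeric run.
        pat = rf"(?<![A-Za-z0-9])(?:{alternation})(?![A-Za-z0-9])"
        _COMPILED_CACHE[key] = re.compile(pat, re.IGNORECASE)
    return _COMPILED_CACHE[key]


def match_shapes(
    text: str, database: Database, spec: PatternSpec | None = None
) -> list[tuple[str, tuple[int, int]]]:
    """Find every token in ``text`` matching one of the database's shapes.

    Returns ``(token, (start, end))`` pairs with 0-based half-open spans over
    the original text.  Matching is case-insensitive; the returned token is
    the original slice (normalize separately so spans stay valid).
    """
    if spec is None:
        spec = default_pattern_specs([database])[database]
    if spec.database is not database:
        raise ValueError("spec/database mismatch")
    return [(m.group(0), m.span()) for m in spec.compiled().finditer(text)]


_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_accession(token: str, database: Database | None = None) -> str:
    """Uppercase and strip a trailing ``.<digits>`` version suffix.

    Idempotent; the ``database`` argument is accepted for interface symmetry
    but normalization is database-independent.
    """
    return _VERSION_SUFFIX.sub("", token.strip().upper())


_SPLIT_ACC = re.compile(r"^([A-Z-]*[A-Z])(\d+)$")

# range punctuation seen in articles: hyphen-minus, en dash, em dash, minus sign
RANGE_MARKERS = "-–—−"


def split_accession(accession: str) -> tuple[str, str]:
    """Split a normalized accession into (letter prefix, numeral part)."""
    m = _SPLIT_ACC.match(accession)
    if not m:
        raise ValueError(f"accession has no trailing numeral part: {accession!r}")
    return m.group(1), m.group(2)


class RangeRejection(ValueError):
    """Raised when two endpoints cannot form an accession range."""


def expand_range(
    start: str, end: str, database: Database, enabled: bool = False
) -> list[str]:
    """Expand an accession range like ``EF151088–EF151123``.

    With ``enabled=False`` only the two endpoints are returned, mirroring a
    pipeline that tags range endpoints individually.  With ``enabled=True``
    the full inclusive arithmetic sequence over the numeral part is
    generated, zero-padded to the endpoints' width.
    """
    start = normalize_accession(start)
    end = normalize_accession(end)
    p1, n1 = split_accession(start)
    p2, n2 = split_accession(end)
    if p1 != p2:
        raise RangeRejection(f"prefix mismatch: {start} vs {end}")
    if len(n1) != len(n2):
        raise RangeRejection(f"numeral width mismatch: {start} vs {end}")
    lo, hi = int(n1), int(n2)
    if hi < lo:
        raise RangeRejection(f"descending range: {start} vs {end}")
    if not enabled:
        return [start, end] if start != end else [start]
    width = len(n1)
    return [f"{p1}{i:0{width}d}" for i in range(lo, hi + 1)]


# --- contextual cues ---------------------------------------------------------

DEFAULT_SENTENCE_CUES: dict[Database, frozenset] = {
    Database.ENA: frozenset({"genbank", "gen", "ddbj", "embl"}),
    Database.UNIPROT: frozenset({"swissprot", "sprot", "uniprot"}),
    Database.PDB: frozenset({"pdb"}),
    Database.ENSEMBL: frozenset({"ensembl"}),
    Database.PFAM: frozenset({"pfam"}),
    Database.INTERPRO: frozenset({"interpro"}),
    Database.ARRAYEXPRESS: frozenset({"arrayexpress"}),
}


@dataclass(frozen=True)
class CueLexicon:
    """Per-database sentence cues plus article-level gating terms."""

    sentence_cues: Mapping[Database, frozenset] = field(
        default_factory=lambda: dict(DEFAULT_SENTENCE_CUES)
    )
    extra_article_terms: frozenset = frozenset({"accession"})

    @property
    def article_terms(self) -> frozenset:
        terms = set(self.extra_article_terms)
        for cues in self.sentence_cues.values():
            terms |= cues
        return frozenset(terms)

    def restricted(self, databases: Iterable[Database]) -> "CueLexicon":
        dbs = set(databases)
        return CueLexicon(
            sentence_cues={d: c for d, c in self.sentence_cues.items() if d in dbs},
            extra_article_terms=self.extra_article_terms,
        )


_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")


def text_tokens(text: str) -> set:
    """Lowercase whole tokens of ``text``, plus hyphen-collapsed variants.

    The collapsed variants let hyphenated spellings ("Swiss-Prot") hit the
    single-word cue forms ("swissprot").
    """
    out = set()
    for m in _TOKEN_RE.finditer(text):
        tok = m.group(0).lower()
        out.add(tok)
        if "-" in tok:
            out.add(tok.replace("-", ""))
            out.update(tok.split("-"))
    return out


# --- config round-trip -------------------------------------------------------


def _shape_to_config(shape: Shape) -> list[dict]:
    out = []
    for seg in shape:
        if seg.chars == UPPER:
            cls = "letter"
        elif seg.chars == DIGIT:
            cls = "digit"
        elif seg.chars == ALNUM:
            cls = "alnum"
        else:
            cls = "".join(sorted(seg.chars))
        out.append({"class": cls, "min": seg.min_repeat, "max": seg.max_repeat})
    return out


def _shape_from_config(entries: list[dict]) -> Shape:
    segs = []
    for e in entries:
        cls = e["class"]
        if cls == "letter":
            chars = UPPER
        elif cls == "digit":
            chars = DIGIT
        elif cls == "alnum":
            chars = ALNUM
        else:
            chars = frozenset(cls)
        segs.append(Segment(chars, int(e.get("min", 1)), int(e.get("max", e.get("min", 1)))))
    return tuple(segs)


def dump_grammar_config(
    specs: Mapping[Database, PatternSpec], lexicon: CueLexicon
) -> str:
    """Serialize shapes and cues to YAML."""
    doc = {
        "patterns": {
            db.value: {
                "provenance": spec.provenance,
                "shapes": [_shape_to_config(s) for s in spec.shapes],
            }
            for db, spec in specs.items()
        },
        "cues": {
            db.value: sorted(cues) for db, cues in lexicon.sentence_cues.items()
        },
        "article_terms": sorted(lexicon.extra_article_terms),
    }
    return yaml.safe_dump(doc, sort_keys=True)


def load_grammar_config(text: str) -> tuple[dict, CueLexicon]:
    """Load shapes and cues from a YAML document produced by dump_grammar_config."""
    doc = yaml.safe_load(text)
    specs = {}
    for label, entry in (doc.get("patterns") or {}).items():
        db = Database.from_string(label)
        shapes = tuple(_shape_from_config(s) for s in entry["shapes"])
        specs[db] = PatternSpec(db, shapes, entry.get("provenance", "paper"))
    cues = {
        Database.from_string(label): frozenset(t.lower() for t in terms)
        for label, terms in (doc.get("cues") or {}).items()
    }
    lexicon = CueLexicon(
        sentence_cues=cues or dict(DEFAULT_SENTENCE_CUES),
        extra_article_terms=frozenset(
            t.lower() for t in doc.get("article_terms", ["accession"])
        ),
    )
    return specs, lexicon
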