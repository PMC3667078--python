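"""Deterministic synthetic JATS corpus with planted accession citations.

The generator emulates the structure that matters to the miner: body
sentences carrying accession citations next to database cue words, a
publisher-tagged subset wrapped in ``ext-link`` mark-up, per-journal
tagging policies (some journals tag everything, some nothing), citations
relegated to back-matter footnotes, and decoy tokens that share an
accession's shape but are not real records (calendar years under a PDB cue,
shape-valid strings without any cue, and cued strings absent from the
database).  Alongside the articles it emits the whitelist that stands in
for database lookup and a ground-truth ledger for scoring.

Everything is drawn from one seeded PRNG, so a spec and seed reproduce the
corpus byte for byte.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .databases import CORE_DATABASES, Database
from .grammar import DEFAULT_SHAPES, Segment, shape_matches
from .jats import XLINK_NS

EXT_LINK_CODE = {Database.PDB: "pdb", Database.ENA: "gen", Database.UNIPROT: "spr"}

#: deposition-statement templates; every one contains a same-sentence cue
#: for its database, with "{acc}" where the accession goes
CITATION_TEMPLATES: dict[Database, tuple[str, ...]] = {
    Database.ENA: (
        "The sequences obtained in this study have been deposited in GenBank [GenBank: {acc}].",
        "All reads were submitted to the EMBL nucleotide archive under accession {acc}.",
        "The assembled genome is available from DDBJ ({acc}).",
    ),
    Database.UNIPROT: (
        "The mature peptide corresponds to UniProt entry {acc}.",
        "Homologues were retrieved by searching against the Swiss-Prot record {acc}.",
        "Sequence features were taken from the curated sprot entry {acc}.",
    ),
    Database.PDB: (
        "The template structure was taken from PDB entry {acc}.",
        "Coordinates and structure factors are available in the PDB under code {acc}.",
        "Docking used the crystal structure (PDB {acc}) as receptor.",
    ),
    Database.ENSEMBL: (
        "Gene models follow the Ensembl annotation {acc}.",
    ),
    Database.PFAM: (
        "The domain belongs to Pfam family {acc}.",
    ),
    Database.INTERPRO: (
        "The signature maps to InterPro entry {acc}.",
    ),
    Database.ARRAYEXPRESS: (
        "Raw expression data are in ArrayExpress under {acc}.",
    ),
}

FILLER_SENTENCES = (
    "The results were consistent across biological replicates.",
    "Samples were incubated at 37 degrees for two hours before analysis.",
    "Statistical significance was assessed with a two-sided test.",
    "Expression levels varied substantially between tissues.",
    "The assay was repeated three times with similar outcomes.",
    "These findings agree with earlier reports on related species.",
)

DECOY_YEAR_TEMPLATE = "The PDB has grown considerably since {year}."
DECOY_CUELESS_TEMPLATE = "The label {acc} appears only in the supplementary tables."
DECOY_UNLISTED_TEMPLATES = {
    Database.ENA: "Further unpublished sequences are referred to in GenBank as {acc}.",
    Database.UNIPROT: "A withdrawn UniProt identifier {acc} is mentioned for completeness.",
    Database.PDB: "An obsolete PDB code {acc} was cited in the original report.",
}


class GenerationError(ValueError):
    """The corpus spec is internally impossible."""


@dataclass(frozen=True)
class CorpusSpec:
    n_articles: int = 50
    seed: int = 0
    per_db_citation_rate: dict = field(
        default_factory=lambda: {
            Database.ENA: 1.2,
            Database.PDB: 0.6,
            Database.UNIPROT: 0.3,
        }
    )
    publisher_tag_fraction: float = 0.6
    decoy_rate: float = 1.0
    footnote_fraction: float = 0.05
    year_range: tuple = (1990, 2012)
    journals: tuple = (
        ("Journal of Structured Archiving", "high"),
        ("Annals of Untagged Biology", "zero"),
        ("Molecular Notes", "partial"),
        ("Sequence Reports", "high"),
        ("Integrative Data Letters", "partial"),
    )
    back_matter: bool = True

    def __post_init__(self) -> None:
        for name, frac in (
            ("publisher_tag_fraction", self.publisher_tag_fraction),
            ("footnote_fraction", self.footnote_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise GenerationError(f"{name} must be in [0, 1]")
        if self.decoy_rate < 0 or any(r < 0 for r in self.per_db_citation_rate.values()):
            raise GenerationError("rates must be non-negative")
        if self.footnote_fraction > 0 and not self.back_matter:
            raise GenerationError("footnote placement requires back matter")
        if self.year_range[0] > self.year_range[1]:
            raise GenerationError("empty year range")


@dataclass(frozen=True)
class TruthRow:
    article_id: str
    database: Database
    accession: str
    zone: str
    publisher_tagged: bool
    is_decoy: bool


@dataclass
class CorpusBundle:
    articles_dir: Path
    whitelist_path: Path
    truth_path: Path
    article_files: list
    ledger: list
    whitelist_pairs: set


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth's method; fine for the small rates used here."""
    if lam <= 0:
        return 0
    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def sample_accession(database: Database, rng: random.Random) -> str:
    """Draw a shape-valid accession: uniform over shapes, then positions.

    All-digit draws are rejected and resampled so that a sampled accession
    can never collide with a calendar-year decoy token.
    """
    shapes = DEFAULT_SHAPES[database]
    while True:
        shape = shapes[rng.randrange(len(shapes))]
        chars = []
        for seg in shape:
            n = rng.randint(seg.min_repeat, seg.max_repeat)
            pool = sorted(seg.chars)
            chars.extend(rng.choice(pool) for _ in range(n))
        token = "".join(chars)
        if not token.isdigit():
            return token


@dataclass
class _PlannedCitation:
    database: Database
    accession: str
    zone: str  # "body" | "footnote"
    publisher_tagged: bool
    template: str


@dataclass
class _PlannedDecoy:
    kind: str  # "year" | "cueless" | "unlisted"
    database: Database | None
    token: str
    template: str


@dataclass
class _PlannedArticle:
    article_id: str
    journal: str
    policy: str
    year: int
    citations: list
    decoys: list


_TAG_PROB = {"high": 1.0, "zero": 0.0}


def _plan(spec: CorpusSpec) -> tuple[list, set]:
    rng = random.Random(spec.seed)
    articles: list[_PlannedArticle] = []
    whitelist: set = set()
    for i in range(spec.n_articles):
        journal, policy = spec.journals[i % len(spec.journals)]
        year = rng.randint(*spec.year_range)
        article_id = f"PMC{9000001 + i}"
        citations = []
        for db in sorted(spec.per_db_citation_rate, key=lambda d: d.value):
            for _ in range(_poisson(rng, spec.per_db_citation_rate[db])):
                acc = sample_accession(db, rng)
                zone = (
                    "footnote"
                    if spec.back_matter and rng.random() < spec.footnote_fraction
                    else "body"
                )
                tag_prob = _TAG_PROB.get(policy, spec.publisher_tag_fraction)
                tagged = db in EXT_LINK_CODE and rng.random() < tag_prob
                template = rng.choice(CITATION_TEMPLATES[db])
                citations.append(_PlannedCitation(db, acc, zone, tagged, template))
                whitelist.add((db, acc))
        articles.append(_PlannedArticle(article_id, journal, policy, year, citations, []))

    # decoys second: the "unlisted" class must avoid the completed whitelist
    for art in articles:
        for _ in range(_poisson(rng, spec.decoy_rate)):
            kind = rng.choice(["year", "cueless", "unlisted"])
            if kind == "year":
                token = str(rng.randint(1990, 2012))
                art.decoys.append(
                    _PlannedDecoy("year", Database.PDB, token,
                                  DECOY_YEAR_TEMPLATE.format(year=token))
                )
            else:
                db = rng.choice(sorted(DECOY_UNLISTED_TEMPLATES, key=lambda d: d.value))
                token = sample_accession(db, rng)
                while (db, token) in whitelist:
                    token = sample_accession(db, rng)
                template = (
                    DECOY_CUELESS_TEMPLATE.format(acc=token)
                    if kind == "cueless"
                    else DECOY_UNLISTED_TEMPLATES[db].format(acc=token)
                )
                art.decoys.append(_PlannedDecoy(kind, db, token, template))
    return articles, whitelist


def _sentence_nodes(parent: etree._Element, text: str, citation: _PlannedCitation | None):
    """Append sentence text to ``parent``, wrapping the accession in an
    ext-link element when the citation is publisher-tagged."""
    if citation is None or not citation.publisher_tagged:
        parent.text = (parent.text or "") + text + " "
        return
    before, _, after = text.partition(citation.accession)
    parent.text = (parent.text or "") + before
    link = etree.SubElement(parent, "ext-link")
    link.set("ext-link-type", EXT_LINK_CODE[citation.database])
    link.set(f"{{{XLINK_NS}}}href", citation.accession)
    link.text = citation.accession
    link.tail = after + " "


def _build_xml(art: _PlannedArticle, spec: CorpusSpec, rng: random.Random) -> bytes:
    nsmap = {"xlink": XLINK_NS}
    root = etree.Element("article", nsmap=nsmap)
    front = etree.SubElement(root, "front")
    jm = etree.SubElement(front, "journal-meta")
    jtg = etree.SubElement(jm, "journal-title-group")
    etree.SubElement(jtg, "journal-title").text = art.journal
    am = etree.SubElement(front, "article-meta")
    aid = etree.SubElement(am, "article-id")
    aid.set("pub-id-type", "pmc")
    aid.text = art.article_id
    pd = etree.SubElement(am, "pub-date")
    etree.SubElement(pd, "year").text = str(art.year)

    body = etree.SubElement(root, "body")
    body_items: list = [c for c in art.citations if c.zone == "body"]
    body_items += [d for d in art.decoys]
    rng.shuffle(body_items)

    # paragraphs of one planted sentence framed by filler sentences
    if not body_items:
        p = etree.SubElement(body, "p")
        p.text = " ".join(rng.choice(FILLER_SENTENCES) for _ in range(3))
    for item in body_items:
        p = etree.SubElement(body, "p")
        p.text = rng.choice(FILLER_SENTENCES) + " "
        if isinstance(item, _PlannedCitation):
            _sentence_nodes(p, item.template.format(acc=item.accession), item)
        else:
            _sentence_nodes(p, item.template, None)
        tail = rng.choice(FILLER_SENTENCES)
        if len(p) > 0:
            p[-1].tail = (p[-1].tail or "") + tail
        else:
            p.text += tail

    footnotes = [c for c in art.citations if c.zone == "footnote"]
    if spec.back_matter:
        back = etree.SubElement(root, "back")
        if footnotes:
            fng = etree.SubElement(back, "fn-group")
            for c in footnotes:
                fn = etree.SubElement(fng, "fn")
                p = etree.SubElement(fn, "p")
                _sentence_nodes(p, c.template.format(acc=c.accession), c)
        ref_list = etree.SubElement(back, "ref-list")
        ref = etree.SubElement(ref_list, "ref")
        etree.SubElement(ref, "mixed-citation").text = (
            "Author A, Author B. A prior study. Some Journal. "
            f"{max(art.year - rng.randint(1, 5), 1980)}."
        )
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def generate_corpus(spec: CorpusSpec, out_dir: Path | str) -> CorpusBundle:
    """Write ``articles/*.xml``, ``whitelist.tsv`` and ``truth.tsv``.

    The whitelist holds every planted (non-decoy) accession and none of the
    decoys; the truth ledger lists planted citations and decoys with their
    zone and publisher-tagging status.
    """
    out_dir = Path(out_dir)
    articles_dir = out_dir / "articles"
    articles_dir.mkdir(parents=True, exist_ok=True)
    planned, whitelist = _plan(spec)
    xml_rng = random.Random(spec.seed + 1)

    files = []
    ledger: list[TruthRow] = []
    for art in planned:
        path = articles_dir / f"{art.article_id}.xml"
        path.write_bytes(_build_xml(art, spec, xml_rng))
        files.append(path)
        for c in art.citations:
            ledger.append(
                TruthRow(art.article_id, c.database, c.accession, c.zone,
                         c.publisher_tagged, False)
            )
        for d in art.decoys:
            ledger.append(
                TruthRow(art.article_id, d.database, d.token, "body", False, True)
            )

    whitelist_path = out_dir / "whitelist.tsv"
    with open(whitelist_path, "w") as fh:
        fh.write("# synthetic whitelist: planted accessions only\n")
        for db, acc in sorted(whitelist, key=lambda p: (p[0].value, p[1])):
            fh.write(f"{db.value}\t{acc}\n")

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("article_id\tdatabase\taccession\tzone\tpublisher_tagged\tis_decoy\n")
        for row in ledger:
            fh.write(
                f"{row.article_id}\t{row.database.value}\t{row.accession}\t"
                f"{row.zone}\t{row.publisher_tagged}\t{row.is_decoy}\n"
            )

    return CorpusBundle(articles_dir, whitelist_path, truth_path, files, ledger, whitelist)


def read_truth(path: Path | str) -> list[TruthRow]:
    rows = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            aid, db, acc, zone, tagged, decoy = line.rstrip("\n").split("\t")
            rows.append(
                TruthRow(aid, Database.from_string(db), acc, zone,
                         tagged == "True", decoy == "True")
            )
    return rows
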